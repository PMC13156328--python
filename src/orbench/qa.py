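"""Question-answer generation for the 23 benchmark tasks.

Each task has one canonical question template (with slot filling) and a pure
ground-truth derivation from a :class:`~orbench.simulate.TimepointRecord` and
its surrounding :class:`~orbench.simulate.SceneTimeline`. Task/modality gating
ensures a task is only instantiated for sources whose modality profile carries
the required annotations — e.g. scene-graph tasks need ``scene_graphs``, robot
and sterility tasks need the fully multimodal profile, gaze tasks need
``gaze``.

Derivations are deterministic in the record, so every stored answer re-derives
identically from the serialized scene (generation is a pure function).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .answers import AnswerValue
from .simulate import (
    CONTACT_PREDICATES,
    PERSON_ROLES,
    PHASE_VERB,
    ROBOT_END,
    STERILE_ROLES,
    TOOL_CLASSES,
    EntityState,
    ModalityProfile,
    SceneTimeline,
    TimepointRecord,
)

logger = logging.getLogger(__name__)

REFERENCE_VIEW = "view0"  # defines left-to-right order and 2D localization

KNOWN_PREDICATES = frozenset(
    {"touching", "holding", "assisting", "monitoring", "lying_on", "cutting",
     "drilling", "sawing", "suturing", "preparing", "cementing", "cleaning"}
)


class TaskId(str, Enum):
    PEOPLE_COUNTING = "people_counting"
    ROLE_DETECTION = "role_detection"
    INTERACTION_DETECTION = "interaction_detection"
    ATTRIBUTE_DETECTION = "attribute_detection"
    ACTION_DETECTION = "action_detection"
    ESTIMATE_TIME_UNTIL = "estimate_time_until"
    ESTIMATE_STATUS = "estimate_status"
    IS_COMPLETED = "is_completed"
    IS_BASE_ARRAY_VISIBLE = "is_base_array_visible"
    IS_ROBOT_CALIBRATED = "is_robot_calibrated"
    STERILITY_BREACH_DETECTION = "sterility_breach_detection"
    ROBOT_STEP_DETECTION = "robot_step_detection"
    NEXT_ROBOT_STEP_ESTIMATION = "next_robot_step_estimation"
    LOCALIZATION_2D = "localization_2d"
    LOCALIZATION_3D = "localization_3d"
    DISTANCE_3D = "distance_3d"
    TOOL_DETECTION = "tool_detection"
    SCENE_GRAPH_GENERATION = "scene_graph_generation"
    ENTITY_DETECTION = "entity_detection"
    SORTED_ENTITY_DETECTION = "sorted_entity_detection"
    GAZE_LOCATION = "gaze_location"
    GAZE_OBJECT_DETECTION = "gaze_object_detection"
    MONITOR_TEXT_RECOGNITION = "monitor_text_recognition"


#: answer tag (and units for scalars) per task
TASK_ANSWER_KIND: Dict[TaskId, Tuple[str, Optional[str]]] = {
    TaskId.PEOPLE_COUNTING: ("count", None),
    TaskId.ROLE_DETECTION: ("set", None),
    TaskId.INTERACTION_DETECTION: ("label", None),
    TaskId.ATTRIBUTE_DETECTION: ("label", None),
    TaskId.ACTION_DETECTION: ("label", None),
    TaskId.ESTIMATE_TIME_UNTIL: ("scalar", "s"),
    TaskId.ESTIMATE_STATUS: ("scalar", "%"),
    TaskId.IS_COMPLETED: ("binary", None),
    TaskId.IS_BASE_ARRAY_VISIBLE: ("binary", None),
    TaskId.IS_ROBOT_CALIBRATED: ("binary", None),
    TaskId.STERILITY_BREACH_DETECTION: ("binary", None),
    TaskId.ROBOT_STEP_DETECTION: ("label", None),
    TaskId.NEXT_ROBOT_STEP_ESTIMATION: ("label", None),
    TaskId.LOCALIZATION_2D: ("box", None),
    TaskId.LOCALIZATION_3D: ("point3", None),
    TaskId.DISTANCE_3D: ("scalar", "m"),
    TaskId.TOOL_DETECTION: ("set", None),
    TaskId.SCENE_GRAPH_GENERATION: ("triplets", None),
    TaskId.ENTITY_DETECTION: ("set", None),
    TaskId.SORTED_ENTITY_DETECTION: ("sequence", None),
    TaskId.GAZE_LOCATION: ("point2", None),
    TaskId.GAZE_OBJECT_DETECTION: ("label", None),
    TaskId.MONITOR_TEXT_RECOGNITION: ("text", None),
}

#: modality gating: task is supported if ANY of the listed flag-sets is fully on
TASK_REQUIREMENTS: Dict[TaskId, Tuple[Tuple[str, ...], ...]] = {
    TaskId.PEOPLE_COUNTING: (("multiview_boxes",), ("points_3d",)),
    TaskId.ROLE_DETECTION: (("roles",),),
    TaskId.INTERACTION_DETECTION: (("scene_graphs",),),
    TaskId.ATTRIBUTE_DETECTION: (("attributes",),),
    TaskId.ACTION_DETECTION: (("phases",),),
    TaskId.ESTIMATE_TIME_UNTIL: (("phases",),),
    TaskId.ESTIMATE_STATUS: (("phases",),),
    TaskId.IS_COMPLETED: (("phases",),),
    TaskId.IS_BASE_ARRAY_VISIBLE: (("robot_log",),),
    TaskId.IS_ROBOT_CALIBRATED: (("robot_log",),),
    TaskId.STERILITY_BREACH_DETECTION: (("scene_graphs", "robot_log"),),
    TaskId.ROBOT_STEP_DETECTION: (("robot_log",),),
    TaskId.NEXT_ROBOT_STEP_ESTIMATION: (("robot_log",),),
    TaskId.LOCALIZATION_2D: (("multiview_boxes",), ("tool_boxes",)),
    TaskId.LOCALIZATION_3D: (("points_3d",),),
    TaskId.DISTANCE_3D: (("points_3d",),),
    TaskId.TOOL_DETECTION: (("tool_boxes",), ("robot_log",)),
    TaskId.SCENE_GRAPH_GENERATION: (("scene_graphs",),),
    TaskId.ENTITY_DETECTION: (("multiview_boxes",), ("tool_boxes",)),
    TaskId.SORTED_ENTITY_DETECTION: (("multiview_boxes",), ("tool_boxes",)),
    TaskId.GAZE_LOCATION: (("gaze",),),
    TaskId.GAZE_OBJECT_DETECTION: (("gaze", "tool_boxes"),),
    TaskId.MONITOR_TEXT_RECOGNITION: (("monitor_text",),),
}

TASK_TEMPLATES: Dict[TaskId, str] = {
    TaskId.PEOPLE_COUNTING: "How many people are in the OR?",
    TaskId.ROLE_DETECTION: "Which roles are present in the OR?",
    TaskId.INTERACTION_DETECTION: "What is the interaction between the {a} and the {b}?",
    TaskId.ATTRIBUTE_DETECTION: "What is the {attr} of the {cls}?",
    TaskId.ACTION_DETECTION: "What is the current action?",
    TaskId.ESTIMATE_TIME_UNTIL: "How many seconds until {action} begins?",
    TaskId.ESTIMATE_STATUS: "What is the progress of the current action in percent?",
    TaskId.IS_COMPLETED: "Was {action} already performed?",
    TaskId.IS_BASE_ARRAY_VISIBLE: "Is the robot base array visible?",
    TaskId.IS_ROBOT_CALIBRATED: "Is the robot calibrated?",
    TaskId.STERILITY_BREACH_DETECTION: "Is there a sterility breach?",
    TaskId.ROBOT_STEP_DETECTION: "What is the current robot step?",
    TaskId.NEXT_ROBOT_STEP_ESTIMATION: "What is the next robot step?",
    TaskId.LOCALIZATION_2D: "Where is the {cls} in the image? Answer with the bounding box x1, y1, x2, y2.",
    TaskId.LOCALIZATION_3D: "What is the 3D center of the {cls} in the OR, in meters?",
    TaskId.DISTANCE_3D: "What is the distance between the {a} and the {b}, in meters?",
    TaskId.TOOL_DETECTION: "Which tools are currently in use?",
    TaskId.SCENE_GRAPH_GENERATION: "List the current scene graph as (subject, predicate, object) triplets.",
    TaskId.ENTITY_DETECTION: "List all entities currently in the OR.",
    TaskId.SORTED_ENTITY_DETECTION: "List all entities in the OR from left to right.",
    TaskId.GAZE_LOCATION: "Where is the surgeon looking, in image pixel coordinates?",
    TaskId.GAZE_OBJECT_DETECTION: "What object is the surgeon looking at?",
    TaskId.MONITOR_TEXT_RECOGNITION: "What information is shown on the monitor?",
}


def task_supported(task: TaskId, profile: ModalityProfile) -> bool:
    return any(all(profile.flag(f) for f in req) for req in TASK_REQUIREMENTS[task])


def supported_tasks(profile: ModalityProfile) -> List[TaskId]:
    return [t for t in TaskId if task_supported(t, profile)]


@dataclass
class QAPair:
    qa_id: str
    task: TaskId
    question: str
    answer: AnswerValue
    source_tag: str
    case_id: str
    timepoint_t: float
    template_id: str
    split: Optional[str] = None

    def to_json(self) -> dict:
        return {
            "qa_id": self.qa_id,
            "task": self.task.value,
            "question": self.question,
            "answer": self.answer.to_json(),
            "source_tag": self.source_tag,
            "case_id": self.case_id,
            "t": self.timepoint_t,
            "template_id": self.template_id,
            "split": self.split,
        }

    @staticmethod
    def from_json(d: dict) -> "QAPair":
        return QAPair(
            qa_id=d["qa_id"],
            task=TaskId(d["task"]),
            question=d["question"],
            answer=AnswerValue.from_json(d["answer"]),
            source_tag=d["source_tag"],
            case_id=d["case_id"],
            timepoint_t=d["t"],
            template_id=d["template_id"],
            split=d.get("split"),
        )


# ---------------------------------------------------------------------------
# primitive derivations

def distance_3d(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between entity centroids, meters."""
    if not all(math.isfinite(v) for v in (*p, *q)):
        raise ValueError("points must be finite")
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def detect_sterility_breach(
    triplets: Iterable[Tuple[str, str, str]], entities: Sequence[EntityState]
) -> str:
    """'yes' iff a contact predicate links a sterile-role person to a
    non-sterile entity; unknown predicates are ignored with a warning."""
    sterile_of = {e.cls: e.sterile for e in entities}
    for s, p, o in triplets:
        if p not in KNOWN_PREDICATES:
            logger.warning("ignoring unknown predicate %r", p)
            continue
        if p not in CONTACT_PREDICATES:
            continue
        for a, b in ((s, o), (o, s)):
            if a in STERILE_ROLES and not sterile_of.get(b, True):
                return "yes"
    return "no"


def resolve_gaze_target(
    gaze_point: Tuple[float, float],
    entities: Sequence[EntityState],
    view: str = REFERENCE_VIEW,
) -> Optional[str]:
    """Class of the smallest-area box (in ``view``) containing the gaze point."""
    gx, gy = gaze_point
    best: Optional[Tuple[float, str]] = None
    for e in entities:
        box = e.boxes_2d.get(view)
        if box is None:
            continue
        x1, y1, x2, y2 = box
        if x1 <= gx < x2 and y1 <= gy < y2:
            area = (x2 - x1) * (y2 - y1)
            if best is None or area < best[0]:
                best = (area, e.cls)
    return best[1] if best else None


def time_until(timeline: SceneTimeline, t: float, action: str) -> Optional[float]:
    """Seconds from ``t`` to the start of phase ``action``; None if not in the
    future (an 'is completed' question is generated instead)."""
    for phase, a, _ in timeline.phase_spans:
        if phase == action:
            return a - t if a > t else None
    raise KeyError(f"unknown action {action!r} in case workflow")


def phase_progress(timeline: SceneTimeline, t: float) -> float:
    for phase, a, b in timeline.phase_spans:
        if a <= t < b or (phase == timeline.phase_spans[-1][0] and t >= a):
            return min(100.0, max(0.0, 100.0 * (t - a) / max(b - a, 1e-9)))
    raise ValueError("t outside the timeline")


def next_robot_step(record: TimepointRecord, workflow: Sequence[str]) -> str:
    """FSM successor of the current robot step; terminal token after the last."""
    if record.robot is None:
        raise ValueError("record has no robot log")
    idx = list(workflow).index(record.robot.current_step)
    return workflow[idx + 1] if idx + 1 < len(workflow) else ROBOT_END


# ---------------------------------------------------------------------------
# answer derivation per task

def _persons(record: TimepointRecord) -> List[EntityState]:
    return [e for e in record.entities if e.cls in PERSON_ROLES]


def _boxed_entities(record: TimepointRecord, view: str = REFERENCE_VIEW) -> List[EntityState]:
    return [e for e in record.entities if view in e.boxes_2d]


def derive_answer(
    task: TaskId,
    record: TimepointRecord,
    context: SceneTimeline,
    **binding,
) -> Optional[AnswerValue]:
    """Canonical ground-truth answer, or None (skip) when unsupported.

    Tasks over a specific entity or pair take the binding via keyword
    arguments (``cls=``, ``a=``/``b=``, ``action=``, ``attr=``).
    """
    if not task_supported(task, context.profile):
        return None

    if task is TaskId.PEOPLE_COUNTING:
        return AnswerValue("count", len(_persons(record)))

    if task is TaskId.ROLE_DETECTION:
        return AnswerValue("set", frozenset(e.cls for e in _persons(record)))

    if task is TaskId.INTERACTION_DETECTION:
        a, b = binding["a"], binding["b"]
        for s, p, o in record.triplets or ():
            if (s, o) == (a, b):
                return AnswerValue("label", p)
        return None

    if task is TaskId.ATTRIBUTE_DETECTION:
        cls, attr = binding["cls"], binding["attr"]
        for e in record.entities:
            if e.cls == cls and attr in e.attributes:
                return AnswerValue("label", e.attributes[attr])
        return None

    if task is TaskId.ACTION_DETECTION:
        return AnswerValue("label", record.phase) if record.phase else None

    if task is TaskId.ESTIMATE_TIME_UNTIL:
        dt = time_until(context, record.t, binding["action"])
        return AnswerValue("scalar", float(int(round(dt))), "s") if dt is not None else None

    if task is TaskId.ESTIMATE_STATUS:
        if record.phase_progress is None:
            return None
        return AnswerValue("scalar", float(int(round(record.phase_progress))), "%")

    if task is TaskId.IS_COMPLETED:
        action = binding["action"]
        for phase, _, b in context.phase_spans:
            if phase == action:
                return AnswerValue("binary", "yes" if b <= record.t else "no")
        return None

    if task is TaskId.IS_BASE_ARRAY_VISIBLE:
        r = record.robot
        return AnswerValue("binary", "yes" if r.base_array_visible else "no") if r else None

    if task is TaskId.IS_ROBOT_CALIBRATED:
        r = record.robot
        return AnswerValue("binary", "yes" if r.calibrated else "no") if r else None

    if task is TaskId.STERILITY_BREACH_DETECTION:
        if record.triplets is None:
            return None
        return AnswerValue("binary", detect_sterility_breach(record.triplets, record.entities))

    if task is TaskId.ROBOT_STEP_DETECTION:
        return AnswerValue("label", record.robot.current_step) if record.robot else None

    if task is TaskId.NEXT_ROBOT_STEP_ESTIMATION:
        if record.robot is None:
            return None
        return AnswerValue("label", next_robot_step(record, context.robot_steps))

    if task is TaskId.LOCALIZATION_2D:
        cls = binding["cls"]
        for e in record.entities:
            if e.cls == cls and REFERENCE_VIEW in e.boxes_2d:
                return AnswerValue("box", tuple(e.boxes_2d[REFERENCE_VIEW]))
        return None

    if task is TaskId.LOCALIZATION_3D:
        cls = binding["cls"]
        for e in record.entities:
            if e.cls == cls and e.position_3d is not None:
                return AnswerValue("point3", tuple(round(c, 2) for c in e.position_3d))
        return None

    if task is TaskId.DISTANCE_3D:
        a, b = binding["a"], binding["b"]
        pa = next((e.position_3d for e in record.entities if e.cls == a), None)
        pb = next((e.position_3d for e in record.entities if e.cls == b), None)
        if pa is None or pb is None:
            return None
        return AnswerValue("scalar", round(distance_3d(pa, pb), 2), "m")

    if task is TaskId.TOOL_DETECTION:
        if record.tools_in_use is None:
            return None
        return AnswerValue("set", frozenset(record.tools_in_use))

    if task is TaskId.SCENE_GRAPH_GENERATION:
        if record.triplets is None:
            return None
        return AnswerValue("triplets", frozenset(record.triplets))

    if task is TaskId.ENTITY_DETECTION:
        boxed = _boxed_entities(record)
        return AnswerValue("set", frozenset(e.cls for e in boxed)) if boxed else None

    if task is TaskId.SORTED_ENTITY_DETECTION:
        boxed = _boxed_entities(record)
        if not boxed:
            return None
        ordered = sorted(boxed, key=lambda e: ((e.boxes_2d[REFERENCE_VIEW][0] + e.boxes_2d[REFERENCE_VIEW][2]) / 2, e.cls))
        return AnswerValue("sequence", tuple(e.cls for e in ordered))

    if task is TaskId.GAZE_LOCATION:
        return AnswerValue("point2", tuple(record.gaze.point)) if record.gaze else None

    if task is TaskId.GAZE_OBJECT_DETECTION:
        if record.gaze is None:
            return None
        tools = [e for e in record.entities if e.cls in TOOL_CLASSES]
        target = resolve_gaze_target(record.gaze.point, tools)
        return AnswerValue("label", target if target else "none")

    if task is TaskId.MONITOR_TEXT_RECOGNITION:
        return AnswerValue("text", record.monitor_text) if record.monitor_text else None

    raise ValueError(f"unhandled task {task}")


# ---------------------------------------------------------------------------
# QA pair generation

def _q(task: TaskId, **slots) -> str:
    text = TASK_TEMPLATES[task].format(**{k: str(v).replace("_", " ") for k, v in slots.items()})
    return text


def _unique_class_entities(record: TimepointRecord) -> List[EntityState]:
    counts: Dict[str, int] = {}
    for e in record.entities:
        counts[e.cls] = counts.get(e.cls, 0) + 1
    return [e for e in record.entities if counts[e.cls] == 1]


def generate_for_timepoint(
    record: TimepointRecord, context: SceneTimeline, timepoint_index: int
) -> List[QAPair]:
    """All QA pairs supported by the source's modality profile at a timepoint."""
    out: List[QAPair] = []
    prefix = f"{record.case_id}:{timepoint_index:04d}"

    def emit(task: TaskId, question: str, answer: Optional[AnswerValue], suffix: str = "0") -> None:
        if answer is None:
            return
        out.append(
            QAPair(
                qa_id=f"{prefix}:{task.value}:{suffix}",
                task=task,
                question=question,
                answer=answer,
                source_tag=record.source_tag,
                case_id=record.case_id,
                timepoint_t=record.t,
                template_id=f"{task.value}-v1",
            )
        )

    ctx = context
    # unary tasks
    for task in (
        TaskId.PEOPLE_COUNTING,
        TaskId.ROLE_DETECTION,
        TaskId.ACTION_DETECTION,
        TaskId.ESTIMATE_STATUS,
        TaskId.IS_BASE_ARRAY_VISIBLE,
        TaskId.IS_ROBOT_CALIBRATED,
        TaskId.STERILITY_BREACH_DETECTION,
        TaskId.ROBOT_STEP_DETECTION,
        TaskId.NEXT_ROBOT_STEP_ESTIMATION,
        TaskId.TOOL_DETECTION,
        TaskId.SCENE_GRAPH_GENERATION,
        TaskId.ENTITY_DETECTION,
        TaskId.SORTED_ENTITY_DETECTION,
        TaskId.GAZE_LOCATION,
        TaskId.GAZE_OBJECT_DETECTION,
        TaskId.MONITOR_TEXT_RECOGNITION,
    ):
        if task_supported(task, ctx.profile):
            emit(task, _q(task), derive_answer(task, record, ctx))

    uniq = _unique_class_entities(record)

    # per-phase temporal tasks
    if task_supported(TaskId.IS_COMPLETED, ctx.profile):
        for j, (phase, _, _) in enumerate(ctx.phase_spans):
            emit(
                TaskId.IS_COMPLETED,
                _q(TaskId.IS_COMPLETED, action=phase),
                derive_answer(TaskId.IS_COMPLETED, record, ctx, action=phase),
                suffix=str(j),
            )
    if task_supported(TaskId.ESTIMATE_TIME_UNTIL, ctx.profile):
        for j, (phase, a, _) in enumerate(ctx.phase_spans):
            if a > record.t:
                emit(
                    TaskId.ESTIMATE_TIME_UNTIL,
                    _q(TaskId.ESTIMATE_TIME_UNTIL, action=phase),
                    derive_answer(TaskId.ESTIMATE_TIME_UNTIL, record, ctx, action=phase),
                    suffix=str(j),
                )

    # entity-bound tasks (only unambiguous class references)
    if task_supported(TaskId.LOCALIZATION_2D, ctx.profile):
        for j, e in enumerate(uniq):
            if REFERENCE_VIEW in e.boxes_2d:
                emit(
                    TaskId.LOCALIZATION_2D,
                    _q(TaskId.LOCALIZATION_2D, cls=e.cls),
                    derive_answer(TaskId.LOCALIZATION_2D, record, ctx, cls=e.cls),
                    suffix=str(j),
                )
    if task_supported(TaskId.LOCALIZATION_3D, ctx.profile):
        for j, e in enumerate(uniq):
            if e.position_3d is not None:
                emit(
                    TaskId.LOCALIZATION_3D,
                    _q(TaskId.LOCALIZATION_3D, cls=e.cls),
                    derive_answer(TaskId.LOCALIZATION_3D, record, ctx, cls=e.cls),
                    suffix=str(j),
                )
    if task_supported(TaskId.ATTRIBUTE_DETECTION, ctx.profile):
        j = 0
        for e in uniq:
            for attr in sorted(e.attributes):
                emit(
                    TaskId.ATTRIBUTE_DETECTION,
                    _q(TaskId.ATTRIBUTE_DETECTION, attr=attr, cls=e.cls),
                    derive_answer(TaskId.ATTRIBUTE_DETECTION, record, ctx, cls=e.cls, attr=attr),
                    suffix=str(j),
                )
                j += 1

    # pair-bound tasks: person-person pairs plus head_surgeon-to-anything
    if task_supported(TaskId.DISTANCE_3D, ctx.profile):
        pos_ents = [e for e in uniq if e.position_3d is not None]
        persons = [e for e in pos_ents if e.cls in PERSON_ROLES]
        others = [e for e in pos_ents if e.cls not in PERSON_ROLES]
        pairs: List[Tuple[str, str]] = []
        for i in range(len(persons)):
            for k in range(i + 1, len(persons)):
                pairs.append((persons[i].cls, persons[k].cls))
        head = next((e for e in persons if e.cls == "head_surgeon"), None)
        if head is not None:
            pairs.extend(("head_surgeon", o.cls) for o in others)
        for j, (a, b) in enumerate(pairs):
            emit(
                TaskId.DISTANCE_3D,
                _q(TaskId.DISTANCE_3D, a=a, b=b),
                derive_answer(TaskId.DISTANCE_3D, record, ctx, a=a, b=b),
                suffix=str(j),
            )

    if task_supported(TaskId.INTERACTION_DETECTION, ctx.profile) and record.triplets:
        seen: set = set()
        j = 0
        for s, p, o in record.triplets:
            if (s, o) in seen:
                continue
            seen.add((s, o))
            emit(
                TaskId.INTERACTION_DETECTION,
                _q(TaskId.INTERACTION_DETECTION, a=s, b=o),
                derive_answer(TaskId.INTERACTION_DETECTION, record, ctx, a=s, b=o),
                suffix=str(j),
            )
            j += 1

    return out


def generate_for_case(timeline: SceneTimeline) -> List[QAPair]:
    out: List[QAPair] = []
    for i, record in enumerate(timeline.records):
        out.extend(generate_for_timepoint(record, timeline, i))
    return out
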