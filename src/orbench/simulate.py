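"""Synthetic operating-room scene simulator.

Generates annotation-only timelines of surgical cases whose structure mirrors
four public OR dataset families: a multi-view RGB-D room dataset (MVOR-like:
multi-view person boxes, 3D positions, phases), a scene-graph knee-replacement
dataset (4D-OR-like: + semantic scene graphs, clinical roles, attributes), an
egocentric dataset (EgoSurgery-like: single head-mounted view, tool boxes,
gaze fixations, phases) and a fully multimodal robotic dataset (MM-OR-like:
everything, plus robot state logs, sterility flags, monitor text and speech
transcripts). No pixels, point clouds or audio are rendered — the simulator
emits the annotations a downstream QA engine consumes.

Conventions: 2D boxes are 0-based pixel xyxy, (x1,y1) inclusive top-left,
(x2,y2) exclusive bottom-right; 3D coordinates are meters with origin at the
room-floor center; cameras are overhead pinhole views.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# configuration

MODALITY_FLAGS = (
    "multiview_boxes",
    "points_3d",
    "scene_graphs",
    "roles",
    "attributes",
    "phases",
    "gaze",
    "tool_boxes",
    "robot_log",
    "tracking",
    "audio_transcript",
    "monitor_text",
)


@dataclass(frozen=True)
class ModalityProfile:
    """Which annotation modalities a pseudo-dataset exposes."""

    multiview_boxes: bool = False
    points_3d: bool = False
    scene_graphs: bool = False
    roles: bool = False
    attributes: bool = False
    phases: bool = False
    gaze: bool = False
    tool_boxes: bool = False
    robot_log: bool = False
    tracking: bool = False
    audio_transcript: bool = False
    monitor_text: bool = False
    n_views: int = 4

    def __post_init__(self) -> None:
        if not (self.multiview_boxes or self.points_3d or self.tool_boxes or self.gaze):
            raise ValueError("profile must enable at least one visual modality")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")

    def flag(self, name: str) -> bool:
        return bool(getattr(self, name))


DEFAULT_PROFILES: Dict[str, ModalityProfile] = {
    "mvor-like": ModalityProfile(multiview_boxes=True, points_3d=True, phases=True, n_views=3),
    "4dor-like": ModalityProfile(
        multiview_boxes=True, points_3d=True, phases=True,
        scene_graphs=True, roles=True, attributes=True, n_views=6,
    ),
    "egosurgery-like": ModalityProfile(
        phases=True, gaze=True, tool_boxes=True, n_views=1,
    ),
    "mmor-like": ModalityProfile(**{f: True for f in MODALITY_FLAGS}, n_views=4),
}

SOURCE_TAGS = tuple(DEFAULT_PROFILES)


@dataclass(frozen=True)
class SimConfig:
    """Scale and geometry of a synthetic corpus."""

    n_cases_per_source: int = 4
    timepoints_per_case: int = 30
    room_extent: Tuple[float, float, float] = (10.0, 6.0, 3.0)
    image_size: Tuple[int, int] = (640, 480)
    breach_fraction: float = 0.5  # fraction of sterility-annotated cases with a breach interval
    seed: int = 0
    source_profiles: Optional[Dict[str, ModalityProfile]] = None

    def __post_init__(self) -> None:
        if self.n_cases_per_source < 1 or self.timepoints_per_case < 1:
            raise ValueError("counts must be >= 1")
        if any(e <= 0 for e in self.room_extent):
            raise ValueError("room_extent must be strictly positive")
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least 64x64")

    @property
    def profiles(self) -> Dict[str, ModalityProfile]:
        return self.source_profiles or DEFAULT_PROFILES


# ---------------------------------------------------------------------------
# scene vocabulary

STERILE_ROLES = frozenset({"head_surgeon", "assistant_surgeon", "scrub_nurse"})
PERSON_ROLES = (
    "head_surgeon",
    "assistant_surgeon",
    "scrub_nurse",
    "circulating_nurse",
    "anaesthetist",
    "patient",
)
OBJECT_CLASSES = ("operating_table", "instrument_table", "anesthesia_machine", "monitor", "tool_cart")
TOOL_CLASSES = ("drill", "saw", "hammer", "scalpel", "forceps", "suction", "grasper")
TOOL_COLORS = ("blue", "green", "silver", "black", "red", "yellow")

PHASES = ("preparation", "incision", "drilling", "sawing", "implant_placement", "closing")
PHASE_TOOL = {
    "preparation": "forceps",
    "incision": "scalpel",
    "drilling": "drill",
    "sawing": "saw",
    "implant_placement": "hammer",
    "closing": "grasper",
}
PHASE_VERB = {
    "preparation": "preparing",
    "incision": "cutting",
    "drilling": "drilling",
    "sawing": "sawing",
    "implant_placement": "cementing",
    "closing": "suturing",
}

ROBOT_STEPS = (
    "docking",
    "registration",
    "calibration",
    "cut_planning",
    "drilling_guide",
    "bone_cutting",
    "implant_check",
    "undocking",
)
ROBOT_END = "end"

CONTACT_PREDICATES = frozenset({"touching", "holding"})

# approximate physical extents (x, y, z meters) per entity class, for 2D boxes
_CLASS_EXTENT = {"person": (0.6, 0.6, 1.75)}
_CLASS_EXTENT.update({c: (1.8, 0.9, 1.0) for c in ("operating_table",)})
_CLASS_EXTENT.update({c: (1.0, 0.6, 1.0) for c in ("instrument_table", "tool_cart")})
_CLASS_EXTENT.update({c: (0.6, 0.6, 1.5) for c in ("anesthesia_machine", "monitor")})
_CLASS_EXTENT.update({c: (0.30, 0.12, 0.20) for c in TOOL_CLASSES})

_MAX_STEP_M = 0.25  # per-timepoint random-walk displacement bound

_TRANSCRIPT_TEMPLATES = (
    "please hand me the {tool}",
    "starting {phase} now",
    "check the patient vitals",
    "suction here please",
    "the {tool} is ready",
    "we are moving to {phase}",
)


# ---------------------------------------------------------------------------
# geometry

@dataclass(frozen=True)
class ViewGeometry:
    """Overhead pinhole camera: position in room coordinates, focal in pixels."""

    camera: Tuple[float, float, float]
    focal_px: float
    image_size: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.focal_px <= 0 or self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("degenerate view geometry")


def default_views(config: SimConfig, n_views: int) -> List[ViewGeometry]:
    """Ceiling cameras: one central, the rest toward the room corners."""
    ex, ey, ez = config.room_extent
    h = ez + 1.5
    offsets = [(0.0, 0.0), (-ex / 4, -ey / 4), (ex / 4, -ey / 4), (-ex / 4, ey / 4), (ex / 4, ey / 4)]
    views = []
    for i in range(n_views):
        ox, oy = offsets[i % len(offsets)]
        views.append(ViewGeometry((ox, oy, h), focal_px=260.0, image_size=config.image_size))
    return views


def project_to_views(
    position_3d: Sequence[float],
    extent_3d: Sequence[float],
    views: Sequence[ViewGeometry],
) -> Dict[str, Tuple[int, int, int, int]]:
    """Project a 3D-positioned entity into each overhead view as a clipped box.

    The box is centered at the pinhole projection of the entity center, with
    half-sizes ``f * extent / (2 * depth)``. Views where the entity projects
    entirely outside the image, or where the depth is non-positive
    (degenerate geometry for an overhead camera), yield no box.
    """
    x, y, z = (float(v) for v in position_3d)
    ex, ey, _ = (float(v) for v in extent_3d)
    boxes: Dict[str, Tuple[int, int, int, int]] = {}
    for i, view in enumerate(views):
        cx, cy, cz = view.camera
        depth = cz - z
        if depth <= 1e-6:
            raise ValueError("degenerate view geometry: point at or above camera plane")
        w, h = view.image_size
        f = view.focal_px
        u = f * (x - cx) / depth + w / 2.0
        v = f * (y - cy) / depth + h / 2.0
        hw = f * ex / (2.0 * depth)
        hh = f * ey / (2.0 * depth)
        x1, y1 = u - hw, v - hh
        x2, y2 = u + hw, v + hh
        # clip to image bounds; drop if no visible area remains
        x1c, y1c = max(0.0, x1), max(0.0, y1)
        x2c, y2c = min(float(w), x2), min(float(h), y2)
        if x2c - x1c < 1.0 or y2c - y1c < 1.0:
            continue
        bx1, by1 = int(math.floor(x1c)), int(math.floor(y1c))
        bx2, by2 = int(math.ceil(x2c)), int(math.ceil(y2c))
        bx2, by2 = min(bx2, w), min(by2, h)
        if bx2 <= bx1:
            bx2 = bx1 + 1
        if by2 <= by1:
            by2 = by1 + 1
        boxes[f"view{i}"] = (bx1, by1, bx2, by2)
    return boxes


# ---------------------------------------------------------------------------
# domain records

@dataclass
class EntityState:
    entity_id: str
    cls: str
    attributes: Dict[str, str] = field(default_factory=dict)
    position_3d: Optional[Tuple[float, float, float]] = None
    boxes_2d: Dict[str, Tuple[int, int, int, int]] = field(default_factory=dict)
    sterile: bool = True


@dataclass
class RobotState:
    current_step: str
    step_index: int
    calibrated: bool
    base_array_visible: bool
    completed_steps: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.current_step in self.completed_steps:
            raise ValueError("current robot step cannot already be completed")
        if self.step_index != len(self.completed_steps):
            raise ValueError("step_index inconsistent with completed_steps")


@dataclass
class GazeSample:
    point: Tuple[int, int]
    target_entity: Optional[str] = None


@dataclass
class TimepointRecord:
    case_id: str
    source_tag: str
    t: float
    entities: List[EntityState]
    triplets: Optional[List[Tuple[str, str, str]]] = None
    phase: Optional[str] = None
    phase_progress: Optional[float] = None
    robot: Optional[RobotState] = None
    gaze: Optional[GazeSample] = None
    tools_in_use: Optional[frozenset] = None
    monitor_text: Optional[str] = None
    transcript_tail: Optional[Tuple[str, ...]] = None


@dataclass
class SceneTimeline:
    """One synthetic surgical case: ordered timepoints plus workflow metadata."""

    case_id: str
    source_tag: str
    profile: ModalityProfile
    records: List[TimepointRecord]
    phase_spans: List[Tuple[str, float, float]]  # (phase, t_start, t_end)
    robot_steps: Tuple[str, ...]  # ordered workflow (empty when no robot log)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc_record(r: TimepointRecord) -> dict:
            d = {
                "t": r.t,
                "entities": [
                    {
                        "entity_id": e.entity_id,
                        "cls": e.cls,
                        "attributes": e.attributes,
                        "position_3d": list(e.position_3d) if e.position_3d else None,
                        "boxes_2d": {k: list(v) for k, v in e.boxes_2d.items()},
                        "sterile": e.sterile,
                    }
                    for e in r.entities
                ],
                "triplets": [list(t) for t in r.triplets] if r.triplets is not None else None,
                "phase": r.phase,
                "phase_progress": r.phase_progress,
                "robot": asdict(r.robot) if r.robot else None,
                "gaze": {"point": list(r.gaze.point), "target_entity": r.gaze.target_entity}
                if r.gaze
                else None,
                "tools_in_use": sorted(r.tools_in_use) if r.tools_in_use is not None else None,
                "monitor_text": r.monitor_text,
                "transcript_tail": list(r.transcript_tail) if r.transcript_tail is not None else None,
            }
            return d

        return {
            "case_id": self.case_id,
            "source_tag": self.source_tag,
            "profile": {f: self.profile.flag(f) for f in MODALITY_FLAGS} | {"n_views": self.profile.n_views},
            "phase_spans": [list(s) for s in self.phase_spans],
            "robot_steps": list(self.robot_steps),
            "records": [enc_record(r) for r in self.records],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_dict(d: dict) -> "SceneTimeline":
        prof = ModalityProfile(**d["profile"])
        records = []
        for rd in d["records"]:
            entities = [
                EntityState(
                    entity_id=e["entity_id"],
                    cls=e["cls"],
                    attributes=dict(e["attributes"]),
                    position_3d=tuple(e["position_3d"]) if e["position_3d"] else None,
                    boxes_2d={k: tuple(v) for k, v in e["boxes_2d"].items()},
                    sterile=e["sterile"],
                )
                for e in rd["entities"]
            ]
            robot = RobotState(**{**rd["robot"], "completed_steps": tuple(rd["robot"]["completed_steps"])}) if rd["robot"] else None
            gaze = (
                GazeSample(point=tuple(rd["gaze"]["point"]), target_entity=rd["gaze"]["target_entity"])
                if rd["gaze"]
                else None
            )
            records.append(
                TimepointRecord(
                    case_id=d["case_id"],
                    source_tag=d["source_tag"],
                    t=rd["t"],
                    entities=entities,
                    triplets=[tuple(t) for t in rd["triplets"]] if rd["triplets"] is not None else None,
                    phase=rd["phase"],
                    phase_progress=rd["phase_progress"],
                    robot=robot,
                    gaze=gaze,
                    tools_in_use=frozenset(rd["tools_in_use"]) if rd["tools_in_use"] is not None else None,
                    monitor_text=rd["monitor_text"],
                    transcript_tail=tuple(rd["transcript_tail"]) if rd["transcript_tail"] is not None else None,
                )
            )
        return SceneTimeline(
            case_id=d["case_id"],
            source_tag=d["source_tag"],
            profile=prof,
            records=records,
            phase_spans=[tuple(s) for s in d["phase_spans"]],
            robot_steps=tuple(d["robot_steps"]),
        )


# ---------------------------------------------------------------------------
# simulation

def _case_rng(seed: int, source_tag: str, case_index: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, source, case)."""
    src_idx = SOURCE_TAGS.index(source_tag) if source_tag in SOURCE_TAGS else (
        sum(source_tag.encode()) % 997 + 10
    )
    return np.random.default_rng(np.random.SeedSequence([seed, src_idx, case_index]))


def _clip_walk(pos: np.ndarray, step: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    nrm = float(np.linalg.norm(step))
    if nrm > _MAX_STEP_M:
        step = step * (_MAX_STEP_M / nrm)
    return np.clip(pos + step, lo, hi)


def simulate_case(config: SimConfig, source_tag: str, case_index: int) -> SceneTimeline:
    """Simulate one case. Deterministic for fixed (seed, source_tag, case_index)."""
    profiles = config.profiles
    if source_tag not in profiles:
        raise KeyError(f"unknown source_tag {source_tag!r}; configured: {sorted(profiles)}")
    profile = profiles[source_tag]
    rng = _case_rng(config.seed, source_tag, case_index)
    case_id = f"{source_tag}-case{case_index:04d}"
    n = config.timepoints_per_case
    ex, ey, ez = config.room_extent
    views = default_views(config, profile.n_views)

    # --- timeline clock: strictly increasing timepoints
    ts = np.cumsum(rng.uniform(5.0, 15.0, size=n))
    duration = float(ts[-1]) + 1.0

    # --- phases: contiguous ordered partition of [0, duration]
    weights = rng.uniform(0.6, 1.4, size=len(PHASES))
    bounds = np.concatenate([[0.0], np.cumsum(weights) / weights.sum() * duration])
    phase_spans = [(PHASES[i], float(bounds[i]), float(bounds[i + 1])) for i in range(len(PHASES))]

    # --- cast: persons (roles) and static objects
    n_extra = int(rng.integers(0, 2))
    roles = list(PERSON_ROLES[: 4 + n_extra]) + ["patient"]
    roles = list(dict.fromkeys(roles))  # unique, ordered
    objects = list(OBJECT_CLASSES[: int(rng.integers(3, len(OBJECT_CLASSES) + 1))])

    lo = np.array([-ex / 2 + 0.3, -ey / 2 + 0.3, 0.0])
    hi = np.array([ex / 2 - 0.3, ey / 2 - 0.3, 0.0])
    positions: Dict[str, np.ndarray] = {}
    entities_meta: List[Tuple[str, str, bool, Dict[str, str]]] = []
    for i, role in enumerate(roles):
        eid = f"{case_id}-p{i}"
        positions[eid] = rng.uniform(lo, hi)
        entities_meta.append((eid, role, role in STERILE_ROLES, {}))
    for i, cls in enumerate(objects):
        eid = f"{case_id}-o{i}"
        positions[eid] = rng.uniform(lo, hi)
        entities_meta.append((eid, cls, True, {}))
    # tools: one per phase tool class, with a color attribute; a couple non-sterile
    tool_ids: Dict[str, str] = {}
    tool_sterile: Dict[str, bool] = {}
    used_tools = sorted(set(PHASE_TOOL.values())) + ["suction"]
    for i, cls in enumerate(used_tools):
        eid = f"{case_id}-t{i}"
        tool_ids[cls] = eid
        tool_sterile[cls] = bool(rng.random() > 0.3)
        positions[eid] = rng.uniform(lo, hi)
        entities_meta.append(
            (eid, cls, tool_sterile[cls], {"color": str(rng.choice(TOOL_COLORS))})
        )
    nonsterile_tools = [c for c, s in tool_sterile.items() if not s]

    # --- sterility breach interval (only meaningful for scene-graph + robot sources)
    breach_lo = breach_hi = -1
    if profile.scene_graphs and profile.robot_log and nonsterile_tools and rng.random() < config.breach_fraction:
        breach_lo = int(rng.integers(0, max(1, n - 3)))
        breach_hi = min(n, breach_lo + max(1, int(rng.integers(2, 6))))
    breach_tool = nonsterile_tools[0] if nonsterile_tools else None

    # --- robot FSM schedule: steps spread over the timeline, last step open-ended
    robot_steps: Tuple[str, ...] = ROBOT_STEPS if profile.robot_log else ()
    step_starts = None
    if profile.robot_log:
        cuts = np.sort(rng.uniform(0.05, 0.98, size=len(ROBOT_STEPS) - 1)) * duration
        step_starts = np.concatenate([[0.0], cuts])

    # --- per-case monitor vitals random walk
    hr, sbp, dbp, spo2 = 72.0, 120.0, 80.0, 98.0

    records: List[TimepointRecord] = []
    transcript: List[str] = []

    for k in range(n):
        t = float(ts[k])
        # positions random-walk (persons and tools move; objects static)
        for eid, cls, _, _ in entities_meta:
            if cls in OBJECT_CLASSES:
                continue
            step = rng.normal(0.0, 0.08, size=3)
            step[2] = 0.0
            positions[eid] = _clip_walk(positions[eid], step, lo, hi)

        phase = next(p for p, a, b in phase_spans if a <= t < b or (p == PHASES[-1] and t >= a))
        p_start, p_end = next((a, b) for pp, a, b in phase_spans if pp == phase)
        progress = 100.0 * (t - p_start) / max(p_end - p_start, 1e-9)
        progress = float(min(100.0, max(0.0, progress)))
        current_tool = PHASE_TOOL[phase]

        ents: List[EntityState] = []
        for eid, cls, sterile, attrs in entities_meta:
            extent = _CLASS_EXTENT["person"] if cls in PERSON_ROLES else _CLASS_EXTENT[cls]
            x, y = float(positions[eid][0]), float(positions[eid][1])
            cz = 0.9 if cls in TOOL_CLASSES else extent[2] / 2  # tools on table height
            center = (x, y, float(cz))
            boxed = profile.multiview_boxes or (profile.tool_boxes and cls in TOOL_CLASSES)
            boxes = project_to_views(center, extent, views) if boxed else {}
            ents.append(
                EntityState(
                    entity_id=eid,
                    cls=cls,
                    attributes=dict(attrs) if profile.attributes else {},
                    position_3d=center if profile.points_3d else None,
                    boxes_2d=boxes,
                    sterile=sterile,
                )
            )

        # scene graph
        triplets: Optional[List[Tuple[str, str, str]]] = None
        if profile.scene_graphs:
            triplets = [
                ("head_surgeon", PHASE_VERB[phase], "patient"),
                ("head_surgeon", "holding", current_tool),
                ("patient", "lying_on", "operating_table"),
            ]
            if "scrub_nurse" in (c for _, c, _, _ in entities_meta):
                triplets.append(("scrub_nurse", "assisting", "head_surgeon"))
            if "anaesthetist" in (c for _, c, _, _ in entities_meta):
                triplets.append(("anaesthetist", "monitoring", "patient"))
            if breach_lo <= k < breach_hi and breach_tool:
                triplets.append(("head_surgeon", "touching", breach_tool))

        # robot state
        robot: Optional[RobotState] = None
        if profile.robot_log:
            idx = int(np.searchsorted(step_starts, t, side="right") - 1)
            idx = max(0, min(idx, len(ROBOT_STEPS) - 1))
            robot = RobotState(
                current_step=ROBOT_STEPS[idx],
                step_index=idx,
                calibrated=idx > ROBOT_STEPS.index("calibration"),
                base_array_visible=bool(rng.random() > 0.15),
                completed_steps=ROBOT_STEPS[:idx],
            )

        # tools in use
        tools = None
        if profile.tool_boxes or profile.robot_log or profile.tracking:
            in_use = {current_tool}
            if rng.random() < 0.3:
                in_use.add("suction")
            tools = frozenset(in_use)

        # gaze at the current tool's box center in the ego view
        gaze = None
        if profile.gaze:
            tool_eid = tool_ids[current_tool]
            tool_ent = next(e for e in ents if e.entity_id == tool_eid)
            box = tool_ent.boxes_2d.get("view0")
            w, h = config.image_size
            if box is not None:
                gx = (box[0] + box[2]) / 2 + rng.normal(0, 4)
                gy = (box[1] + box[3]) / 2 + rng.normal(0, 4)
            else:
                gx, gy = rng.uniform(0, w), rng.uniform(0, h)
            point = (int(min(max(gx, 0), w - 1)), int(min(max(gy, 0), h - 1)))
            gaze = GazeSample(point=point, target_entity=tool_eid)

        # monitor text: vitals random walk
        monitor = None
        if profile.monitor_text:
            hr = float(np.clip(hr + rng.normal(0, 2), 50, 130))
            sbp = float(np.clip(sbp + rng.normal(0, 2), 85, 180))
            dbp = float(np.clip(dbp + rng.normal(0, 1.5), 45, 110))
            spo2 = float(np.clip(spo2 + rng.normal(0, 0.4), 88, 100))
            monitor = (
                f"heart rate {hr:.0f} bpm blood pressure {sbp:.0f} over {dbp:.0f} spo2 {spo2:.0f} percent"
            )

        # speech transcript tail (last <= 5 sentences)
        tail = None
        if profile.audio_transcript:
            if rng.random() < 0.6:
                tpl = _TRANSCRIPT_TEMPLATES[int(rng.integers(len(_TRANSCRIPT_TEMPLATES)))]
                transcript.append(tpl.format(tool=current_tool.replace("_", " "), phase=phase.replace("_", " ")))
            tail = tuple(transcript[-5:])

        records.append(
            TimepointRecord(
                case_id=case_id,
                source_tag=source_tag,
                t=t,
                entities=ents,
                triplets=triplets,
                phase=phase if profile.phases else None,
                phase_progress=progress if profile.phases else None,
                robot=robot,
                gaze=gaze,
                tools_in_use=tools,
                monitor_text=monitor,
                transcript_tail=tail,
            )
        )

    return SceneTimeline(
        case_id=case_id,
        source_tag=source_tag,
        profile=profile,
        records=records,
        phase_spans=phase_spans if profile.phases else [],
        robot_steps=robot_steps,
    )


def simulate_corpus(config: SimConfig) -> List[SceneTimeline]:
    """All cases for all configured sources."""
    out = []
    for tag in config.profiles:
        for i in range(config.n_cases_per_source):
            out.append(simulate_case(config, tag, i))
    return out


# ---------------------------------------------------------------------------
# split assignment

def assign_splits(
    cases: Sequence[Tuple[str, str]],
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Dict[str, str]:
    """Assign each (case_id, source_tag) to train/val/test, per source.

    Assignment is by case, never by timepoint, so no scene leaks across
    splits. Counts per split use largest-remainder rounding of the ratios
    within each source; an empty split then steals one case from the largest,
    so all three splits are nonempty per source.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    by_source: Dict[str, List[str]] = {}
    for case_id, tag in cases:
        by_source.setdefault(tag, []).append(case_id)
    labels = ("train", "val", "test")
    rng = np.random.default_rng(seed)
    out: Dict[str, str] = {}
    for tag in sorted(by_source):
        ids = sorted(by_source[tag])
        if len(ids) < 3:
            raise ValueError(f"source {tag!r} has fewer than 3 cases; cannot form 3 splits")
        rng_s = np.random.default_rng(np.random.SeedSequence([seed, sum(tag.encode())]))
        perm = list(rng_s.permutation(ids))
        m = len(ids)
        exact = [r * m for r in ratios]
        counts = [int(math.floor(e)) for e in exact]
        rem = m - sum(counts)
        order = sorted(range(3), key=lambda i: (-(exact[i] - counts[i]), i))
        for i in order[:rem]:
            counts[i] += 1
        for i in range(3):  # no empty split
            if counts[i] == 0:
                j = max(range(3), key=lambda q: counts[q])
                counts[j] -= 1
                counts[i] += 1
        pos = 0
        for lab, c in zip(labels, counts):
            for cid in perm[pos : pos + c]:
                out[cid] = lab
            pos += c
    return out
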