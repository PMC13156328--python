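"""JSON/JSONL persistence for corpora, QA pools, predictions and reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from .qa import QAPair
from .simulate import SceneTimeline


def write_corpus(timelines: Sequence[SceneTimeline], splits: Dict[str, str], out_dir: str | Path) -> None:
    """One JSON file per case plus a JSONL manifest (case_id, source_tag, split)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.jsonl", "w") as mf:
        for tl in timelines:
            with open(out / f"{tl.case_id}.json", "w") as f:
                f.write(tl.to_json())
            mf.write(json.dumps({
                "case_id": tl.case_id,
                "source_tag": tl.source_tag,
                "split": splits.get(tl.case_id),
            }) + "\n")


def read_corpus(in_dir: str | Path) -> Tuple[List[SceneTimeline], Dict[str, str]]:
    in_dir = Path(in_dir)
    splits: Dict[str, str] = {}
    timelines: List[SceneTimeline] = []
    with open(in_dir / "manifest.jsonl") as mf:
        for line in mf:
            rec = json.loads(line)
            splits[rec["case_id"]] = rec["split"]
            with open(in_dir / f"{rec['case_id']}.json") as f:
                timelines.append(SceneTimeline.from_dict(json.load(f)))
    return timelines, splits


def write_qa_jsonl(pairs: Iterable[QAPair], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        for qa in pairs:
            f.write(json.dumps(qa.to_json()) + "\n")


def read_qa_jsonl(path: str | Path) -> List[QAPair]:
    with open(path) as f:
        return [QAPair.from_json(json.loads(line)) for line in f if line.strip()]


def write_predictions(preds: Dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        for qa_id, text in preds.items():
            f.write(json.dumps({"qa_id": qa_id, "answer_text": text}) + "\n")


def read_predictions(path: str | Path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as f:
        for line in f:
            if line.strip():
                rec = json.loads(line)
                out[rec["qa_id"]] = rec["answer_text"]
    return out
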