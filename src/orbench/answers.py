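"""Canonical answer values: typed ground truth, serialization and lenient parsing.

Every QA pair carries an :class:`AnswerValue` — a tagged union covering the
answer kinds the benchmark tasks produce (counts, labels, yes/no, token sets
and sequences, pixel boxes and points, 3D points, unit-carrying scalars,
scene-graph triplet lists, and free text). The canonical text serialization is
what the statistical baseline emits and what the scorer parses back, so
``parse_answer(serialize_answer(a), task) == a`` must hold for every tag.

Parsing of model output is deliberately lenient (case-folding, punctuation
stripping, leading-number extraction) because free-text systems rarely emit
the canonical form exactly; a failure is flagged by returning ``None``, never
by raising.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Optional

#: closed set of answer tags
TAGS = (
    "count",
    "label",
    "binary",
    "set",
    "sequence",
    "box",
    "point2",
    "point3",
    "scalar",
    "triplets",
    "text",
)

_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")
_INT_RE = re.compile(r"[-+]?\d+")
_TRIPLET_RE = re.compile(r"\(([^()]*)\)")


@dataclass(frozen=True)
class AnswerValue:
    """A tagged canonical answer.

    ``value`` representation by tag:
      count      int
      label      str token
      binary     "yes" | "no"
      set        frozenset[str]
      sequence   tuple[str, ...]
      box        (x1, y1, x2, y2) ints, pixel xyxy
      point2     (x, y) ints, pixels
      point3     (x, y, z) floats, meters
      scalar     float, with ``units`` in {"m", "s", "%"}
      triplets   frozenset[(subject, predicate, object)]
      text       str
    """

    tag: str
    value: Any
    units: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tag not in TAGS:
            raise ValueError(f"unknown answer tag: {self.tag}")
        if self.tag == "scalar" and self.units is None:
            raise ValueError("scalar answers must carry units")

    def to_json(self) -> dict:
        v = self.value
        if self.tag == "set":
            v = sorted(v)
        elif self.tag == "triplets":
            v = [list(t) for t in sorted(v)]
        elif self.tag in ("sequence", "box", "point2", "point3"):
            v = list(v)
        return {"tag": self.tag, "value": v, "units": self.units}

    @staticmethod
    def from_json(d: dict) -> "AnswerValue":
        tag, v = d["tag"], d["value"]
        if tag == "set":
            v = frozenset(v)
        elif tag == "triplets":
            v = frozenset(tuple(t) for t in v)
        elif tag == "sequence":
            v = tuple(v)
        elif tag == "box" or tag == "point2":
            v = tuple(int(x) for x in v)
        elif tag == "point3":
            v = tuple(float(x) for x in v)
        elif tag == "count":
            v = int(v)
        elif tag == "scalar":
            v = float(v)
        return AnswerValue(tag, v, d.get("units"))


def normalize_token(tok: str) -> str:
    """Case-fold, trim edge punctuation, collapse inner whitespace to ``_``."""
    tok = tok.strip().casefold()
    tok = tok.strip(".,;:!?\"'()[]{} \t")
    tok = re.sub(r"\s+", "_", tok)
    return tok


def _fmt_float(x: float) -> str:
    # shortest repr that round-trips through float()
    return format(float(x), "g")


def serialize_answer(a: AnswerValue) -> str:
    """Canonical text form of an answer (what the baseline predictor emits)."""
    t, v = a.tag, a.value
    if t == "count":
        return str(int(v))
    if t in ("label", "binary", "text"):
        return str(v)
    if t == "set":
        return ", ".join(sorted(v))
    if t == "sequence":
        return ", ".join(v)
    if t in ("box", "point2"):
        return ", ".join(str(int(c)) for c in v)
    if t == "point3":
        return ", ".join(_fmt_float(c) for c in v)
    if t == "scalar":
        return f"{_fmt_float(v)} {a.units}"
    if t == "triplets":
        return "; ".join(f"({s}, {p}, {o})" for s, p, o in sorted(v))
    raise ValueError(f"unknown tag {t}")


def _numbers(text: str) -> list[float]:
    return [float(m) for m in _NUM_RE.findall(text)]


def _split_tokens(text: str) -> list[str]:
    parts = re.split(r"[;,]| and ", text)
    toks = [normalize_token(p) for p in parts]
    return [t for t in toks if t]


def parse_answer(text: str, tag: str, units: Optional[str] = None) -> Optional[AnswerValue]:
    """Leniently parse free text into the answer kind ``tag``.

    Returns ``None`` on failure (flagged, never raised). ``units`` is attached
    to scalar answers; unit words in the text are ignored beyond locating the
    leading number.
    """
    if text is None:
        return None
    raw = text.strip()
    if tag == "text":
        return AnswerValue("text", raw) if raw else None
    low = raw.casefold()
    if tag == "binary":
        m = re.search(r"\b(yes|no|true|false)\b", low)
        if not m:
            return None
        return AnswerValue("binary", "yes" if m.group(1) in ("yes", "true") else "no")
    if tag == "count":
        m = _INT_RE.search(low)
        return AnswerValue("count", int(m.group())) if m else None
    if tag == "scalar":
        nums = _numbers(low)
        return AnswerValue("scalar", nums[0], units) if nums else None
    if tag == "box":
        nums = _numbers(low)
        if len(nums) < 4:
            return None
        return AnswerValue("box", tuple(int(round(n)) for n in nums[:4]))
    if tag == "point2":
        nums = _numbers(low)
        if len(nums) < 2:
            return None
        return AnswerValue("point2", tuple(int(round(n)) for n in nums[:2]))
    if tag == "point3":
        nums = _numbers(low)
        if len(nums) < 3:
            return None
        return AnswerValue("point3", tuple(nums[:3]))
    if tag == "label":
        tok = normalize_token(low)
        return AnswerValue("label", tok) if tok else None
    if tag == "set":
        toks = _split_tokens(low)
        return AnswerValue("set", frozenset(toks)) if toks or "none" in low else (
            AnswerValue("set", frozenset()) if low in ("", "none", "nothing") else None
        )
    if tag == "sequence":
        toks = _split_tokens(low)
        return AnswerValue("sequence", tuple(toks)) if toks else None
    if tag == "triplets":
        groups = _TRIPLET_RE.findall(low)
        trips = []
        if groups:
            for g in groups:
                parts = [normalize_token(p) for p in g.split(",")]
                if len(parts) == 3 and all(parts):
                    trips.append(tuple(parts))
        else:
            for chunk in low.split(";"):
                parts = [normalize_token(p) for p in chunk.split(",")]
                if len(parts) == 3 and all(parts):
                    trips.append(tuple(parts))
        if not trips and normalize_token(low) not in ("", "none"):
            return None
        return AnswerValue("triplets", frozenset(trips))
    return None
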