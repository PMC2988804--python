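"""Histopathology-derived per-sample weights.

Each tumor sample carries a pathologist's estimate of the area fractions of
tumor epithelium (t), stroma (s) and adipocytes (a), usually from two tissue
sections. The analysis weights derive from these fractions under two
assumption parameters:

``c`` in [0, 1]
    transcription efficiency of adipocytes relative to tumor and stroma
    cells (0 = transcriptionally silent, 1 = equal contribution);
``d`` in (0, 1]
    transcription efficiency of stromal cells relative to tumor epithelium.

The adipocyte rescaling is ``t' = t/(t+s+ac)``, ``s' = s/(t+s+ac)``; the
stroma rescaling is ``t'' = t'/(t'+s'd)`` and ``s'' = (t'+s') - t''`` (so the
pair conserves ``t'+s'``). A tumor-focused analysis uses ``t''`` as the
sample weight, a stroma-focused analysis uses ``s''``, and the unweighted
analysis sets every weight to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("DM", "NoDM")
FOCI = ("tumor", "stroma", "unweighted")

_SECTION_SUM_TOL = 0.5


@dataclass(frozen=True)
class SectionFractions:
    """Area percentages of one tissue section; should sum to ~100."""

    tumor_pct: float
    stroma_pct: float
    adipo_pct: float

    def __post_init__(self):
        for name in ("tumor_pct", "stroma_pct", "adipo_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")

    @property
    def total(self) -> float:
        return self.tumor_pct + self.stroma_pct + self.adipo_pct


@dataclass
class SampleAnnotation:
    """Outcome group and per-section histopathology for one sample."""

    sample_id: str
    group: str
    sections: List[SectionFractions] = field(default_factory=list)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def has_histopathology(self) -> bool:
        return len(self.sections) > 0

    @property
    def mean_fractions(self) -> Tuple[float, float, float]:
        return average_sections(self)


def average_sections(ann: SampleAnnotation) -> Tuple[float, float, float]:
    """Average the per-section area percentages, renormalizing to sum 100.

    Sections whose three percentages do not sum to 100 within 0.5 are
    proportionally renormalized first, with a warning.
    """
    if not ann.sections:
        raise ValueError(f"no histopathology for sample {ann.sample_id!r}")
    t = s = a = 0.0
    for sec in ann.sections:
        tot = sec.total
        if tot <= 0:
            raise ValueError(f"section of sample {ann.sample_id!r} has zero total area")
        if abs(tot - 100.0) > _SECTION_SUM_TOL:
            logger.warning(
                "sample %s: section percentages sum to %.2f, renormalizing to 100",
                ann.sample_id,
                tot,
            )
        t += 100.0 * sec.tumor_pct / tot
        s += 100.0 * sec.stroma_pct / tot
        a += 100.0 * sec.adipo_pct / tot
    n = len(ann.sections)
    return (t / n, s / n, a / n)


def rescale_for_adipocytes(t: float, s: float, a: float, c: float) -> Tuple[float, float]:
    """Down-weight the adipocyte area by its assumed efficiency c.

    Returns the rescaled tumor and stroma shares ``t' = t/(t+s+ac)`` and
    ``s' = s/(t+s+ac)`` on the [0, 1] scale.  The inputs may be percentages
    or fractions; the formula is scale-free.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c={c} outside [0, 1]")
    if min(t, s, a) < 0:
        raise ValueError("area fractions must be nonnegative")
    if t + s <= 0:
        raise ValueError("no tumor or stroma tissue")
    denom = t + s + a * c
    return t / denom, s / denom


def rescale_for_stroma(t_prime: float, s_prime: float, d: float) -> Tuple[float, float]:
    """Rescale tumor/stroma shares under stromal efficiency d.

    ``t'' = t'/(t' + s'd)`` and ``s'' = (t' + s') - t''``; d = 0 is rejected
    because it collapses the weighted test onto the unweighted one.
    """
    if not 0.0 < d <= 1.0:
        raise ValueError(f"d={d} outside (0, 1]")
    if min(t_prime, s_prime) < 0:
        raise ValueError("shares must be nonnegative")
    if t_prime + s_prime <= 0:
        raise ValueError("no tumor or stroma tissue")
    t_dp = t_prime / (t_prime + s_prime * d)
    s_dp = (t_prime + s_prime) - t_dp
    return t_dp, s_dp


@dataclass
class WeightScheme:
    """Per-sample analysis weights for one (focus, c, d) assumption."""

    focus: str
    c: float
    d: float
    weights: Dict[str, float]

    def __post_init__(self):
        if self.focus not in FOCI:
            raise ValueError(f"focus must be one of {FOCI}")
        for sid, w in self.weights.items():
            if not 0.0 <= w <= 1.0 or not math.isfinite(w):
                raise ValueError(f"weight {w} for sample {sid!r} outside [0, 1]")
        if self.focus == "unweighted" and any(w != 1.0 for w in self.weights.values()):
            raise ValueError("unweighted scheme must have all weights equal to 1")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.weights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.weights),
                "focus": self.focus,
                "c": self.c,
                "d": self.d,
                "weight": list(self.weights.values()),
            }
        )


def sample_weights(
    annotations: Sequence[SampleAnnotation],
    focus: str,
    c: float = 0.0,
    d: float = 1.0,
) -> WeightScheme:
    """Build the per-sample weights for one analysis.

    Tumor focus uses w = t'', stroma focus w = s''; the unweighted analysis
    sets every weight to 1.  Samples without histopathology are excluded
    from the weighted schemes but retained in the unweighted one.
    """
    if focus not in FOCI:
        raise ValueError(f"focus must be one of {FOCI}")
    if not annotations:
        raise ValueError("no annotations")
    weights: Dict[str, float] = {}
    if focus == "unweighted":
        for ann in annotations:
            weights[ann.sample_id] = 1.0
        return WeightScheme(focus, c, d, weights)

    n_excluded = 0
    for ann in annotations:
        if not ann.has_histopathology:
            n_excluded += 1
            continue
        t, s, a = average_sections(ann)
        t_p, s_p = rescale_for_adipocytes(t, s, a, c)
        # the stroma rescaling is defined on shares summing to 1 (it is only
        # combined with c = 0); at d = 1 the weights are t', s' themselves
        if d == 1.0:
            t_dp, s_dp = t_p, s_p
        else:
            t_dp, s_dp = rescale_for_stroma(t_p, s_p, d)
        weights[ann.sample_id] = t_dp if focus == "tumor" else s_dp
    if not weights:
        raise ValueError("all samples lack histopathology; weighted analysis impossible")
    if n_excluded:
        logger.info("%d samples without histopathology excluded from %s-focused weights", n_excluded, focus)
    return WeightScheme(focus, c, d, weights)


# -- annotation I/O ----------------------------------------------------------


def read_annotations(path) -> List[SampleAnnotation]:
    """Read the annotation TSV: sample_id, group, section_index, tumor_pct,
    stroma_pct, adipo_pct. Samples may appear with zero sections (missing
    histopathology) by leaving the percentage columns empty."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    if not required <= set(frame.columns):
        raise ValueError(f"annotation table lacks columns {sorted(required - set(frame.columns))}")
    out: Dict[str, SampleAnnotation] = {}
    for _, row in frame.iterrows():
        sid = str(row["sample_id"])
        ann = out.setdefault(sid, SampleAnnotation(sid, str(row["group"])))
        if ann.group != str(row["group"]):
            raise ValueError(f"conflicting group labels for sample {sid!r}")
        if "tumor_pct" in frame.columns and pd.notna(row.get("tumor_pct")):
            ann.sections.append(
                SectionFractions(
                    float(row["tumor_pct"]), float(row["stroma_pct"]), float(row["adipo_pct"])
                )
            )
    return list(out.values())


def annotations_to_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        if ann.sections:
            for idx, sec in enumerate(ann.sections, start=1):
                rows.append(
                    {
                        "sample_id": ann.sample_id,
                        "group": ann.group,
                        "section_index": idx,
                        "tumor_pct": sec.tumor_pct,
                        "stroma_pct": sec.stroma_pct,
                        "adipo_pct": sec.adipo_pct,
                    }
                )
        else:
            rows.append(
                {
                    "sample_id": ann.sample_id,
                    "group": ann.group,
                    "section_index": pd.NA,
                    "tumor_pct": pd.NA,
                    "stroma_pct": pd.NA,
                    "adipo_pct": pd.NA,
                }
            )
    return pd.DataFrame(rows)


def group_labels(annotations: Iterable[SampleAnnotation]) -> Dict[str, str]:
    return {ann.sample_id: ann.group for ann in annotations}
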