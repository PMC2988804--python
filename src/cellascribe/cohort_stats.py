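"""Cohort-level supporting statistics.

Contingency tests on clinical characteristics, the Kolmogorov-Smirnov
comparison of cell-type fraction distributions between outcome groups, the
paired comparison of weights derived from two histopathology procedures,
marker-gene checks relating expression to area fractions, and
cross-platform probe matching by gene symbol.

Note on the contingency convention: the clinical-table p-values here are the
standard upper-tail Pearson chi-square without continuity correction (or the
two-sided Fisher exact test for sparse 2x2 tables); see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .weights import SampleAnnotation, average_sections
from .weighted_test import DEGList, WeightedDifferentialExpression, bh_fdr, permutation_pvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Small observed-count table (2x2 or 2x3) for a clinical characteristic."""

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    counts: Tuple[Tuple[int, ...], ...]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.to_array()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def fisher_exact_2x2(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table (hypergeometric
    tail summation over tables at least as improbable as the observed)."""
    counts = table.to_array()
    if counts.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(p)


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue))


def fraction_distribution_tests(annotations: Sequence[SampleAnnotation]) -> Dict[str, KSResult]:
    """KS comparison of tumor/stroma/adipocyte fraction distributions
    between the DM and NoDM groups."""
    fracs = {"tumor": ([], []), "stroma": ([], []), "adipocyte": ([], [])}
    for ann in annotations:
        if not ann.has_histopathology:
            continue
        t, s, a = average_sections(ann)
        idx = 0 if ann.group == "DM" else 1
        fracs["tumor"][idx].append(t)
        fracs["stroma"][idx].append(s)
        fracs["adipocyte"][idx].append(a)
    return {name: ks_two_sample(dm, nodm) for name, (dm, nodm) in fracs.items()}


@dataclass
class PairedWeightComparison:
    identical: bool
    n: int
    mean_difference: float
    pvalue: Optional[float]  # None when the weights are identical


def paired_weight_comparison(w1: Mapping[str, float], w2: Mapping[str, float]) -> PairedWeightComparison:
    """Paired t-test of two weight maps over their common samples.

    Used to check robustness of the weights to the histopathology procedure
    (pathologist's area estimates vs stereological point counting): a large
    p-value means the two procedures yield interchangeable weights.
    """
    common = sorted(set(w1) & set(w2))
    if len(common) < 2:
        raise ValueError("need at least 2 common samples")
    a = np.array([w1[s] for s in common])
    b = np.array([w2[s] for s in common])
    diff = a - b
    if np.var(diff, ddof=1) == 0:
        return PairedWeightComparison(
            identical=bool(np.all(diff == 0)), n=len(common),
            mean_difference=float(diff.mean()), pvalue=None,
        )
    t = stats.ttest_rel(a, b)
    return PairedWeightComparison(False, len(common), float(diff.mean()), float(t.pvalue))


def extreme_group_marker_test(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    n_top: int = 15,
    B: int = 9999,
    level: float = 0.05,
    seed: Optional[int] = None,
) -> Tuple[List[str], List[str]]:
    """Compare the samples richest in tumor epithelium against those richest
    in stroma.

    Selects the ``n_top`` samples with the highest mean tumor fraction and
    the ``n_top`` with the highest stroma fraction (ties broken by sample
    id; samples landing in both sets are excluded with a warning), runs an
    unweighted permutation t + BH analysis between the two sets, and
    returns ``(list_A, list_B)``: probes elevated in the high-tumor and
    high-stroma sets respectively.
    """
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    with_hist = [ann for ann in annotations if ann.has_histopathology and ann.sample_id in set(matrix.sample_ids)]
    if len(with_hist) < 2 * n_top:
        raise ValueError("not enough annotated samples for two disjoint selections")
    fr = {ann.sample_id: average_sections(ann) for ann in with_hist}
    by_tumor = sorted(fr, key=lambda sid: (-fr[sid][0], sid))[:n_top]
    by_stroma = sorted(fr, key=lambda sid: (-fr[sid][1], sid))[:n_top]
    overlap = set(by_tumor) & set(by_stroma)
    if overlap:
        logger.warning("%d samples fall in both extreme groups; excluded", len(overlap))
        by_tumor = [s for s in by_tumor if s not in overlap]
        by_stroma = [s for s in by_stroma if s not in overlap]
    if not by_tumor or not by_stroma:
        raise ValueError("extreme selections overlap entirely")

    sel = by_tumor + by_stroma
    sub = matrix.subset_samples(sel)
    X = sub.values.to_numpy(dtype=float)
    g1 = np.array([sid in set(by_tumor) for sid in sel])
    w = np.ones(len(sel))
    T_obs, p = permutation_pvalues(X, g1, w, B=B, seed=seed)
    _, rejected = bh_fdr(p, level=level)
    probes = np.asarray(sub.probe_ids)
    list_a = sorted(probes[rejected & (T_obs > 0)])
    list_b = sorted(probes[rejected & (T_obs < 0)])
    return list_a, list_b


def fraction_correlation(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Pearson correlation of each probe with the mean-centered tumor and
    stroma area fractions.

    Returns a frame indexed by probe with columns r_tumor, p_tumor,
    r_stroma, p_stroma, zero_variance.  Zero-variance probes get r = 0,
    p = 1 and the flag set.
    """
    anns = [a for a in annotations if a.has_histopathology and a.sample_id in set(matrix.sample_ids)]
    if len(anns) < 3:
        raise ValueError("need at least 3 annotated samples")
    sids = [a.sample_id for a in anns]
    sub = matrix.subset_samples(sids)
    X = sub.values.to_numpy(dtype=float)
    fracs = np.array([average_sections(a) for a in anns])  # n x (t, s, a)
    n = len(sids)

    out = {"probe_id": sub.probe_ids}
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = np.sqrt((Xc**2).sum(axis=1))
    zero_var = xsd == 0
    for name, col in (("tumor", 0), ("stroma", 1)):
        f = fracs[:, col] - fracs[:, col].mean()
        fsd = np.sqrt((f**2).sum())
        if fsd == 0:
            raise ValueError(f"{name} fractions are constant across samples")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc @ f) / (xsd * fsd)
        r = np.where(zero_var, 0.0, np.clip(r, -1.0, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(zero_var, 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
        out[f"r_{name}"] = r
        out[f"p_{name}"] = p
    out["zero_variance"] = zero_var
    return pd.DataFrame(out).set_index("probe_id")


def match_probes_by_symbol(
    source_symbols: Mapping[str, str],
    target_matrix: ExpressionMatrix,
    target_symbols: Mapping[str, str],
) -> Tuple[Dict[str, str], List[str]]:
    """Match source gene symbols to probes of another platform.

    ``source_symbols`` / ``target_symbols`` map probe id -> gene symbol.
    For a symbol with several candidate target probes, the probe with the
    highest variance across the target cohort wins.  Returns
    ``(symbol -> target probe, unmatched symbols)``.
    """
    var = target_matrix.values.var(axis=1, ddof=1, skipna=True)
    candidates: Dict[str, List[str]] = {}
    probes_in_matrix = set(target_matrix.probe_ids)
    for probe, symbol in target_symbols.items():
        if probe in probes_in_matrix:
            candidates.setdefault(symbol, []).append(probe)
    mapping: Dict[str, str] = {}
    unmatched: List[str] = []
    for symbol in sorted(set(source_symbols.values())):
        probes = candidates.get(symbol)
        if not probes:
            unmatched.append(symbol)
            continue
        mapping[symbol] = max(sorted(probes), key=lambda p: (var[p], p))
    if unmatched:
        logger.info("%d symbols had no probe on the target platform", len(unmatched))
    return mapping, unmatched


def compartment_t_tests(
    matrix: ExpressionMatrix, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-probe Welch-free classical t-tests (equal variance) of DM vs NoDM
    in compartment-pure (e.g. microdissected) expression data."""
    sids = [s for s in matrix.sample_ids if s in groups]
    sub = matrix.subset_samples(sids)
    g = np.array([groups[s] == "DM" for s in sids])
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    X = sub.values.to_numpy(dtype=float)
    res = stats.ttest_ind(X[:, g], X[:, ~g], axis=1, equal_var=True)
    return pd.DataFrame(
        {
            "probe_id": sub.probe_ids,
            "t": res.statistic,
            "p": res.pvalue,
            "mean_DM": X[:, g].mean(axis=1),
            "mean_NoDM": X[:, ~g].mean(axis=1),
        }
    ).set_index("probe_id")
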