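"""Synthetic bulk-expression cohorts with the mixture structure the
weighting model assumes.

Each simulated tumor sample is a mixture of three compartments — tumor
epithelium, stroma and adipocytes — with per-sample area fractions drawn
from a Dirichlet distribution and constrained to the observed ranges
(tumor and stroma 5-85%, adipocytes 0-50%).  The observed linear-scale
signal of gene g in sample i is

    signal = (t_i E_T + d s_i E_S + c a_i E_A) * 2^eps,   eps ~ N(0, sd^2)

where E_K are per-gene compartment expression levels (log-normal
baselines), c and d are the true adipocyte and stroma transcription
efficiencies, and the multiplicative log-normal noise models array and
biological variability.  Differentially expressed genes shift the
designated compartment's log2 mean by ``effect_log2`` in the DM group
(random sign).  Histopathology is reported as two noisy sections per
sample (truncated Gaussian noise on the true fractions, renormalized),
mimicking pathologist section-to-section variability.

Default parameters are the study conditions: 118 DM / 80 NoDM samples,
2000 gene-probes, Dirichlet(4, 3, 1) fractions, 5-percentage-point section
noise, log2 noise sd 1.0, true c = 0.2, true d = 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .weights import SampleAnnotation, SectionFractions
from .cohort_stats import ContingencyTable

ORIGINS = ("tumor", "stroma", "shared", "null")

# observed area-fraction ranges, percent
FRACTION_RANGES = {"tumor": (5.0, 85.0), "stroma": (5.0, 85.0), "adipocyte": (0.0, 50.0)}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort."""

    n_dm: int = 118
    n_nodm: int = 80
    n_genes: int = 2000
    n_de_tumor: int = 50
    n_de_stroma: int = 50
    n_de_shared: int = 50
    effect_log2: float = 2.0
    true_c: float = 0.2
    true_d: float = 1.0
    noise_sd_log2: float = 1.0
    fraction_alpha: Tuple[float, float, float] = (4.0, 3.0, 1.0)
    section_noise_sd: float = 5.0  # percentage points
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_de_tumor + self.n_de_stroma + self.n_de_shared > self.n_genes:
            raise ValueError("DE gene counts exceed n_genes")
        if min(self.n_dm, self.n_nodm) < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0.0 <= self.true_c <= 1.0 and 0.0 <= self.true_d <= 1.0):
            raise ValueError("true_c and true_d must lie in [0, 1]")
        for name in ("effect_log2", "noise_sd_log2", "section_noise_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort: per-gene origin, direction, effect."""

    frame: pd.DataFrame  # index gene id; columns origin, direction, effect_log2

    def genes_of_origin(self, origin: str) -> List[str]:
        if origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}")
        return list(self.frame.index[self.frame["origin"] == origin])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def _draw_fractions(rng: np.random.Generator, n: int, alpha) -> np.ndarray:
    """Dirichlet fractions (percent) clipped to the observed ranges and
    renormalized; iterate clip+renormalize until all rows comply."""
    lo = np.array([FRACTION_RANGES["tumor"][0], FRACTION_RANGES["stroma"][0], FRACTION_RANGES["adipocyte"][0]])
    hi = np.array([FRACTION_RANGES["tumor"][1], FRACTION_RANGES["stroma"][1], FRACTION_RANGES["adipocyte"][1]])
    f = rng.dirichlet(alpha, size=n) * 100.0
    for _ in range(200):
        f = np.clip(f, lo, hi)
        f = f / f.sum(axis=1, keepdims=True) * 100.0
        if ((f >= lo - 1e-9) & (f <= hi + 1e-9)).all():
            break
    return np.clip(f, lo, hi) / np.clip(f, lo, hi).sum(axis=1, keepdims=True) * 100.0


def _noisy_sections(rng: np.random.Generator, fractions: np.ndarray, sd: float) -> np.ndarray:
    """Two observed sections per sample: truncated Gaussian noise on the true
    fractions, clipped at zero and renormalized to 100."""
    n = fractions.shape[0]
    sections = fractions[:, None, :] + rng.normal(0.0, sd, size=(n, 2, 3))
    sections = np.clip(sections, 0.05, None)
    return sections / sections.sum(axis=2, keepdims=True) * 100.0


def generate_cohort(cfg: SimulationConfig) -> Tuple[ExpressionMatrix, List[SampleAnnotation], SyntheticTruth]:
    """Simulate a two-group cohort as a fraction-weighted compartment mixture.

    Returns the log2 expression matrix, per-sample annotations (two noisy
    sections each), and the ground-truth gene table.  The same seed
    reproduces identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_dm + cfg.n_nodm
    groups = np.array(["DM"] * cfg.n_dm + ["NoDM"] * cfg.n_nodm)
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    gene_ids = [f"G{i+1:04d}" for i in range(cfg.n_genes)]

    # gene origins: first tumor, then stroma, then shared, rest null
    origin = np.array(["null"] * cfg.n_genes, dtype=object)
    k = 0
    for name, cnt in (("tumor", cfg.n_de_tumor), ("stroma", cfg.n_de_stroma), ("shared", cfg.n_de_shared)):
        origin[k : k + cnt] = name
        k += cnt
    direction = np.where(origin == "null", "none", np.where(rng.random(cfg.n_genes) < 0.5, "up_in_DM", "up_in_NoDM"))
    effect = np.where(origin == "null", 0.0, cfg.effect_log2)
    signed = np.where(direction == "up_in_DM", 1.0, np.where(direction == "up_in_NoDM", -1.0, 0.0)) * effect

    # per-gene compartment baselines (log2)
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=(cfg.n_genes, 3))
    shift_t = np.where(np.isin(origin, ["tumor", "shared"]), signed, 0.0)
    shift_s = np.where(np.isin(origin, ["stroma", "shared"]), signed, 0.0)

    # linear compartment levels per group
    E = {}  # (compartment, group) -> (n_genes,)
    for gi, grp in enumerate(("DM", "NoDM")):
        dm = grp == "DM"
        E[("tumor", grp)] = 2.0 ** (base[:, 0] + (shift_t if dm else 0.0))
        E[("stroma", grp)] = 2.0 ** (base[:, 1] + (shift_s if dm else 0.0))
        E[("adipocyte", grp)] = 2.0 ** base[:, 2]

    fractions = _draw_fractions(rng, n, cfg.fraction_alpha) / 100.0  # true fractions in [0,1]
    X = np.empty((cfg.n_genes, n))
    for i in range(n):
        g = groups[i]
        mix = (
            fractions[i, 0] * E[("tumor", g)]
            + cfg.true_d * fractions[i, 1] * E[("stroma", g)]
            + cfg.true_c * fractions[i, 2] * E[("adipocyte", g)]
        )
        X[:, i] = np.log2(mix) + rng.normal(0.0, cfg.noise_sd_log2, size=cfg.n_genes)

    matrix = ExpressionMatrix(pd.DataFrame(X, index=gene_ids, columns=sample_ids), scale="log2")

    sections = _noisy_sections(rng, fractions * 100.0, cfg.section_noise_sd)
    annotations = [
        SampleAnnotation(
            sample_ids[i],
            groups[i],
            [SectionFractions(*sections[i, j]) for j in range(2)],
        )
        for i in range(n)
    ]
    truth = SyntheticTruth(
        pd.DataFrame(
            {"origin": origin, "direction": direction, "effect_log2": effect},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return matrix, annotations, truth


def generate_clinical_table(
    n_dm: int,
    n_nodm: int,
    association: float = 0.0,
    n_levels: int = 2,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, ContingencyTable]:
    """Simulate a categorical clinical covariate with tunable group association.

    ``association`` in [0, 1] interpolates between identical level
    probabilities in both groups (0) and a deterministic group-level link
    (1).  Returns the per-sample covariate table and the corresponding
    contingency table (groups x levels).
    """
    if not 0.0 <= association <= 1.0:
        raise ValueError("association must lie in [0, 1]")
    if n_levels < 2:
        raise ValueError("need at least 2 covariate levels")
    rng = np.random.default_rng(seed)
    levels = [f"L{j+1}" for j in range(n_levels)]
    uniform = np.full(n_levels, 1.0 / n_levels)
    peak_dm = np.zeros(n_levels)
    peak_dm[0] = 1.0
    peak_nodm = np.zeros(n_levels)
    peak_nodm[-1] = 1.0
    p_dm = (1 - association) * uniform + association * peak_dm
    p_nodm = (1 - association) * uniform + association * peak_nodm
    rows = []
    counts = np.zeros((2, n_levels), dtype=int)
    for gi, (grp, size, p) in enumerate((("DM", n_dm, p_dm), ("NoDM", n_nodm, p_nodm))):
        draw = rng.choice(n_levels, size=size, p=p)
        for i, lv in enumerate(draw):
            rows.append({"sample_id": f"{grp}{i+1:03d}", "group": grp, "covariate": levels[lv]})
            counts[gi, lv] += 1
    table = ContingencyTable(("DM", "NoDM"), tuple(levels), tuple(tuple(r) for r in counts))
    return pd.DataFrame(rows), table


@dataclass
class ConfusionSummary:
    """Recovery of the simulated truth by an ascription report."""

    frame: pd.DataFrame  # origins x categories counts
    tumor_sensitivity: float  # tumor-origin genes landing in tumor_ascribed/associated
    stroma_consensus_rate: float  # stroma-origin genes present in SACsev
    tumor_in_stroma_associated: int  # tumor-origin genes misascribed to stroma
    null_ascribed: int  # null genes receiving any non-"none" category


def truth_evaluation(report: pd.DataFrame, truth: SyntheticTruth) -> ConfusionSummary:
    """Cross-tabulate ascription categories against the simulated origins.

    ``report`` is the frame produced by :func:`cellascribe.ascription.categorize`;
    genes absent from the report (never significant) count as category
    ``none``.
    """
    unknown = set(report["probe_id"]) - set(truth.frame.index)
    if unknown:
        raise ValueError(f"report contains genes outside the truth universe: {sorted(unknown)[:5]}")
    cat = pd.Series("none", index=truth.frame.index, dtype=object)
    in_sacsev = pd.Series(False, index=truth.frame.index, dtype=bool)
    if len(report):
        cat.loc[list(report["probe_id"])] = list(report["category"])
        in_sacsev.loc[list(report["probe_id"])] = [bool(v) for v in report["in_SACsev"]]

    crosstab = pd.crosstab(truth.frame["origin"], cat)
    tumor_genes = truth.frame["origin"] == "tumor"
    stroma_genes = truth.frame["origin"] == "stroma"
    null_genes = truth.frame["origin"] == "null"
    n_tumor = int(tumor_genes.sum())
    n_stroma = int(stroma_genes.sum())
    tumor_hit = cat[tumor_genes].isin(["tumor_ascribed", "tumor_associated"]).sum()
    return ConfusionSummary(
        frame=crosstab,
        tumor_sensitivity=float(tumor_hit / n_tumor) if n_tumor else float("nan"),
        stroma_consensus_rate=float(in_sacsev[stroma_genes].mean()) if n_stroma else float("nan"),
        tumor_in_stroma_associated=int((cat[tumor_genes] == "stroma_associated").sum()),
        null_ascribed=int((cat[null_genes] != "none").sum()),
    )
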