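"""Raw-signal preprocessing: quality filtering, quantile normalization,
KNN imputation, and per-array rescale + log2 transform.

The pipeline order is: flag/S-N filtering at the measurement level,
probe-level missingness filtering, missing-aware quantile normalization,
KNN imputation, then per-array rescaling to sum 1 followed by log2.
Each step reports the number of probes/measurements it removed so a run
can be audited; `preprocess_pipeline` collects these into a JSON-ready
report.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

REQUIRED_LONG_COLUMNS = ("probe_id", "sample_id", "signal", "snr", "flagged")


def read_long_records(path) -> pd.DataFrame:
    """Read long-format raw records (probe_id, sample_id, signal, snr, flagged)."""
    records = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_LONG_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"long-format input lacks columns: {sorted(missing)}")
    records["flagged"] = records["flagged"].astype(bool)
    return records


def filter_low_quality(records: pd.DataFrame, snr_min: float = 3.0):
    """Drop flagged measurements; set signals with S/N below `snr_min` to missing.

    Returns ``(records, report)`` where `records` keeps one row per surviving
    (probe, sample) pair (low-S/N signals become NaN) and `report` counts what
    each rule touched.

    The S/N rule is applied per measurement: a low-S/N cell becomes missing
    rather than removing the probe outright; probe-level removal is then the
    job of :func:`filter_missingness`.
    """
    if snr_min <= 0:
        raise ValueError("snr_min must be positive")
    if len(records) == 0:
        raise ValueError("no records")
    dup = records.duplicated(subset=["probe_id", "sample_id"])
    if dup.any():
        raise ValueError("duplicate (probe_id, sample_id) pairs in raw records")

    flagged = records["flagged"].to_numpy(dtype=bool)
    out = records.loc[~flagged].copy()
    n_flag_removed = int(flagged.sum())
    if len(out) == 0:
        raise ValueError("no records survive")
    low_snr = out["snr"].to_numpy() < snr_min
    out.loc[low_snr, "signal"] = np.nan
    report = {
        "n_input": int(len(records)),
        "n_flagged_removed": n_flag_removed,
        "n_low_snr_set_missing": int(low_snr.sum()),
        "snr_min": float(snr_min),
    }
    logger.info(
        "quality filter: %d flagged removed, %d low-S/N set missing",
        report["n_flagged_removed"],
        report["n_low_snr_set_missing"],
    )
    return out, report


def records_to_matrix(records: pd.DataFrame) -> ExpressionMatrix:
    """Pivot long records to a wide linear-scale matrix (unseen cells = missing)."""
    wide = records.pivot(index="probe_id", columns="sample_id", values="signal")
    wide.index.name = None
    wide.columns.name = None
    return ExpressionMatrix(wide, scale="linear")


def filter_missingness(m: ExpressionMatrix, max_missing_frac: float = 0.80) -> ExpressionMatrix:
    """Drop probes missing in strictly more than `max_missing_frac` of samples."""
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in (0, 1]")
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = int((~keep).sum())
    if dropped:
        logger.info("missingness filter: dropped %d of %d probes", dropped, m.n_probes)
    return ExpressionMatrix(m.values.loc[keep], m.scale)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto a common (average) intensity distribution.

    Within each column, non-missing values are ranked and replaced by the
    cross-column mean quantile function evaluated at their rank positions;
    missing cells stay missing.  Ties receive the average of the reference
    values at their tied positions, so within-column ordering is preserved.
    Columns with differing numbers of non-missing values are aligned by
    rank interpolation on [0, 1].
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    counts = obs.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("a sample has no non-missing values")

    # reference quantile function: mean across columns of each column's
    # empirical quantile function, on a grid of n_probes points
    grid = np.linspace(0.0, 1.0, m.n_probes) if m.n_probes > 1 else np.array([0.5])
    ref = np.zeros_like(grid)
    for j in range(X.shape[1]):
        col = np.sort(X[obs[:, j], j])
        if col.size == 1:
            ref += col[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    ref /= X.shape[1]

    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        col = X[obs[:, j], j]
        n = col.size
        # average ranks handle ties; map rank r in 1..n to quantile (r-1)/(n-1)
        ranks = rankdata(col, method="average")
        pos = (ranks - 1.0) / (n - 1.0) if n > 1 else np.array([0.5])
        out[obs[:, j], j] = np.interp(pos, grid, ref)
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.scale)


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells with the mean of the k nearest probes.

    Distance between two probes is the Euclidean distance over the samples
    where both are observed (no missingness rescaling); a neighbor is usable
    for a given cell only if it is observed there.  A probe with no usable
    neighbor falls back to its own row mean with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if obs.all():
        return m.copy()
    X0 = np.where(obs, X, 0.0)
    out = X.copy()
    rows_with_missing = np.where(~obs.all(axis=1))[0]
    for i in rows_with_missing:
        shared = obs & obs[i]  # (n_probes, n_samples)
        d2 = (((X0 - X0[i]) ** 2) * shared).sum(axis=1)
        n_shared = shared.sum(axis=1)
        d2 = np.where(n_shared > 0, d2, np.inf)
        d2[i] = np.inf
        order = np.argsort(d2, kind="stable")
        for j in np.where(~obs[i])[0]:
            usable = order[np.isfinite(d2[order]) & obs[order, j]]
            if usable.size == 0:
                row = X[i, obs[i]]
                out[i, j] = row.mean() if row.size else np.nan
                warnings.warn(
                    f"probe {m.values.index[i]!r} has no usable neighbor for sample "
                    f"{m.values.columns[j]!r}; imputed with its row mean",
                    stacklevel=2,
                )
            else:
                out[i, j] = X[usable[:k], j].mean()
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.scale)


def rescale_and_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each array to sum 1, then log2-transform.

    Output value is log2(value / column_sum); requires a complete,
    strictly positive linear-scale matrix.
    """
    if m.scale != "linear":
        raise ValueError(f"rescale_and_log expects linear scale, got {m.scale}")
    X = m.values.to_numpy(dtype=float)
    bad = ~(X > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive or missing value at probe {m.values.index[i]!r}, "
            f"sample {m.values.columns[j]!r}"
        )
    props = X / X.sum(axis=0, keepdims=True)
    out = np.log2(props)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), scale="log2"
    )


def preprocess_pipeline(
    records: pd.DataFrame,
    snr_min: float = 3.0,
    max_missing_frac: float = 0.80,
    k: int = 10,
):
    """Run the full preprocessing chain on long-format raw records.

    Returns ``(matrix, report)``: the analysis-ready log2 matrix and a
    JSON-serializable report of counts removed at each step and the
    parameters used.
    """
    filtered, qreport = filter_low_quality(records, snr_min=snr_min)
    m = records_to_matrix(filtered)
    n0 = m.n_probes
    m = filter_missingness(m, max_missing_frac=max_missing_frac)
    n1 = m.n_probes
    m = quantile_normalize(m)
    m = knn_impute(m, k=k)
    m = rescale_and_log(m)
    report = {
        "quality_filter": qreport,
        "n_probes_before_missingness_filter": n0,
        "n_probes_after_missingness_filter": n1,
        "max_missing_frac": float(max_missing_frac),
        "knn_k": int(k),
        "n_samples": m.n_samples,
    }
    return m, report
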