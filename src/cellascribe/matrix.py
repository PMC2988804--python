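"""Probe-by-sample expression container.

The matrix is a thin wrapper around a pandas DataFrame (rows = probes,
columns = samples) that tracks what scale the values are on:

``linear``
    raw chemiluminescence-type signals, strictly positive where present;
``proportion``
    per-array signals rescaled so each column sums to one;
``log2``
    log2-transformed values, the analysis-ready scale.

Missing measurements are NaN cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VALID_SCALES = ("linear", "proportion", "log2")

_PROPORTION_TOL = 1e-9


class ExpressionMatrix:
    """Expression values for a set of probes across a set of samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes in rows (index = probe ids), samples in columns
        (columns = sample ids). NaN marks a missing measurement.
    scale : {"linear", "proportion", "log2"}
        Scale of the stored values.
    """

    def __init__(self, values: pd.DataFrame, scale: str = "linear"):
        if scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {scale!r}; expected one of {VALID_SCALES}")
        if values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = values.astype(float)
        if scale == "proportion":
            sums = values.sum(axis=0, skipna=True).to_numpy()
            if not np.allclose(sums, 1.0, atol=_PROPORTION_TOL, rtol=0.0):
                raise ValueError("proportion-scale columns must sum to 1")
        self.values = values
        self.scale = scale

    # -- basic introspection -------------------------------------------------

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the measurement is missing."""
        return self.values.isna()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ExpressionMatrix {self.n_probes} probes x {self.n_samples} samples, "
            f"scale={self.scale}, missing={self.n_missing()}>"
        )

    # -- convenience ---------------------------------------------------------

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.scale)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, scale: str = "linear") -> "ExpressionMatrix":
        """Read a wide matrix TSV: first column probe ids, header = sample ids,
        empty cells = missing."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame, scale)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="")
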