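"""Assumption grids, consensus DEG lists, and cell-type ascription.

Two grids of weighted analyses are run per focus (tumor / stroma):

* the c-series varies the adipocyte efficiency c over {0, 0.2, ..., 1}
  at d = 1, yielding the TACat / SACat consensus lists;
* the d-series fixes c = 0 and varies the stromal efficiency d over
  {0.2, 0.4, 0.6, 0.8, 1}, yielding the TACsev / SACsev consensus lists.

A consensus list is the direction-concordant intersection of the per-cell
DEG lists.  Each probe in the d-series universe is then categorized:

* ``tumor_ascribed``    — in TACsev and in no stroma-focused list at any d;
* ``tumor_associated``  — in TACsev, not in SACsev, but in at least one
  stroma-focused list;
* ``stroma_associated`` — in SACsev but not in TACsev;
* ``shared_robust``     — in both consensus lists;
* ``none``              — in neither consensus list.

The ``#tf`` / ``#sf`` appearance counts record in how many of the five
tumor-focused and stroma-focused d-series analyses a probe was identified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .weights import SampleAnnotation
from .weighted_test import DEGList, WeightedDifferentialExpression

logger = logging.getLogger(__name__)

C_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
D_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)
CATEGORIES = ("tumor_ascribed", "tumor_associated", "stroma_associated", "shared_robust", "none")

GridKey = Tuple[str, float, float]  # (focus, c, d)


@dataclass
class GridResult:
    """DEG lists for every cell of one assumption grid."""

    series: str  # "c_series" | "d_series"
    lists: Dict[GridKey, DEGList]

    def focus_lists(self, focus: str) -> List[DEGList]:
        return [lst for (f, _, _), lst in sorted(self.lists.items()) if f == focus]

    def sizes(self) -> Dict[str, int]:
        return {f"{f},c={c:g},d={d:g}": len(lst) for (f, c, d), lst in sorted(self.lists.items())}


def _derive_seeds(seed: Optional[int], n: int) -> List[Optional[int]]:
    """Deterministic per-cell permutation seeds from one master seed."""
    if seed is None:
        return [None] * n
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_grid(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    series: str = "d_series",
    B: int = 9999,
    level: float = 0.05,
    seed: Optional[int] = None,
) -> GridResult:
    """Run every (focus, parameter) analysis of a series.

    The d-series produces exactly five tumor-focused and five stroma-focused
    lists; the c-series six per focus.
    """
    if series == "c_series":
        cells = [(focus, c, 1.0) for focus in ("tumor", "stroma") for c in C_GRID]
    elif series == "d_series":
        cells = [(focus, 0.0, d) for focus in ("tumor", "stroma") for d in D_GRID]
    else:
        raise ValueError("series must be 'c_series' or 'd_series'")
    seeds = _derive_seeds(seed, len(cells))
    lists: Dict[GridKey, DEGList] = {}
    for (focus, c, d), cell_seed in zip(cells, seeds):
        model = WeightedDifferentialExpression(matrix, annotations, focus=focus, c=c, d=d)
        lists[(focus, c, d)] = model.fit(B=B, level=level, seed=cell_seed).deg_list()
    return GridResult(series, lists)


def consensus(lists: Iterable[DEGList]) -> Dict[str, str]:
    """Direction-concordant intersection of DEG lists (probe -> direction).

    A probe qualifies only if every list contains it with the same
    direction; direction-discordant probes are dropped with a warning.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("no DEG lists to intersect")
    common = set.intersection(*(lst.probes for lst in lists))
    out: Dict[str, str] = {}
    for probe in sorted(common):
        directions = {lst.members[probe] for lst in lists}
        if len(directions) == 1:
            out[probe] = directions.pop()
        else:
            logger.warning("probe %s has discordant directions across lists; dropped from consensus", probe)
    return out


def appearance_counts(probe: str, grid: GridResult, tested_probes: Optional[Set[str]] = None) -> Tuple[int, int]:
    """(#tf, #sf): how many tumor- and stroma-focused lists contain the probe."""
    if tested_probes is not None and probe not in tested_probes:
        raise KeyError(f"probe {probe!r} was not tested")
    tf = sum(probe in lst for lst in grid.focus_lists("tumor"))
    sf = sum(probe in lst for lst in grid.focus_lists("stroma"))
    return tf, sf


def categorize(grid: GridResult) -> pd.DataFrame:
    """Per-probe ascription report over the union of all d-series lists.

    Columns: probe_id, tf_count, sf_count, in_TACsev, in_SACsev, category,
    direction.  Categories partition the union of the two consensus lists;
    probes outside both get ``none``.
    """
    if grid.series != "d_series":
        raise ValueError("categorization is defined on the d-series grid")
    tumor_lists = grid.focus_lists("tumor")
    stroma_lists = grid.focus_lists("stroma")
    tacsev = consensus(tumor_lists)
    sacsev = consensus(stroma_lists)
    sfa_union: Set[str] = set().union(*(lst.probes for lst in stroma_lists))
    universe: Set[str] = set().union(*(lst.probes for lst in tumor_lists), sfa_union)

    rows = []
    for probe in sorted(universe):
        tf, sf = appearance_counts(probe, grid)
        in_tac = probe in tacsev
        in_sac = probe in sacsev
        if in_tac and in_sac:
            category = "shared_robust"
        elif in_tac and probe not in sfa_union:
            category = "tumor_ascribed"
        elif in_tac:
            category = "tumor_associated"
        elif in_sac:
            category = "stroma_associated"
        else:
            category = "none"
        direction = tacsev.get(probe) or sacsev.get(probe)
        if direction is None:
            directions = {
                lst.members[probe] for lst in tumor_lists + stroma_lists if probe in lst
            }
            direction = directions.pop() if len(directions) == 1 else "discordant"
        rows.append(
            {
                "probe_id": probe,
                "tf_count": tf,
                "sf_count": sf,
                "in_TACsev": in_tac,
                "in_SACsev": in_sac,
                "category": category,
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["probe_id", "tf_count", "sf_count", "in_TACsev", "in_SACsev", "category", "direction"],
    )


def compare_with_unweighted(grid: GridResult, uwa: DEGList) -> Dict[str, int]:
    """Venn-style overlap of UWA with the TACsev and SACsev consensus sets."""
    tac = set(consensus(grid.focus_lists("tumor")))
    sac = set(consensus(grid.focus_lists("stroma")))
    u = uwa.probes
    return {
        "UWA_only": len(u - tac - sac),
        "TACsev_only": len(tac - u - sac),
        "SACsev_only": len(sac - u - tac),
        "UWA_and_TACsev_only": len((u & tac) - sac),
        "UWA_and_SACsev_only": len((u & sac) - tac),
        "TACsev_and_SACsev_only": len((tac & sac) - u),
        "all_three": len(u & tac & sac),
        "weighted_not_in_UWA": len((tac | sac) - u),
    }


class AscriptionResults:
    """Results of a full ascription analysis: grid lists, consensus sets,
    per-probe report, and the comparison with the unweighted analysis."""

    def __init__(self, grid: GridResult, report: pd.DataFrame, uwa: Optional[DEGList]):
        self.grid = grid
        self.report = report
        self.uwa = uwa
        self.tacsev = consensus(grid.focus_lists("tumor"))
        self.sacsev = consensus(grid.focus_lists("stroma"))

    def category_counts(self) -> Dict[str, int]:
        counts = self.report["category"].value_counts().to_dict()
        return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}

    def venn(self) -> Optional[Dict[str, int]]:
        if self.uwa is None:
            return None
        return compare_with_unweighted(self.grid, self.uwa)

    def summary_dict(self) -> dict:
        out = {
            "series": self.grid.series,
            "list_sizes": self.grid.sizes(),
            "n_TACsev": len(self.tacsev),
            "n_SACsev": len(self.sacsev),
            "category_counts": self.category_counts(),
        }
        if self.uwa is not None:
            out["n_UWA"] = len(self.uwa)
            out["venn_with_UWA"] = self.venn()
        return out

    def summary(self) -> str:
        d = self.summary_dict()
        lines = [
            "Cell-type ascription of DM-vs-NoDM differential expression",
            "=" * 58,
            f"grid: {d['series']}",
            "DEG list sizes per cell:",
        ]
        for cell, size in d["list_sizes"].items():
            lines.append(f"  {cell:<28s} {size}")
        lines.append(f"TACsev consensus: {d['n_TACsev']}   SACsev consensus: {d['n_SACsev']}")
        if "n_UWA" in d:
            lines.append(f"UWA list: {d['n_UWA']}")
        lines.append("categories:")
        for cat, n in d["category_counts"].items():
            lines.append(f"  {cat:<18s} {n}")
        if d.get("venn_with_UWA"):
            lines.append("overlap with UWA:")
            for k, v in d["venn_with_UWA"].items():
                lines.append(f"  {k:<24s} {v}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.report.to_csv(path, sep="\t", index=False)

    def to_json_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


class AscriptionAnalysis:
    """Model wrapper: run the assumption grid(s) and categorize every DEG.

    ``fit`` runs the d-series grid (and, unless disabled, the unweighted
    analysis for the overlap comparison) and returns
    :class:`AscriptionResults`.
    """

    def __init__(self, matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]):
        self.matrix = matrix
        self.annotations = list(annotations)

    def fit(
        self,
        B: int = 9999,
        level: float = 0.05,
        seed: Optional[int] = None,
        include_unweighted: bool = True,
    ) -> AscriptionResults:
        grid = run_grid(self.matrix, self.annotations, "d_series", B=B, level=level, seed=seed)
        uwa = None
        if include_unweighted:
            uwa_seed = _derive_seeds(seed + 1 if seed is not None else None, 1)[0]
            model = WeightedDifferentialExpression(self.matrix, self.annotations, focus="unweighted")
            uwa = model.fit(B=B, level=level, seed=uwa_seed).deg_list()
        report = categorize(grid)
        return AscriptionResults(grid, report, uwa)
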