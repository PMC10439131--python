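"""Neighboring cell-type composition of the tumor core and leading edge.

For each of the TC and LE regions, the non-malignant spots directly in
contact (hexagonal adjacency) with at least one spot of the region are
collected, classified by their dominant non-cancer deconvolution
proportion, and counted per cell type.  A spot touching both regions
contributes to both counts.  Across a cohort, per-cell-type TC vs LE
counts are compared with a two-sided rank-sum test and a
Benjamini–Hochberg correction across cell types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, rank_sum_test
from .lattice import hex_neighbors, neighbor_table  # noqa: F401  (re-export)


def neighbor_composition(adata, regions=("TC", "LE")) -> pd.DataFrame:
    """Counts of non-malignant neighbor spots per (region, cell type).

    Requires ``obs['region']`` and ``obs['cell_type']`` (see
    :mod:`spatialedge.annotation`).  Returns a long-format DataFrame
    with one row per (region, cell_type), including zero counts for
    every non-cancer cell type of the deconvolution table.
    """
    lattice = adata.obs[["array_row", "array_col", "in_tissue"]].copy()
    adjacency = neighbor_table(lattice)
    region = adata.obs["region"]
    cell_type = adata.obs["cell_type"]
    malignant = adata.obs["malignant"]
    universe = [c for c in adata.obsm["deconv"].columns if c != "cancer"]
    rows = []
    for reg in regions:
        members = region.index[region == reg]
        touching: set[str] = set()
        for spot in members:
            touching.update(adjacency.get(spot, ()))
        touching = {s for s in touching if not malignant.get(s, False)}
        counts = cell_type.loc[sorted(touching)].value_counts()
        for ct in universe:
            rows.append(
                {"region": reg, "cell_type": ct, "count": int(counts.get(ct, 0))}
            )
    return pd.DataFrame(rows)


def compare_composition(
    counts: pd.DataFrame, region_a: str = "TC", region_b: str = "LE"
) -> pd.DataFrame:
    """Per-cell-type rank-sum comparison of neighbor counts across samples.

    ``counts`` is long-format with columns ``sample``, ``region``,
    ``cell_type``, ``count`` (concatenate :func:`neighbor_composition`
    outputs with a ``sample`` column).  Cell types with no neighbors in
    any sample are skipped with a warning.
    """
    required = {"sample", "region", "cell_type", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts needs columns {sorted(required)}")
    if counts["sample"].nunique() < 2:
        raise ValueError("need at least two samples")
    rows = []
    for ct, sub in counts.groupby("cell_type", observed=True):
        a = sub.loc[sub["region"] == region_a, "count"].to_numpy()
        b = sub.loc[sub["region"] == region_b, "count"].to_numpy()
        if a.sum() == 0 and b.sum() == 0:
            warnings.warn(f"cell type {ct!r} absent from all samples; skipped")
            continue
        stat, p = rank_sum_test(a, b)
        rows.append(
            {
                "cell_type": ct,
                "statistic": stat,
                "pval": p,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = benjamini_hochberg(out["pval"])
    return out
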