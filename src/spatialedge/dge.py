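"""Per-sample differential expression between regions, consensus
aggregation across a cohort, and region-by-sample correlation structure.

Per sample, each gene is tested with a two-sided Wilcoxon rank-sum test
on the normalized layer (Bonferroni-adjusted over the genes tested in
that sample) and called significant when |log2FC| > 0.25 and adjusted
p < 0.001.  The fold change convention is
log2((mean expm1(norm_A) + 1) / (mean expm1(norm_B) + 1)).  A gene
reaches the cross-sample consensus when it is significant with a
consistent direction in at least ``min_samples`` samples; its
cumulative log2FC sums those samples' fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bonferroni, rank_sum_matrix, rank_sum_test


def _norm_frame(adata) -> pd.DataFrame:
    return pd.DataFrame(
        np.asarray(adata.layers["norm"]),
        index=adata.obs_names,
        columns=adata.var_names,
    )


def de_table(
    adata,
    group_a: str = "TC",
    group_b: str = "LE",
    logfc_min: float = 0.25,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Differential expression of ``group_a`` vs ``group_b`` regions.

    Only genes detected in at least 3 spots of either group are tested;
    the Bonferroni factor is the number of genes tested.  Returns a
    per-gene DataFrame with ``log2fc``, ``pval``, ``padj``,
    ``direction`` ("A-up"/"B-up" spelled with the group names) and
    ``significant``.
    """
    region = adata.obs["region"]
    a_mask = (region == group_a).to_numpy()
    b_mask = (region == group_b).to_numpy()
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("each group needs at least 3 spots for the rank-sum test")
    norm = np.asarray(adata.layers["norm"])
    A, B = norm[a_mask], norm[b_mask]
    detected = ((A > 0).sum(axis=0) >= 3) | ((B > 0).sum(axis=0) >= 3)
    genes = np.asarray(adata.var_names)[detected]
    A, B = A[:, detected], B[:, detected]

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    if max(A.shape[0], B.shape[0]) <= 8:
        pvals = np.array(
            [rank_sum_test(A[:, j], B[:, j])[1] for j in range(A.shape[1])]
        )
    else:
        pvals = rank_sum_matrix(A, B)
    padj = bonferroni(pvals, m=len(genes))
    direction = np.where(log2fc > 0, f"{group_a}-up", f"{group_b}-up")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pval": pvals,
            "padj": padj,
            "direction": direction,
            "significant": (np.abs(log2fc) > logfc_min) & (padj < alpha),
        },
        index=pd.Index(genes, name="gene"),
    )
    out.attrs["groups"] = (group_a, group_b)
    return out


def consensus_genes(tables: list[pd.DataFrame], min_samples: int = 10) -> pd.DataFrame:
    """Aggregate per-sample DE tables into a consensus table.

    A gene qualifies when significant with the same direction in
    >= ``min_samples`` tables.  ``cumulative_log2fc`` sums the log2FC of
    exactly those qualifying samples; rows are ranked by support count
    then |cumulative log2FC|.
    """
    if not tables:
        raise ValueError("need at least one DE table")
    if min_samples > len(tables):
        raise ValueError("min_samples exceeds the number of samples")
    sig = pd.concat(
        [t.loc[t["significant"], ["log2fc", "direction"]] for t in tables],
        keys=range(len(tables)),
        names=["sample", "gene"],
    ).reset_index()
    if sig.empty:
        return pd.DataFrame(
            columns=["n_samples", "cumulative_log2fc", "direction"]
        ).rename_axis("gene")
    grouped = sig.groupby(["gene", "direction"], observed=True)["log2fc"].agg(
        ["count", "sum"]
    )
    rows = []
    for gene, sub in grouped.groupby(level="gene"):
        sub = sub.droplevel("gene")
        sub = sub[sub["count"] >= min_samples]
        if sub.empty:
            continue
        # if both directions somehow qualify, keep the better-supported one
        best = sub.sort_values(
            ["count", "sum"], key=lambda s: s.abs(), ascending=False
        ).iloc[0]
        rows.append(
            {
                "gene": gene,
                "n_samples": int(best["count"]),
                "cumulative_log2fc": float(best["sum"]),
                "direction": best.name,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_samples", "cumulative_log2fc", "direction"])
    out = out.set_index("gene")
    order = out.assign(_a=out["cumulative_log2fc"].abs()).sort_values(
        ["n_samples", "_a"], ascending=False
    )
    return out.loc[order.index]


def region_correlation_matrix(
    samples: list, regions=("TC", "LE"), sample_names: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations of region-mean expression profiles.

    Rows/columns are (sample, region) pairs; each profile is the mean
    normalized expression vector of that region in that sample.
    """
    profiles, labels = [], []
    for i, adata in enumerate(samples):
        name = (
            sample_names[i]
            if sample_names
            else adata.uns.get("sample_id", f"sample_{i+1:02d}")
        )
        norm = _norm_frame(adata)
        for reg in regions:
            mask = (adata.obs["region"] == reg).to_numpy()
            if not mask.any():
                raise ValueError(f"{name} has no {reg} spots")
            profiles.append(norm[mask].mean(axis=0).to_numpy())
            labels.append((name, reg))
    mat = np.vstack(profiles)
    if np.any(mat.std(axis=1) == 0):
        raise ValueError("zero-variance expression profile")
    corr = np.corrcoef(mat)
    idx = pd.MultiIndex.from_tuples(labels, names=["sample", "region"])
    return pd.DataFrame(corr, index=idx, columns=idx)
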