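"""Gene-set scoring: control-bin module scores, signed up/down composite
scores, and rank-based single-sample scores, plus region comparisons.

The module score follows the expression-bin control scheme: signature
genes are binned with all genes by mean expression, control genes are
drawn (with replacement, seeded) from the matching bins, and the score
is the mean signature expression minus the mean control expression per
spot.  The rank score is a single-sample statistic in [-0.5, +0.5]
normalizing the mean midrank of the set between its theoretical
extremes, so it is invariant under monotone transforms of expression.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, bonferroni, rank_sum_test


def _as_frame(data, layer: str = "norm") -> pd.DataFrame:
    """Accept a spots x genes DataFrame or an AnnData with a norm layer."""
    if isinstance(data, pd.DataFrame):
        return data
    import anndata as ad

    if isinstance(data, ad.AnnData):
        mat = data.layers[layer] if layer in data.layers else data.X
        return pd.DataFrame(
            np.asarray(mat), index=data.obs_names, columns=data.var_names
        )
    raise TypeError("expected DataFrame or AnnData")


def _resolve_set(genes: Iterable[str], universe: pd.Index, label: str) -> list[str]:
    requested = list(genes)
    present = [g for g in requested if g in universe]
    missing = len(requested) - len(present)
    if missing:
        warnings.warn(f"{missing} gene(s) of {label} not measured; dropped")
    return present


def module_score(
    data,
    gene_set: Iterable[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-spot control-bin module score of ``gene_set``.

    Genes are cut into ``n_bins`` equal-frequency bins of mean
    expression; each signature gene contributes ``n_ctrl`` control genes
    sampled with replacement from its bin.
    """
    X = _as_frame(data)
    genes = _resolve_set(gene_set, X.columns, "gene_set")
    if not genes:
        raise ValueError("gene set empty after filtering to measured genes")
    mean_expr = X.mean(axis=0)
    n_bins = min(n_bins, X.shape[1])
    bins = pd.qcut(mean_expr.rank(method="first"), n_bins, labels=False)
    rng = np.random.default_rng(seed)
    by_bin = {
        b: np.asarray(idx) for b, idx in X.columns.groupby(bins.to_numpy()).items()
    }
    controls: list[np.ndarray] = []
    for g in genes:
        pool = by_bin[bins[g]]
        controls.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(controls)
    score = X[genes].mean(axis=1) - X[ctrl].mean(axis=1)
    score.name = "module_score"
    return score


def signed_score(
    data,
    up_set: Iterable[str],
    down_set: Iterable[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Signed composite score: module score of the up-regulated set minus
    module score of the down-regulated set (either may be empty)."""
    up, down = list(up_set), list(down_set)
    if not up and not down:
        raise ValueError("up_set and down_set are both empty")
    X = _as_frame(data)
    zero = pd.Series(0.0, index=X.index)
    s_up = module_score(X, up, n_bins, n_ctrl, seed) if up else zero
    s_down = module_score(X, down, n_bins, n_ctrl, seed) if down else zero
    out = s_up - s_down
    out.name = "signed_score"
    return out


def rank_score(expression: pd.Series, gene_set: Iterable[str]) -> float:
    """Single-sample rank score of ``gene_set`` in one expression vector.

    Genes are midranked ascending; the mean rank of the set is mapped
    linearly onto [-0.5, +0.5] between the minimal and maximal mean
    ranks achievable by a set of that size.
    """
    expression = pd.Series(expression)
    n = expression.size
    requested = list(gene_set)
    if len(requested) > n:
        raise ValueError("gene set larger than the transcriptome")
    genes = _resolve_set(requested, expression.index, "gene_set")
    if not genes:
        raise ValueError("gene set empty after filtering")
    k = len(genes)
    if k == n:
        return 0.0  # the whole transcriptome always has the central mean rank
    ranks = pd.Series(stats.rankdata(expression.to_numpy()), index=expression.index)
    mean_rank = float(ranks[genes].mean())
    mu_min = (k + 1) / 2.0
    mu_max = (2 * n - k + 1) / 2.0
    return (mean_rank - mu_min) / (mu_max - mu_min) - 0.5


def rank_score_frame(expression: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Vectorized :func:`rank_score` over the rows (samples) of a
    samples x genes matrix."""
    n = expression.shape[1]
    requested = list(gene_set)
    if len(requested) > n:
        raise ValueError("gene set larger than the transcriptome")
    genes = _resolve_set(requested, expression.columns, "gene_set")
    if not genes:
        raise ValueError("gene set empty after filtering")
    k = len(genes)
    if k == n:
        return pd.Series(0.0, index=expression.index, name="rank_score")
    ranks = stats.rankdata(expression.to_numpy(), axis=1)
    cols = expression.columns.get_indexer(genes)
    mean_rank = ranks[:, cols].mean(axis=1)
    mu_min = (k + 1) / 2.0
    mu_max = (2 * n - k + 1) / 2.0
    return pd.Series(
        (mean_rank - mu_min) / (mu_max - mu_min) - 0.5,
        index=expression.index,
        name="rank_score",
    )


def compare_region_scores(
    scores: pd.DataFrame,
    *,
    paired_by_sample: bool = False,
    correction: str = "bonferroni",
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Compare a per-spot score between regions.

    ``scores`` is long-format with columns ``score``, ``region`` and (for
    paired mode) ``sample``.  Paired mode reduces to per-sample region
    means and applies the signed-rank test across matched samples;
    unpaired mode applies the rank-sum test to spot-level scores.
    P-values are adjusted across region pairs with Bonferroni or
    Benjamini–Hochberg.
    """
    required = {"score", "region"} | ({"sample"} if paired_by_sample else set())
    if not required.issubset(scores.columns):
        raise ValueError(f"scores needs columns {sorted(required)}")
    regs = list(regions) if regions else sorted(scores["region"].unique())
    if len(regs) < 2:
        raise ValueError("need at least two regions")
    rows = []
    for i in range(len(regs)):
        for j in range(i + 1, len(regs)):
            a, b = regs[i], regs[j]
            if paired_by_sample:
                wide = (
                    scores[scores["region"].isin([a, b])]
                    .groupby(["sample", "region"], observed=True)["score"]
                    .mean()
                    .unstack("region")
                )
                if wide[[a, b]].isna().any().any():
                    raise ValueError(f"paired mode: samples missing region {a} or {b}")
                diff = wide[a] - wide[b]
                if np.allclose(diff, 0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.wilcoxon(wide[a], wide[b])
            else:
                xa = scores.loc[scores["region"] == a, "score"]
                xb = scores.loc[scores["region"] == b, "score"]
                stat, p = rank_sum_test(xa, xb)
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "pval": p})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["padj"] = bonferroni(out["pval"])
    elif correction in ("BH", "bh", "fdr_bh"):
        out["padj"] = benjamini_hochberg(out["pval"])
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out
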