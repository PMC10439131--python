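"""Malignant spot calling and tumor core / transitory / leading edge
annotation.

The malignancy rule combines three channels: a spot is called malignant
iff its cancer deconvolution proportion exceeds the threshold OR its
CNV ("mutant versus normal") probability exceeds the threshold, AND the
pathologist label marks the spot as squamous cell carcinoma.  Malignant
spots are then clustered on a shared-nearest-neighbor graph in PC space
and the clusters are cut into three nodal groups on an average-linkage
tree; the group with the highest mean tumor-core marker expression
(CLDN4/SPRR1B by default) becomes TC, the highest leading-edge marker
expression (LAMC2/ITGA5) becomes LE, and the remainder transitory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

TUMOR_REGIONS = ("TC", "transitory", "LE")


@dataclass
class RegionAnnotation:
    """Result of the three-state annotation of malignant spots."""

    nodal_group: pd.Series        # per malignant spot, in {1, 2, 3}
    region: pd.Series             # per malignant spot
    group_of_cluster: dict        # cluster id -> nodal group
    marker_scores: pd.DataFrame   # nodal group x {core, edge} mean marker expression


def normalize_counts(adata: ad.AnnData, min_features: int = 200) -> ad.AnnData:
    """Filter low-complexity spots and add a log-normalized layer.

    Spots detecting fewer than ``min_features`` genes are removed; the
    remaining counts are scaled to the median library size and
    log1p-transformed into ``layers['norm']``.
    """
    counts = np.asarray(adata.X)
    detected = (counts > 0).sum(axis=1)
    keep = detected >= min_features
    if not keep.any():
        raise ValueError("all spots filtered out by the feature threshold")
    out = adata[keep].copy()
    counts = np.asarray(out.X, dtype=float)
    libsize = counts.sum(axis=1)
    scale = libsize / np.median(libsize)
    out.layers["norm"] = np.log1p(counts / scale[:, None])
    return out


def call_malignant(adata: ad.AnnData, threshold: float = 0.99) -> pd.Series:
    """Dual-probability malignancy call with a pathology gate.

    malignant <=> (deconv_cancer > threshold OR p_cnv > threshold)
    AND pathology == "SCC"; both inequalities strict.  Writes and
    returns ``obs['malignant']``.
    """
    if "deconv" not in adata.obsm:
        raise KeyError("obsm['deconv'] missing")
    deconv = adata.obsm["deconv"]
    if "cancer" not in deconv.columns:
        raise KeyError("deconvolution has no 'cancer' column")
    if "p_cnv" not in adata.obs or "pathology" not in adata.obs:
        raise KeyError("obs needs 'p_cnv' and 'pathology'")
    prob_ok = (deconv["cancer"].to_numpy() > threshold) | (
        adata.obs["p_cnv"].to_numpy() > threshold
    )
    malignant = prob_ok & (adata.obs["pathology"].to_numpy() == "SCC")
    adata.obs["malignant"] = malignant
    return adata.obs["malignant"]


def assign_noncancer_type(adata: ad.AnnData) -> pd.Series:
    """Type each non-malignant spot by its largest non-cancer
    deconvolution proportion (ties broken by column order); malignant
    spots are typed "cancer".  Writes and returns ``obs['cell_type']``.
    """
    if "malignant" not in adata.obs:
        raise KeyError("run call_malignant first")
    deconv = adata.obsm["deconv"]
    noncancer = deconv[[c for c in deconv.columns if c != "cancer"]]
    # idxmax takes the first column on exact ties, i.e. declared order
    best = noncancer.idxmax(axis=1)
    cell_type = np.where(adata.obs["malignant"], "cancer", best)
    adata.obs["cell_type"] = cell_type
    return adata.obs["cell_type"]


def _snn_graph(pcs: np.ndarray, k: int, prune: float = 1 / 15) -> sparse.csr_matrix:
    """Seurat-style shared-nearest-neighbor graph: Jaccard overlap of
    k-NN sets (self included), edges below ``prune`` dropped."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(pcs)
    idx = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), idx.shape[1] + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    member = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    shared = (member @ member.T).tocoo()
    kk = idx.shape[1] + 1
    jacc = shared.data / (2 * kk - shared.data)
    keep = (jacc >= prune) & (shared.row != shared.col)
    return sparse.csr_matrix(
        (jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def cluster_malignant(
    adata: ad.AnnData,
    resolution: float = 1.0,
    n_pcs: int = 30,
    k: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Graph-based clustering of malignant spots.

    PCA of the normalized layer, SNN graph over ``k`` neighbors, and
    Leiden community detection at the given resolution (seeded, hence
    deterministic).  Writes ``obs['cluster']`` (NaN on non-malignant
    spots) and caches the malignant PC embedding in
    ``uns['malignant_pca']`` for the region annotation step.
    """
    mask = adata.obs["malignant"].to_numpy()
    n_mal = int(mask.sum())
    if n_mal < 2:
        raise ValueError("need at least two malignant spots")
    X = np.asarray(adata.layers["norm"])[mask]
    n_comp = min(n_pcs, n_mal - 1, X.shape[1])
    if n_comp < n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n_comp}")
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    pcs = pca.fit_transform(X)
    if np.allclose(pcs, pcs[0]):
        # degenerate: all spots identical in PC space -> one community
        cluster = pd.Series(pd.NA, index=adata.obs_names, dtype="object")
        cluster.iloc[np.flatnonzero(mask)] = "0"
        adata.obs["cluster"] = cluster
        adata.uns["malignant_pca"] = {
            "spot_ids": np.asarray(adata.obs_names[mask]),
            "X": pcs,
        }
        return adata.obs["cluster"]
    snn = _snn_graph(pcs, k=k)
    coo = sparse.triu(snn, k=1).tocoo()
    graph = igraph.Graph(
        n=n_mal,
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    cluster = pd.Series(pd.NA, index=adata.obs_names, dtype="object")
    cluster.iloc[np.flatnonzero(mask)] = [str(c) for c in labels]
    adata.obs["cluster"] = cluster
    adata.uns["malignant_pca"] = {
        "spot_ids": np.asarray(adata.obs_names[mask]),
        "X": pcs,
    }
    return adata.obs["cluster"]


def annotate_regions(
    adata: ad.AnnData,
    core_markers: Sequence[str] = ("CLDN4", "SPRR1B"),
    edge_markers: Sequence[str] = ("LAMC2", "ITGA5"),
) -> RegionAnnotation:
    """Cut the cluster tree into three nodal groups and label them.

    An average-linkage tree over cluster-mean PC embeddings is cut to
    three groups; marker scores are the mean normalized expression of
    each marker set over the spots of a group.  The group maximizing
    the core score becomes TC, the edge score LE, the remainder
    transitory.  Ambiguous or conflicting maxima raise.  Writes
    ``obs['region']`` ("non-malignant" outside the tumor).
    """
    if "cluster" not in adata.obs or "malignant_pca" not in adata.uns:
        raise KeyError("run cluster_malignant first")
    mask = adata.obs["malignant"].to_numpy()
    clusters = adata.obs["cluster"][mask].astype(str)
    ids = sorted(clusters.unique(), key=str)
    if len(ids) < 3:
        raise ValueError(f"need >= 3 clusters to cut into 3 nodal groups, got {len(ids)}")
    pcs = adata.uns["malignant_pca"]["X"]
    means = np.vstack([pcs[(clusters == c).to_numpy()].mean(axis=0) for c in ids])
    tree = linkage(means, method="average", metric="euclidean")
    groups = fcluster(tree, t=3, criterion="maxclust")
    group_of_cluster = dict(zip(ids, groups.tolist()))
    nodal = clusters.map(group_of_cluster)

    norm = pd.DataFrame(
        np.asarray(adata.layers["norm"])[mask],
        index=adata.obs_names[mask],
        columns=adata.var_names,
    )
    score = {}
    for name, markers in (("core", core_markers), ("edge", edge_markers)):
        present = [g for g in markers if g in norm.columns]
        if len(present) < len(list(markers)):
            warnings.warn(f"{name} markers missing from the matrix: using {present}")
        if not present:
            raise ValueError(f"no {name} markers measured")
        score[name] = norm[present].mean(axis=1).groupby(nodal).mean()
    marker_scores = pd.DataFrame(score).sort_index()
    for col in marker_scores:
        vals = marker_scores[col].to_numpy()
        top = np.max(vals)
        if (vals >= top - 1e-12).sum() > 1:
            raise ValueError(f"{col} marker score does not single out one group")
    tc_group = int(marker_scores["core"].idxmax())
    le_group = int(marker_scores["edge"].idxmax())
    if tc_group == le_group:
        raise ValueError("same nodal group maximizes core and edge markers")
    label_of_group = {
        g: ("TC" if g == tc_group else "LE" if g == le_group else "transitory")
        for g in marker_scores.index
    }
    region_mal = nodal.map(label_of_group)
    region = pd.Series("non-malignant", index=adata.obs_names, dtype="object")
    region[region_mal.index] = region_mal
    adata.obs["region"] = region
    return RegionAnnotation(
        nodal_group=nodal,
        region=region_mal,
        group_of_cluster=group_of_cluster,
        marker_scores=marker_scores,
    )


def annotate_sample(
    adata: ad.AnnData,
    *,
    min_features: int = 200,
    threshold: float = 0.99,
    resolution: float = 1.0,
    n_pcs: int = 30,
    k: int = 20,
    seed: int = 0,
    core_markers: Sequence[str] = ("CLDN4", "SPRR1B"),
    edge_markers: Sequence[str] = ("LAMC2", "ITGA5"),
) -> ad.AnnData:
    """Full per-sample annotation pipeline: normalize, call malignancy,
    type non-cancer spots, cluster, and assign TC/transitory/LE."""
    out = normalize_counts(adata, min_features=min_features)
    call_malignant(out, threshold=threshold)
    assign_noncancer_type(out)
    cluster_malignant(out, resolution=resolution, n_pcs=n_pcs, k=k, seed=seed)
    annotate_regions(out, core_markers=core_markers, edge_markers=edge_markers)
    return out
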