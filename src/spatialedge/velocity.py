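"""Steady-state RNA velocity, vector fields, fate-transition state
graphs, and in-silico target perturbation.

Model summary.  Spliced (s) and unspliced (u) counts are library-size
normalized and smoothed over k nearest neighbors in a PCA embedding of
the log spliced layer (moment smoothing).  Under the steady-state model
the degradation/splicing ratio of a gene is the slope of u on s through
the origin fitted on the extreme quantiles of s, and the velocity is
v = u - gamma_hat * s.  Velocities are projected into the embedding
through the PCA loadings (with the log-transform chain rule), smoothed
by a radial-basis-function kernel-ridge vector field, and converted to
a spot-to-spot Markov transition matrix by a cosine-softmax kernel over
embedding neighbors.  Averaging transition mass over the
TC/transitory/LE annotation yields a 3x3 row-stochastic state graph
whose "edge outgoing" signature is Q[LE->transitory] + Q[LE->TC] and
"core incoming" signature Q[LE->TC] + Q[transitory->TC].

In-silico perturbation overrides the velocity column of each target
gene with (M / 200) standard deviations of its smoothed spliced
expression per unit time (M = -200 down-regulation, +200 up-regulation,
-1000 for the checkpoint-gene variant), re-projects, refits the vector
field, and rebuilds the state graph.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

STATES = ("TC", "transitory", "LE")
MAGNITUDE_SCALE = 200.0  # |M| = 200 <=> one SD of the target per unit time


@dataclass
class VelocityResult:
    """Velocity layers and embedding for one set of spots."""

    spot_ids: np.ndarray
    genes: np.ndarray
    gamma: pd.Series                 # per-gene ratio estimate (NaN = masked)
    ms: np.ndarray                   # smoothed normalized spliced
    mu: np.ndarray                   # smoothed normalized unspliced
    velocity: np.ndarray             # spots x genes
    embedding: np.ndarray            # spots x d
    loadings: np.ndarray             # genes x d
    embedded_velocity: np.ndarray    # spots x d
    neighbors: np.ndarray            # spots x k smoothing neighbors
    confidence: pd.Series | None = None


@dataclass(frozen=True)
class PerturbationSpec:
    """Signed velocity overrides: gene -> magnitude M (screen units,
    +/-200 by default; -1000 for checkpoint genes)."""

    targets: Mapping[str, float]

    @classmethod
    def from_directions(
        cls, directions: Mapping[str, str], magnitude: float = 200.0
    ) -> "PerturbationSpec":
        signed = {}
        for gene, d in directions.items():
            if d == "up":
                signed[gene] = abs(magnitude)
            elif d == "down":
                signed[gene] = -abs(magnitude)
            else:
                raise ValueError(f"direction of {gene} must be 'up' or 'down'")
        return cls(targets=signed)


@dataclass
class StateGraph:
    """Coarse-grained fate-transition matrix over TC/transitory/LE."""

    Q: pd.DataFrame

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.Q.index)

    @property
    def edge_outgoing(self) -> float:
        return float(self.Q.loc["LE", "transitory"] + self.Q.loc["LE", "TC"])

    @property
    def core_incoming(self) -> float:
        return float(self.Q.loc["LE", "TC"] + self.Q.loc["transitory", "TC"])

    def to_dict(self) -> dict:
        return {
            "states": list(self.Q.index),
            "Q": self.Q.to_numpy().tolist(),
            "edge_outgoing": self.edge_outgoing,
            "core_incoming": self.core_incoming,
        }


# ---------------------------------------------------------------------------
# moments and the steady-state estimator

def moment_smoothing(
    values: np.ndarray, embedding: np.ndarray, k: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """First-order moments: mean of ``values`` over each spot's k
    nearest embedding neighbors (self included).  Returns the smoothed
    matrix and the neighbor index array."""
    n = embedding.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    idx = np.concatenate([np.arange(n)[:, None], idx], axis=1)
    return values[idx].mean(axis=1), idx


def estimate_gamma(
    ms: np.ndarray, mu: np.ndarray, extreme_quantile: float = 0.05
) -> np.ndarray:
    """Per-gene steady-state ratio: regression of u on s through the
    origin restricted to the top and bottom ``extreme_quantile`` of s.

    Genes whose spliced signal is identically zero are masked (NaN).
    """
    if ms.shape != mu.shape:
        raise ValueError("spliced/unspliced shape mismatch")
    n, g = ms.shape
    lo = np.quantile(ms, extreme_quantile, axis=0)
    hi = np.quantile(ms, 1 - extreme_quantile, axis=0)
    mask = (ms <= lo[None, :]) | (ms >= hi[None, :])
    s2 = np.where(mask, ms, 0.0)
    num = (s2 * mu).sum(axis=0)
    den = (s2 * ms).sum(axis=0)
    gamma = np.full(g, np.nan)
    ok = den > 0
    gamma[ok] = np.maximum(num[ok] / den[ok], 0.0)
    return gamma


def compute_velocity(
    adata,
    n_pcs: int = 10,
    n_neighbors: int = 30,
    extreme_quantile: float = 0.05,
    subset: str | None = "malignant",
) -> VelocityResult:
    """Full steady-state velocity pipeline on (by default) the malignant
    spots of an annotated sample.

    Normalizes the spliced/unspliced layers to their median library
    sizes, embeds log1p spliced counts with PCA, smooths both layers
    over embedding neighbors, estimates per-gene ratios, forms
    v = mu - gamma_hat * ms and projects it into the embedding.
    """
    if subset is not None and subset in adata.obs:
        adata = adata[adata.obs[subset].astype(bool)]
    s = np.asarray(adata.layers["spliced"], dtype=float)
    u = np.asarray(adata.layers["unspliced"], dtype=float)
    if s.shape != u.shape:
        raise ValueError("layer shape mismatch")
    s_norm = _libsize_normalize(s)
    u_norm = _libsize_normalize(u)
    logs = np.log1p(s_norm)
    n_comp = min(n_pcs, s.shape[0] - 1, s.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    embedding = pca.fit_transform(logs)
    loadings = pca.components_.T  # genes x d
    ms, idx = moment_smoothing(s_norm, embedding, k=n_neighbors)
    mu = u_norm[idx].mean(axis=1)
    gamma = estimate_gamma(ms, mu, extreme_quantile=extreme_quantile)
    gamma_filled = np.where(np.isnan(gamma), 0.0, gamma)
    velocity = mu - gamma_filled[None, :] * ms
    velocity[:, np.isnan(gamma)] = 0.0
    embedded = _project_velocity(velocity, ms, loadings)
    return VelocityResult(
        spot_ids=np.asarray(adata.obs_names),
        genes=np.asarray(adata.var_names),
        gamma=pd.Series(gamma, index=adata.var_names, name="gamma"),
        ms=ms,
        mu=mu,
        velocity=velocity,
        embedding=embedding,
        loadings=loadings,
        embedded_velocity=embedded,
        neighbors=idx,
    )


def _libsize_normalize(x: np.ndarray) -> np.ndarray:
    lib = x.sum(axis=1)
    lib = np.where(lib == 0, 1.0, lib)
    return x / (lib / np.median(lib))[:, None]


def _project_velocity(
    velocity: np.ndarray, ms: np.ndarray, loadings: np.ndarray
) -> np.ndarray:
    """Project gene-space velocities through the PCA loadings of the
    log1p embedding (chain rule d log1p(s)/dt = v / (1 + s))."""
    return (velocity / (1.0 + ms)) @ loadings


def velocity_confidence(result: VelocityResult, k: int = 30) -> pd.Series:
    """Correlation between each spot's velocity vector and the mean
    velocity of its k embedding neighbors; zero-variance vectors get
    confidence 0 with a warning."""
    n = result.embedding.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 spots")
    nn = NearestNeighbors(n_neighbors=k).fit(result.embedding)
    idx = nn.kneighbors(return_distance=False)
    v = result.velocity
    vbar = v[idx].mean(axis=1)
    conf = _rowwise_pearson(v, vbar)
    bad = np.isnan(conf)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} spot(s) with zero-variance velocity")
        conf[bad] = 0.0
    out = pd.Series(conf, index=result.spot_ids, name="velocity_confidence")
    result.confidence = out
    return out


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=1) / denom


# ---------------------------------------------------------------------------
# vector field

@dataclass
class VectorField:
    """RBF kernel-ridge map from embedding points to velocity vectors,
    fit around the mean velocity (so infinite ridge shrinks to it)."""

    centers: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    bandwidth: float
    ridge: float
    train_r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        K = _rbf_kernel(np.atleast_2d(x), self.centers, self.bandwidth)
        return self.intercept[None, :] + K @ self.coef


def _rbf_kernel(a: np.ndarray, b: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = (
        (a**2).sum(axis=1)[:, None]
        + (b**2).sum(axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * bandwidth**2))


def _median_bandwidth(x: np.ndarray) -> float:
    n = x.shape[0]
    take = min(n, 500)
    sub = x[np.linspace(0, n - 1, take).astype(int)]
    d2 = (
        (sub**2).sum(axis=1)[:, None]
        + (sub**2).sum(axis=1)[None, :]
        - 2.0 * sub @ sub.T
    )
    med = np.median(np.sqrt(np.maximum(d2[np.triu_indices(take, 1)], 0.0)))
    return float(med) if med > 0 else 1.0


def fit_vector_field(
    embedding: np.ndarray,
    embedded_velocity: np.ndarray,
    bandwidth: float | None = None,
    ridge: float = 1e-4,
) -> VectorField:
    """Fit the kernel-ridge vector field min sum ||f(x_i) - v_i||^2 +
    ridge * ||f||^2; reports the training R^2."""
    x = np.asarray(embedding, dtype=float)
    v = np.asarray(embedded_velocity, dtype=float)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more spots than embedding dimensions")
    bw = bandwidth if bandwidth is not None else _median_bandwidth(x)
    intercept = v.mean(axis=0)
    resid = v - intercept
    K = _rbf_kernel(x, x, bw)
    A = K + ridge * np.eye(x.shape[0])
    try:
        c = cho_factor(A)
        coef = cho_solve(c, resid)
    except np.linalg.LinAlgError:
        warnings.warn("singular kernel system; increasing ridge 100x")
        c = cho_factor(K + 100 * max(ridge, 1e-8) * np.eye(x.shape[0]))
        coef = cho_solve(c, resid)
    fitted = intercept[None, :] + K @ coef
    ss_res = ((v - fitted) ** 2).sum()
    ss_tot = ((v - v.mean(axis=0)) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return VectorField(
        centers=x, coef=coef, intercept=intercept, bandwidth=bw, ridge=ridge,
        train_r2=float(r2),
    )


# ---------------------------------------------------------------------------
# perturbation

def apply_perturbation(
    result: VelocityResult, spec: PerturbationSpec
) -> VelocityResult:
    """Override target-gene velocities and re-project.

    Each target's velocity column becomes (M / 200) * SD(smoothed
    spliced of the gene) at every spot; targets with zero expression are
    dropped (error when all are).  Returns a new VelocityResult sharing
    the embedding.
    """
    gene_index = {g: j for j, g in enumerate(result.genes)}
    v2 = result.velocity.copy()
    applied = 0
    for gene, m in spec.targets.items():
        if m == 0:  # zero magnitude = no perturbation
            applied += 1
            continue
        j = gene_index.get(gene)
        if j is None:
            warnings.warn(f"target {gene!r} not measured; dropped")
            continue
        sd = float(result.ms[:, j].std())
        if result.ms[:, j].max() <= 0 or sd == 0:
            warnings.warn(f"target {gene!r} has zero expression; dropped")
            continue
        v2[:, j] = (m / MAGNITUDE_SCALE) * sd
        applied += 1
    if spec.targets and applied == 0:
        raise ValueError("no perturbation target with nonzero expression")
    embedded = _project_velocity(v2, result.ms, result.loadings)
    return dataclasses.replace(result, velocity=v2, embedded_velocity=embedded)


# ---------------------------------------------------------------------------
# transition matrix and state graph

def build_transition_matrix(
    embedding: np.ndarray,
    embedded_velocity: np.ndarray,
    k: int = 30,
    sigma: float = 0.1,
) -> sparse.csr_matrix:
    """Velocity-directed spot-to-spot Markov matrix.

    For each spot i and its k nearest embedding neighbors j,
    P_ij  propto  exp(cos angle(v_i, x_j - x_i) / sigma), rows
    normalized; spots with (numerically) zero velocity distribute
    uniformly over their neighbors.  No self loops.
    """
    x = np.asarray(embedding, dtype=float)
    v = np.asarray(embedded_velocity, dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of spots")
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    idx = nn.kneighbors(return_distance=False)
    delta = x[idx] - x[:, None, :]            # n x k x d
    dn = np.linalg.norm(delta, axis=2)
    vn = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("nkd,nd->nk", delta, v) / (dn * vn[:, None])
    cos = np.where(np.isfinite(cos), cos, 0.0)
    logits = cos / sigma
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    zero_v = vn <= 1e-12
    w[zero_v] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(n), k)
    return sparse.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))


def coarse_state_graph(P, labels, states: Sequence[str] = STATES) -> StateGraph:
    """Average spot-level transition mass into a state-level matrix.

    Q[A -> B] is the mean over spots i in state A of the total
    transition probability into state B; rows inherit stochasticity
    from P.  Every requested state must be populated.
    """
    labels = pd.Series(labels)
    states = list(states)
    unknown = set(labels) - set(states)
    if unknown:
        raise ValueError(f"labels outside the state set: {sorted(unknown)}")
    P = sparse.csr_matrix(P)
    if P.shape[0] != len(labels):
        raise ValueError("labels must cover every spot of P")
    lab = labels.to_numpy()
    masks = {s: lab == s for s in states}
    for s, m in masks.items():
        if not m.any():
            raise ValueError(f"state {s!r} is empty")
    Q = np.zeros((len(states), len(states)))
    for bi, b in enumerate(states):
        mass_to_b = np.asarray(P[:, masks[b]].sum(axis=1)).ravel()
        for ai, a in enumerate(states):
            Q[ai, bi] = mass_to_b[masks[a]].mean()
    qdf = pd.DataFrame(Q, index=states, columns=states)
    return StateGraph(Q=qdf)


# ---------------------------------------------------------------------------
# cached engine for repeated perturbation screens

class PerturbationEngine:
    """Precomputes everything reusable across perturbations of one
    sample: embedding neighbors, kernel factorization of the vector
    field, and per-gene projection terms.  Each perturbed state graph
    then costs one triangular solve plus the cosine kernel."""

    def __init__(
        self,
        result: VelocityResult,
        labels,
        k: int = 30,
        sigma: float = 0.1,
        bandwidth: float | None = None,
        ridge: float = 1e-4,
        smooth_with_field: bool = True,
    ):
        self.result = result
        self.labels = pd.Series(labels, index=result.spot_ids).loc[result.spot_ids]
        self.k = k
        self.sigma = sigma
        self.smooth_with_field = smooth_with_field
        x = result.embedding
        self._bw = bandwidth if bandwidth is not None else _median_bandwidth(x)
        self._ridge = ridge
        K = _rbf_kernel(x, x, self._bw)
        self._K = K
        self._chol = cho_factor(K + ridge * np.eye(x.shape[0]))
        nn = NearestNeighbors(n_neighbors=k).fit(x)
        self._knn = nn.kneighbors(return_distance=False)
        delta = x[self._knn] - x[:, None, :]
        self._delta = delta
        self._delta_norm = np.linalg.norm(delta, axis=2)
        self._gene_index = {g: j for j, g in enumerate(result.genes)}
        self._sd = result.ms.std(axis=0)
        self._expressed = result.ms.max(axis=0) > 0

    def _field(self, v_emb: np.ndarray) -> np.ndarray:
        if not self.smooth_with_field:
            return v_emb
        intercept = v_emb.mean(axis=0)
        coef = cho_solve(self._chol, v_emb - intercept)
        return intercept[None, :] + self._K @ coef

    def _graph(self, v_emb: np.ndarray) -> StateGraph:
        f = self._field(v_emb)
        vn = np.linalg.norm(f, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.einsum("nkd,nd->nk", self._delta, f) / (
                self._delta_norm * vn[:, None]
            )
        cos = np.where(np.isfinite(cos), cos, 0.0)
        logits = cos / self.sigma
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        w[vn <= 1e-12] = 1.0
        w /= w.sum(axis=1, keepdims=True)
        n = f.shape[0]
        P = sparse.csr_matrix(
            (w.ravel(), (np.repeat(np.arange(n), self.k), self._knn.ravel())),
            shape=(n, n),
        )
        return coarse_state_graph(P, self.labels)

    def baseline_graph(self) -> StateGraph:
        return self._graph(self.result.embedded_velocity)

    def perturbed_graph(self, spec: PerturbationSpec) -> StateGraph:
        """State graph after overriding target velocities (rank-one
        embedding updates per target, no full re-projection)."""
        r = self.result
        v_emb = r.embedded_velocity.copy()
        applied = 0
        for gene, m in spec.targets.items():
            if m == 0:
                applied += 1
                continue
            j = self._gene_index.get(gene)
            if j is None or not self._expressed[j] or self._sd[j] == 0:
                continue
            new_col = np.full(r.ms.shape[0], (m / MAGNITUDE_SCALE) * self._sd[j])
            diff = (new_col - r.velocity[:, j]) / (1.0 + r.ms[:, j])
            v_emb += diff[:, None] * r.loadings[j][None, :]
            applied += 1
        if spec.targets and applied == 0:
            raise ValueError("no perturbation target with nonzero expression")
        return self._graph(v_emb)

    def expressed_targets(self, genes: Sequence[str]) -> list[str]:
        return [
            g
            for g in genes
            if g in self._gene_index
            and self._expressed[self._gene_index[g]]
            and self._sd[self._gene_index[g]] > 0
        ]
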