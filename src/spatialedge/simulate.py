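"""Seeded synthetic data with the statistical structure the pipeline assumes.

Four generators cover the pipeline's inputs:

* :func:`simulate_st_sample` — one hex-lattice spatial sample with
  concentric tumor zoning (core / transitory ring / leading-edge ring)
  surrounded by stroma, negative-binomial counts with zone-specific
  expression programs, spliced/unspliced layers driven by splicing
  kinetics along the core-to-edge axis, and ground-truth-concordant
  deconvolution, CNV-probability and pathology channels.
* :func:`simulate_kinetics` — spliced/unspliced layers from per-gene
  transcription/splicing/degradation rates evaluated at each spot's
  pseudotime (closed-form linear-ODE solution, Poisson sampling).
* :func:`simulate_drug_screen` — drug response tables with a planted
  association between flow-reversing drugs (down-regulators of
  leading-edge driver genes) and higher AAC.
* :func:`simulate_survival_cohort` — expression + right-censored
  survival with proportional-hazards dependence on rank-based
  signature scores.

All randomness flows through one ``numpy.random.Generator`` created
from the ``seed`` argument; identical (config, seed) pairs reproduce
outputs exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .lattice import generate_hex_lattice, hex_distance

CELL_TYPES = (
    "cancer",
    "ecm-myCAF",
    "detox-iCAF",
    "intermediate-fibroblast",
    "macrophage",
    "cytotoxic-CD8-T",
    "other",
)
STROMA_TYPES = CELL_TYPES[1:]

# literature marker symbols used for the planted programs
CORE_MARKERS = ("CLDN4", "SPRR1B")
EDGE_MARKERS = ("LAMC2", "ITGA5")
CELLTYPE_MARKERS = {
    "ecm-myCAF": ("LRRC15", "GJB2"),
    "detox-iCAF": ("ADH1B", "GPX3"),
}


@dataclass(frozen=True)
class KineticsParams:
    """Rates of the two-stage transcription model
    du/dt = alpha - beta*u, ds/dt = beta*u - gamma*s."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be > 0")


@dataclass(frozen=True)
class STConfig:
    """Geometry, expression and noise settings for one spatial sample.

    Radii are hex (ring) distances from the lattice center: the tumor
    core occupies ``d <= r_core``, the transitory ring
    ``r_core < d <= r_transitory``, the leading edge
    ``r_transitory < d <= r_edge`` and everything further out is stroma.
    """

    n_rows: int = 40
    n_cols: int = 40
    r_core: int = 4
    r_transitory: int = 6
    r_edge: int = 9
    n_genes: int = 300
    core_program_size: int = 25
    edge_program_size: int = 25
    n_edge_drivers: int = 10
    core_markers: Sequence[str] = CORE_MARKERS
    edge_markers: Sequence[str] = EDGE_MARKERS
    markers_per_celltype: int = 5
    program_high: float = 8.0
    program_mid: float = 3.0
    program_low: float = 1.0
    celltype_boost: float = 6.0
    base_log_mean: float = 1.1   # lognormal gene base mean, log scale
    base_log_sigma: float = 0.7
    libsize_sigma: float = 0.12  # lognormal spot library-size factor
    dispersion: float = 0.15     # NB: var = mu * (1 + dispersion * mu)
    sample_gene_sigma: float = 0.0  # per-sample lognormal gene jitter
    channel_noise: float = 0.0   # fraction of tumor spots with degraded
                                 # deconvolution/CNV channels
    # kinetics of the spliced/unspliced layers
    beta: float = 1.0
    gamma_range: tuple[float, float] = (0.4, 1.0)
    t_span: float = 2.0          # absolute time at pseudotime 1
    unspliced_capture: float = 0.5
    noise: bool = True           # Poisson/NB sampling on; False returns means


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    # numpy parameterization: n successes, p = n / (n + mu)
    return rng.negative_binomial(size, size / (size + np.maximum(mean, 1e-12)))


def _gene_names(cfg: STConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    """Gene name vector plus index sets of every planted program."""
    names: list[str] = []
    core = list(cfg.core_markers) + [
        f"COREG{i:03d}" for i in range(cfg.core_program_size - len(cfg.core_markers))
    ]
    edge = list(cfg.edge_markers) + [
        f"EDGEG{i:03d}" for i in range(cfg.edge_program_size - len(cfg.edge_markers))
    ]
    if cfg.core_program_size < len(cfg.core_markers):
        raise ValueError("core program smaller than its marker set")
    if cfg.edge_program_size < len(cfg.edge_markers):
        raise ValueError("edge program smaller than its marker set")
    if not core or not edge:
        raise ValueError("marker sets must be non-empty")
    names += core + edge
    ct_markers: dict[str, list[str]] = {}
    for ct in STROMA_TYPES:
        fixed = list(CELLTYPE_MARKERS.get(ct, ()))[: cfg.markers_per_celltype]
        extra = [
            f"{ct.upper().replace('-', '')[:6]}M{i}"
            for i in range(cfg.markers_per_celltype - len(fixed))
        ]
        ct_markers[ct] = fixed + extra
        names += ct_markers[ct]
    n_hk = cfg.n_genes - len(names)
    if n_hk < 0:
        raise ValueError("n_genes too small for the configured programs")
    names += [f"HKG{i:04d}" for i in range(n_hk)]
    idx = {n: i for i, n in enumerate(names)}
    sets = {
        "core_program": np.array([idx[g] for g in core]),
        "edge_program": np.array([idx[g] for g in edge]),
        "edge_drivers": np.array([idx[g] for g in edge[: cfg.n_edge_drivers]]),
        "housekeeping": np.arange(len(names) - n_hk, len(names)),
    }
    for ct, genes in ct_markers.items():
        sets[f"markers:{ct}"] = np.array([idx[g] for g in genes])
    return names, sets


def kinetic_solution(t, alpha, beta, gamma, u0=0.0, s0=0.0):
    """Closed-form (u(t), s(t)) of du/dt = alpha - beta*u,
    ds/dt = beta*u - gamma*s with initial condition (u0, s0).

    ``t`` may be an array; parameters are scalars or broadcastable.
    """
    t = np.asarray(t, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(beta <= 0) or np.any(gamma <= 0):
        raise ValueError("beta and gamma must be positive")
    # nudge apart the degenerate beta == gamma case
    gamma = np.where(np.abs(gamma - beta) < 1e-9, gamma * (1 + 1e-6), gamma)
    eb = np.exp(-beta * t)
    eg = np.exp(-gamma * t)
    u = u0 * eb + (alpha / beta) * (1 - eb)
    s = (
        s0 * eg
        + (alpha / gamma) * (1 - eg)
        + (alpha - beta * u0) / (gamma - beta) * (eg - eb)
    )
    return u, s


def simulate_kinetics(
    adata: ad.AnnData,
    params: Sequence[KineticsParams],
    seed: int = 0,
    *,
    phases: Sequence[str] | None = None,
    t_scale: float = 1.0,
    unspliced_capture: float = 1.0,
    background: float = 0.2,
    noise: bool = True,
) -> ad.AnnData:
    """Write ``spliced``/``unspliced`` layers following the splicing ODE.

    Spots with finite ``obs['pseudotime']`` follow the closed-form
    solution at ``t = pseudotime * t_scale``; per-gene ``phases`` select
    "induction" (from the empty state) or "repression" (transcription
    switched off at t = 0 from steady state).  Spots without pseudotime
    (stroma) receive Poisson background counts.
    """
    if len(params) != adata.n_vars:
        raise ValueError("need one KineticsParams per gene")
    phases = list(phases) if phases is not None else ["induction"] * adata.n_vars
    rng = np.random.default_rng(seed)
    t = adata.obs["pseudotime"].to_numpy(dtype=float) * t_scale
    tumor = np.isfinite(t)
    u_mean = np.full((adata.n_obs, adata.n_vars), background, dtype=float)
    s_mean = np.full((adata.n_obs, adata.n_vars), background, dtype=float)
    tt = t[tumor]
    for j, (p, phase) in enumerate(zip(params, phases)):
        if phase == "induction":
            u, s = kinetic_solution(tt, p.alpha, p.beta, p.gamma)
        elif phase == "repression":
            u, s = kinetic_solution(
                tt, 0.0, p.beta, p.gamma, u0=p.alpha / p.beta, s0=p.alpha / p.gamma
            )
        elif phase == "steady":
            u = np.full_like(tt, p.alpha / p.beta)
            s = np.full_like(tt, p.alpha / p.gamma)
        else:
            raise ValueError(f"unknown phase {phase!r}")
        u_mean[tumor, j] = u
        s_mean[tumor, j] = s
    u_mean *= unspliced_capture
    if noise:
        adata.layers["spliced"] = rng.poisson(s_mean).astype(np.int64)
        adata.layers["unspliced"] = rng.poisson(u_mean).astype(np.int64)
    else:
        adata.layers["spliced"] = s_mean
        adata.layers["unspliced"] = u_mean
    return adata


def simulate_st_sample(
    config: STConfig | None = None, seed: int = 0, *, sample_id: str | None = None
) -> ad.AnnData:
    """Generate one annotated hex-lattice spatial sample.

    Returns an :class:`anndata.AnnData` with raw counts in ``X``,
    ``spliced``/``unspliced`` layers, ground truth in
    ``obs[['region_true', 'cell_type_true', 'pseudotime']]``, the three
    malignancy-calling channels (``obsm['deconv']``, ``obs['p_cnv']``,
    ``obs['pathology']``) and the planted gene programs in ``uns``.
    """
    cfg = config or STConfig()
    rng = np.random.default_rng(seed)
    lattice = generate_hex_lattice(cfg.n_rows, cfg.n_cols)
    center = lattice.iloc[
        ((lattice["array_row"] - cfg.n_rows // 2).abs()
         + (lattice["array_col"] - cfg.n_cols // 2).abs()).argmin()
    ]
    d = hex_distance(
        lattice["array_row"].to_numpy(),
        lattice["array_col"].to_numpy(),
        int(center["array_row"]),
        int(center["array_col"]),
    )
    if cfg.r_edge >= int(d.max()):
        raise ValueError("tumor radius exceeds the lattice")
    if not (0 < cfg.r_core < cfg.r_transitory < cfg.r_edge):
        raise ValueError("zone radii must satisfy 0 < r_core < r_transitory < r_edge")

    region = np.where(
        d <= cfg.r_core,
        "TC",
        np.where(d <= cfg.r_transitory, "transitory", np.where(d <= cfg.r_edge, "LE", "stroma")),
    )
    tumor = region != "stroma"
    n_spots = len(lattice)
    pseudotime = np.where(tumor, d / cfg.r_edge, np.nan)

    # --- stroma cell types in distance bands hugging the leading edge
    cell_type = np.where(tumor, "cancer", "other").astype(object)
    stroma_idx = np.flatnonzero(~tumor)
    band = d[stroma_idx] - cfg.r_edge
    probs = np.empty((stroma_idx.size, len(STROMA_TYPES)))
    inner = band <= 2          # CAF collar around the LE
    middle = (band > 2) & (band <= 5)
    probs[inner] = [0.65, 0.10, 0.10, 0.05, 0.05, 0.05]
    probs[middle] = [0.15, 0.30, 0.30, 0.10, 0.10, 0.05]
    probs[band > 5] = [0.05, 0.10, 0.10, 0.30, 0.25, 0.20]
    draws = np.array(
        [rng.choice(len(STROMA_TYPES), p=p) for p in probs], dtype=int
    )
    cell_type[stroma_idx] = np.array(STROMA_TYPES, dtype=object)[draws]

    # --- deconvolution, CNV probability, pathology channels
    deconv = np.zeros((n_spots, len(CELL_TYPES)))
    cancer_prop = 0.99 + 0.01 * rng.beta(2.0, 2.0, size=n_spots)
    rest = rng.dirichlet(np.ones(len(STROMA_TYPES)), size=n_spots)
    deconv[tumor, 0] = cancer_prop[tumor]
    deconv[tumor, 1:] = rest[tumor] * (1 - cancer_prop[tumor])[:, None]
    for k, ct in enumerate(STROMA_TYPES):
        mask = (~tumor) & (cell_type == ct)
        dom = 0.55 + 0.25 * rng.beta(2.0, 2.0, size=int(mask.sum()))
        other = rng.dirichlet(np.ones(len(CELL_TYPES) - 1), size=int(mask.sum()))
        deconv[mask, k + 1] = dom
        cols = [j for j in range(len(CELL_TYPES)) if j != k + 1]
        deconv[np.ix_(np.flatnonzero(mask), cols)] = other * (1 - dom)[:, None]
    p_cnv = np.where(
        tumor, 0.99 + 0.01 * rng.beta(2.0, 2.0, size=n_spots),
        0.3 * rng.beta(1.0, 3.0, size=n_spots),
    )
    pathology = np.where(tumor, "SCC", "stroma")
    if cfg.channel_noise > 0:
        flip = tumor & (rng.random(n_spots) < cfg.channel_noise)
        deconv[flip, 0] = 0.5 * rng.random(int(flip.sum()))
        deconv[flip, 1:] = (
            rng.dirichlet(np.ones(len(STROMA_TYPES)), size=int(flip.sum()))
            * (1 - deconv[flip, 0])[:, None]
        )
        p_cnv[flip] = 0.5 * rng.random(int(flip.sum()))

    # --- expression programs (stepwise by region for the count assay)
    names, sets = _gene_names(cfg)
    base = rng.lognormal(cfg.base_log_mean, cfg.base_log_sigma, size=cfg.n_genes)
    if cfg.sample_gene_sigma > 0:
        base = base * rng.lognormal(0.0, cfg.sample_gene_sigma, size=cfg.n_genes)
    mult = np.ones((n_spots, cfg.n_genes))
    hi, mid, lo = cfg.program_high, cfg.program_mid, cfg.program_low
    for reg, cmul, emul in (("TC", hi, lo), ("transitory", mid, mid), ("LE", lo, hi)):
        rows = np.flatnonzero(region == reg)
        mult[np.ix_(rows, sets["core_program"])] = cmul
        mult[np.ix_(rows, sets["edge_program"])] = emul
    mult[np.ix_(np.flatnonzero(~tumor), sets["core_program"])] = lo
    mult[np.ix_(np.flatnonzero(~tumor), sets["edge_program"])] = lo
    for ct in STROMA_TYPES:
        rows = np.flatnonzero((~tumor) & (cell_type == ct))
        mult[np.ix_(rows, sets[f"markers:{ct}"])] = cfg.celltype_boost
    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_spots)
    mean = base[None, :] * mult * lib[:, None]
    counts = (
        _nb_sample(rng, mean, cfg.dispersion).astype(np.int64)
        if cfg.noise
        else mean
    )

    obs = pd.DataFrame(
        {
            "array_row": lattice["array_row"].to_numpy(),
            "array_col": lattice["array_col"].to_numpy(),
            "in_tissue": True,
            "hex_dist": d,
            "region_true": region,
            "cell_type_true": cell_type,
            "pseudotime": pseudotime,
            "p_cnv": p_cnv,
            "pathology": pathology,
        },
        index=lattice.index.copy(),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(names, name="gene")))
    adata.obsm["deconv"] = pd.DataFrame(
        deconv, index=adata.obs_names, columns=list(CELL_TYPES)
    )
    adata.uns["gene_sets"] = {
        "core_program": [names[i] for i in sets["core_program"]],
        "edge_program": [names[i] for i in sets["edge_program"]],
        "edge_drivers": [names[i] for i in sets["edge_drivers"]],
        "housekeeping": [names[i] for i in sets["housekeeping"]],
    }
    adata.uns["config"] = dataclasses.asdict(cfg)
    if sample_id is not None:
        adata.uns["sample_id"] = sample_id

    # --- spliced/unspliced layers from kinetics along the TC->LE axis.
    # Edge-program genes are being induced along the trajectory
    # (positive velocity), core-program genes repressed (negative),
    # everything else sits at steady state.
    gammas = rng.uniform(*cfg.gamma_range, size=cfg.n_genes)
    params, phases = [], []
    in_core = np.zeros(cfg.n_genes, bool)
    in_core[sets["core_program"]] = True
    in_edge = np.zeros(cfg.n_genes, bool)
    in_edge[sets["edge_program"]] = True
    for j in range(cfg.n_genes):
        g = gammas[j]
        if in_edge[j]:
            target = base[j] * hi
            params.append(KineticsParams(alpha=target * g, beta=cfg.beta, gamma=g))
            phases.append("induction")
        elif in_core[j]:
            start = base[j] * hi
            params.append(KineticsParams(alpha=start * g, beta=cfg.beta, gamma=g))
            phases.append("repression")
        else:
            params.append(KineticsParams(alpha=base[j] * g, beta=cfg.beta, gamma=g))
            phases.append("steady")
    simulate_kinetics(
        adata,
        params,
        seed=int(rng.integers(2**31 - 1)),
        phases=phases,
        t_scale=cfg.t_span,
        unspliced_capture=cfg.unspliced_capture,
        noise=cfg.noise,
    )
    adata.uns["kinetics"] = {
        "gamma": gammas,
        "alpha": np.array([p.alpha for p in params]),
        "beta": cfg.beta,
        "phases": np.array(phases),
    }
    return adata


def simulate_cohort(
    n_samples: int = 12,
    config: STConfig | None = None,
    seed: int = 0,
    *,
    sample_gene_sigma: float = 0.15,
) -> list[ad.AnnData]:
    """A cohort of samples sharing programs but with per-sample
    gene-level variation (lognormal jitter of the base means)."""
    cfg = dataclasses.replace(
        config or STConfig(), sample_gene_sigma=sample_gene_sigma
    )
    root = np.random.default_rng(seed)
    seeds = root.integers(2**31 - 1, size=n_samples)
    return [
        simulate_st_sample(cfg, seed=int(s), sample_id=f"sample_{i+1:02d}")
        for i, s in enumerate(seeds)
    ]


def simulate_gamma_benchmark(
    n_spots: int = 2000,
    n_genes: int = 200,
    seed: int = 0,
    *,
    gamma_range: tuple[float, float] = (0.1, 2.0),
    t_max: float = 30.0,
    noise: bool = True,
) -> ad.AnnData:
    """Kinetics-only dataset for degradation-rate recovery experiments.

    Spots sample each gene's induction trajectory at uniform times so
    that the extremes of the spliced distribution bracket the steady
    state.  Genes carry random phase offsets (wrap-around time) so they
    are asynchronous across the population, as in real tissue — this
    keeps library size roughly independent of any single gene's
    position on its curve.  ``var['gamma_true']`` holds the planted
    rates (log-uniform over ``gamma_range``).
    """
    rng = np.random.default_rng(seed)
    gammas = np.exp(rng.uniform(np.log(gamma_range[0]), np.log(gamma_range[1]), n_genes))
    s_star = rng.uniform(10.0, 50.0, size=n_genes)
    alphas = s_star * gammas
    t = rng.uniform(0.0, t_max, size=n_spots)
    phase = rng.uniform(0.0, t_max, size=n_genes)
    t_eff = (t[:, None] + phase[None, :]) % t_max
    u_mean = np.empty((n_spots, n_genes))
    s_mean = np.empty((n_spots, n_genes))
    for j in range(n_genes):
        u_mean[:, j], s_mean[:, j] = kinetic_solution(
            t_eff[:, j], alphas[j], 1.0, gammas[j]
        )
    obs = pd.DataFrame(
        {"pseudotime": t}, index=[f"cell_{i}" for i in range(n_spots)]
    )
    var = pd.DataFrame(
        {"gamma_true": gammas}, index=[f"G{j:04d}" for j in range(n_genes)]
    )
    if noise:
        spliced = rng.poisson(s_mean).astype(np.int64)
        unspliced = rng.poisson(u_mean).astype(np.int64)
    else:
        spliced, unspliced = s_mean, u_mean
    adata = ad.AnnData(X=spliced.copy(), obs=obs, var=var)
    adata.layers["spliced"] = spliced
    adata.layers["unspliced"] = unspliced
    return adata


# ---------------------------------------------------------------------------
# drug screen

UP_KEYWORDS = (
    "activator", "agonist", "inducer", "partial agonist",
    "positive modulator", "potentiator", "stimulator",
)
DOWN_KEYWORDS = (
    "inhibitor", "antagonist", "partial antagonist", "blocker",
    "inverse agonist", "negative modulator", "suppressor",
)
NEUTRAL_KEYWORDS = ("binder", "ligand", "modulator", "substrate", "cofactor")


@dataclass
class DrugRecord:
    """One drug with raw per-(cell line, dataset) AAC values and its
    target interactions."""

    drug_id: str
    aac: pd.DataFrame  # columns: cell_line, dataset, aac
    targets: list[tuple[str, str]]  # (gene, interaction keyword)
    mechanism: str | None = None
    direction: dict[str, str] | None = None
    aggregated_aac: float | None = None
    group: str | None = None


@dataclass(frozen=True)
class DrugScreenConfig:
    n_drugs: int = 40
    n_cell_lines: int = 30
    n_datasets: int = 3
    frac_reversing: float = 0.5
    effect: float = 0.2          # AAC shift of flow-reversing drugs
    targets_per_drug: tuple[int, int] = (1, 3)
    aac_beta: tuple[float, float] = (12.6, 50.4)  # mean 0.2, sd 0.05
    cell_line_sd: float = 0.08
    dataset_sd: float = 0.05


def simulate_drug_screen(
    config: DrugScreenConfig | None = None,
    driver_genes: Sequence[str] = (),
    decoy_genes: Sequence[str] = (),
    seed: int = 0,
) -> tuple[list[DrugRecord], pd.DataFrame]:
    """Drug records with a planted flow-reversal/AAC association.

    A ``frac_reversing`` fraction of drugs target ``driver_genes``
    (planted leading-edge drivers) with down-regulating keywords and
    receive an AAC shifted up by ``config.effect``; the rest target
    ``decoy_genes`` with keywords drawn from the up/down/neutral pools.
    Returns the records and a truth table (drug_id, reversing, base_aac).
    """
    import warnings

    cfg = config or DrugScreenConfig()
    if not driver_genes:
        raise ValueError("driver_genes must be provided")
    decoys = list(decoy_genes) or list(driver_genes)
    rng = np.random.default_rng(seed)
    n_rev = int(round(cfg.n_drugs * cfg.frac_reversing))
    cell_lines = [f"CL{i:02d}" for i in range(cfg.n_cell_lines)]
    datasets = [f"DS{i}" for i in range(cfg.n_datasets)]
    records, truth = [], []
    for i in range(cfg.n_drugs):
        reversing = i < n_rev
        base = rng.beta(*cfg.aac_beta)
        if reversing:
            base += cfg.effect
            if base > 1.0:
                warnings.warn("planted AAC effect clamped to [0, 1]")
                base = 1.0
        per_line = np.clip(
            base + rng.normal(0, cfg.cell_line_sd, size=cfg.n_cell_lines), 0, 1
        )
        rows = []
        for cl, v in zip(cell_lines, per_line):
            for ds in datasets:
                rows.append(
                    (cl, ds, float(np.clip(v + rng.normal(0, cfg.dataset_sd), 0, 1)))
                )
        aac = pd.DataFrame(rows, columns=["cell_line", "dataset", "aac"])
        n_t = int(rng.integers(cfg.targets_per_drug[0], cfg.targets_per_drug[1] + 1))
        if reversing:
            genes = rng.choice(list(driver_genes), size=min(n_t, len(driver_genes)), replace=False)
            targets = [(g, str(rng.choice(DOWN_KEYWORDS))) for g in genes]
            mech = "LE-driver inhibitor"
        else:
            genes = rng.choice(decoys, size=min(n_t, len(decoys)), replace=False)
            pool = UP_KEYWORDS + DOWN_KEYWORDS + NEUTRAL_KEYWORDS
            targets = [(g, str(rng.choice(pool))) for g in genes]
            mech = str(rng.choice(["kinase inhibitor", "receptor agonist", "DNA binder"]))
        records.append(
            DrugRecord(drug_id=f"drug_{i:03d}", aac=aac, targets=targets, mechanism=mech)
        )
        truth.append((f"drug_{i:03d}", reversing, base))
    truth_df = pd.DataFrame(truth, columns=["drug_id", "reversing", "base_aac"])
    return records, truth_df


# ---------------------------------------------------------------------------
# survival cohort

@dataclass(frozen=True)
class SurvivalConfig:
    n: int = 275
    n_genes: int = 2000
    signature_size: int = 40
    signature_effect: float = 1.0   # per-gene loading of the latent score
    expr_noise: float = 1.0
    score_correlation: float = -0.2  # latent TC/LE correlation
    hr_le: float = 1.0               # hazard ratio per SD of the LE score
    hr_tc: float = 1.0
    cut_quantile: float | None = None  # binary-risk mode: threshold on z_LE
    hr_group: float | None = None      # hazard ratio of the high group
    baseline_hazard: float = 0.1
    censoring: float = 0.3


@dataclass
class SurvivalCohort:
    """Expression + survival endpoints with computed signature scores."""

    expression: pd.DataFrame         # patients x genes
    time: pd.Series
    event: pd.Series
    gene_sets: dict[str, list[str]]
    scores: pd.DataFrame             # standardized rank scores z_TC, z_LE
    truth: dict


def simulate_survival_cohort(
    config: SurvivalConfig | None = None, seed: int = 0
) -> SurvivalCohort:
    """Cohort whose hazard depends on its own rank-based signature scores.

    Expression of each signature gene loads on a latent per-patient
    factor; rank scores are computed from the realized expression (the
    same scoring the analysis applies) and the hazard is
    ``h0 * exp(log(hr_le) * z_LE + log(hr_tc) * z_TC)`` — or, in
    binary-risk mode, ``h0 * exp(log(hr_group) * [z_LE > cutpoint])``
    with the true cutpoint at ``cut_quantile`` of the LE score.
    Censoring is administrative: uniform entry before a fixed data
    cutoff, with the follow-up window calibrated so the expected
    censored fraction matches ``config.censoring``.
    """
    from .scoring import rank_score_frame

    cfg = config or SurvivalConfig()
    if cfg.n <= 0 or cfg.baseline_hazard <= 0:
        raise ValueError("n and baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    rho = cfg.score_correlation
    latent = rng.multivariate_normal(
        [0, 0], [[1, rho], [rho, 1]], size=cfg.n
    )  # columns: TC, LE
    genes = [f"SG{j:04d}" for j in range(cfg.n_genes)]
    tc_set = genes[: cfg.signature_size]
    le_set = genes[cfg.signature_size : 2 * cfg.signature_size]
    expr = rng.normal(0, cfg.expr_noise, size=(cfg.n, cfg.n_genes))
    expr[:, : cfg.signature_size] += cfg.signature_effect * latent[:, [0]]
    expr[:, cfg.signature_size : 2 * cfg.signature_size] += (
        cfg.signature_effect * latent[:, [1]]
    )
    patients = [f"P{i:04d}" for i in range(cfg.n)]
    expression = pd.DataFrame(expr, index=patients, columns=genes)
    scores = pd.DataFrame(
        {
            "z_TC": rank_score_frame(expression, tc_set),
            "z_LE": rank_score_frame(expression, le_set),
        }
    )
    z = (scores - scores.mean()) / scores.std(ddof=0)
    if cfg.cut_quantile is not None:
        if cfg.hr_group is None:
            raise ValueError("binary-risk mode needs hr_group")
        cut = float(np.quantile(z["z_LE"], cfg.cut_quantile))
        lin = np.log(cfg.hr_group) * (z["z_LE"].to_numpy() > cut)
        true_cut = cut
    else:
        lin = np.log(cfg.hr_le) * z["z_LE"].to_numpy() + np.log(cfg.hr_tc) * z[
            "z_TC"
        ].to_numpy()
        true_cut = None
    hazard = cfg.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring <= 0:
        time, event = t_event, np.ones(cfg.n, dtype=int)
    else:
        horizon = _censoring_horizon(t_event, cfg.censoring)
        c = rng.uniform(0.0, horizon, size=cfg.n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    return SurvivalCohort(
        expression=expression,
        time=pd.Series(time, index=patients, name="time"),
        event=pd.Series(event, index=patients, name="event"),
        gene_sets={"TC": tc_set, "LE": le_set},
        scores=z,
        truth={
            "latent": latent,
            "true_cut": true_cut,
            "config": dataclasses.asdict(cfg),
        },
    )


def _censoring_horizon(t_event: np.ndarray, target: float) -> float:
    """Follow-up window of uniform administrative censoring whose
    expected censored fraction, given the drawn event times, equals
    ``target`` (bisection; censored iff C < T with C ~ U(0, horizon))."""
    def frac(h):
        return float(np.mean(np.minimum(t_event, h) / h))

    lo = float(t_event.min()) * 1e-6 + 1e-12
    hi = float(t_event.max()) * 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:  # shorter window censors more
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
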