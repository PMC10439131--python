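"""End-to-end property benchmarks of the pipeline on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns the measured quantities.  These back both
the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import (
    PerturbationEngine,
    PerturbationSpec,
    STConfig,
    annotate_sample,
    compute_velocity,
    consensus_genes,
    de_table,
    optimal_cutpoint,
    region_correlation_matrix,
    run_screen,
    simulate_cohort,
    simulate_drug_screen,
    simulate_gamma_benchmark,
    simulate_st_sample,
    simulate_survival_cohort,
)
from .simulate import DrugScreenConfig, SurvivalConfig
from .survival import cox_fit, fit_signature_survival
from .velocity import build_transition_matrix

COHORT_CONFIG = STConfig(core_program_size=50, edge_program_size=50, n_genes=400)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def gamma_recovery(seed: int, n_spots: int = 2000, n_genes: int = 200) -> dict:
    """Median relative error of the steady-state degradation-rate
    estimate on simulated splicing kinetics."""
    bench = simulate_gamma_benchmark(n_spots=n_spots, n_genes=n_genes, seed=seed)
    vr = compute_velocity(bench, subset=None)
    truth = bench.var["gamma_true"].to_numpy()
    rel = np.abs(vr.gamma.to_numpy() - truth) / truth
    return {"median_rel_error": float(np.median(rel)), "n": n_genes}


def _default_engine(seed: int):
    sample = simulate_st_sample(seed=seed)
    ann = annotate_sample(sample, seed=0)
    vr = compute_velocity(ann)
    labels = ann.obs.loc[vr.spot_ids, "region"]
    return ann, vr, PerturbationEngine(vr, labels)


def transition_machinery(seed: int, n_check: int = 200) -> dict:
    """Row-stochasticity of P and Q and agreement of P with a
    brute-force recomputation from its definition on random spots."""
    ann, vr, engine = _default_engine(seed)
    k, sigma = 30, 0.1
    P = build_transition_matrix(vr.embedding, vr.embedded_velocity, k=k, sigma=sigma)
    row_dev = float(np.abs(np.asarray(P.sum(axis=1)).ravel() - 1.0).max())
    Q = engine.baseline_graph().Q
    q_dev = float(np.abs(Q.sum(axis=1) - 1.0).max())

    x, v = vr.embedding, vr.embedded_velocity
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in rng.choice(n, size=min(n_check, n), replace=False):
        d2 = ((x - x[i]) ** 2).sum(axis=1)
        d2[i] = np.inf
        nbrs = np.argsort(d2, kind="stable")[:k]
        vi, vnorm = v[i], np.linalg.norm(v[i])
        w = np.zeros(k)
        for jj, j in enumerate(nbrs):
            delta = x[j] - x[i]
            if vnorm <= 1e-12:
                w[jj] = 1.0
            else:
                w[jj] = np.exp(
                    vi @ delta / (vnorm * np.linalg.norm(delta)) / sigma - 1.0 / sigma
                )
        w /= w.sum()
        row = np.zeros(n)
        row[nbrs] = w
        worst = max(worst, float(np.abs(np.asarray(P[i].todense()).ravel() - row).max()))
    return {
        "P_rowsum_max_dev": row_dev,
        "Q_rowsum_max_dev": q_dev,
        "bruteforce_max_abs_diff": worst,
        "n": n,
    }


def flow_reversal(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of seeded samples where down-perturbing the planted
    leading-edge drivers (M = -200) raises the edge-outgoing signature
    above baseline, plus the opposite-direction control."""
    down_hits = up_ok = 0
    for s in _child_seeds(seed, n_seeds):
        sample = simulate_st_sample(seed=int(s))
        ann = annotate_sample(sample, seed=0)
        vr = compute_velocity(ann)
        engine = PerturbationEngine(vr, ann.obs.loc[vr.spot_ids, "region"])
        drivers = ann.uns["gene_sets"]["edge_drivers"]
        base = engine.baseline_graph().edge_outgoing
        down = engine.perturbed_graph(
            PerturbationSpec.from_directions({g: "down" for g in drivers})
        ).edge_outgoing
        up = engine.perturbed_graph(
            PerturbationSpec.from_directions({g: "up" for g in drivers})
        ).edge_outgoing
        down_hits += down > base
        up_ok += up <= base + 1e-9
    return {
        "reversal_rate": down_hits / n_seeds,
        "up_control_rate": up_ok / n_seeds,
        "n": n_seeds,
    }


def screen_power(
    seed: int, n_reps: int = 10, effect: float = 0.2, n_null: int = 100
) -> dict:
    """Power of the in-silico screen at the planted AAC effect and its
    type-I error under a null effect, on one shared sample."""
    ann, vr, engine = _default_engine(seed)
    drivers = ann.uns["gene_sets"]["edge_drivers"]
    decoys = ann.uns["gene_sets"]["housekeeping"]
    seeds = _child_seeds(seed + 1, n_reps + n_null)
    hits = 0
    for s in seeds[:n_reps]:
        records, _ = simulate_drug_screen(
            DrugScreenConfig(effect=effect), drivers, decoys, seed=int(s)
        )
        res = run_screen(engine, records)
        hits += res.stats.loc["edge_outgoing", "pval"] < 0.05
    rejections = 0
    for s in seeds[n_reps:]:
        records, _ = simulate_drug_screen(
            DrugScreenConfig(effect=0.0), drivers, decoys, seed=int(s)
        )
        res = run_screen(engine, records)
        rejections += res.stats.loc["edge_outgoing", "pval"] < 0.05
    return {
        "power": hits / n_reps,
        "null_rejection_rate": rejections / n_null,
        "n": n_reps,
        "n_null": n_null,
    }


def malignancy_rule_agreement(seed: int, n: int = 10_000) -> dict:
    """Exact agreement of the malignancy call with a truth-table oracle
    on random channel triples."""
    import anndata as ad

    from . import call_malignant

    rng = np.random.default_rng(seed)
    cancer = rng.uniform(0.9, 1.0, n)
    p_cnv = rng.uniform(0.9, 1.0, n)
    path = rng.choice(["SCC", "stroma"], n)
    a = ad.AnnData(X=np.ones((n, 2), dtype=np.int64))
    a.obs_names = [f"s{i}" for i in range(n)]
    a.obsm["deconv"] = pd.DataFrame(
        np.column_stack([cancer, 1 - cancer]),
        index=a.obs_names,
        columns=["cancer", "CAF"],
    )
    a.obs["p_cnv"] = p_cnv
    a.obs["pathology"] = path
    got = call_malignant(a).to_numpy()
    oracle = np.array(
        [
            ((c > 0.99) or (p > 0.99)) and lab == "SCC"
            for c, p, lab in zip(cancer, p_cnv, path)
        ]
    )
    return {"agreement": float((got == oracle).mean()), "n": n}


def region_recovery(seed: int, n_samples: int = 3) -> dict:
    """Accuracy of the TC/transitory/LE annotation against the planted
    zones on default-condition samples."""
    accs = []
    for s in _child_seeds(seed, n_samples):
        sample = simulate_st_sample(seed=int(s))
        ann = annotate_sample(sample, seed=0)
        mal = ann.obs["malignant"]
        accs.append(
            float((ann.obs.loc[mal, "region"] == ann.obs.loc[mal, "region_true"]).mean())
        )
    return {"min_accuracy": min(accs), "mean_accuracy": float(np.mean(accs)), "n": n_samples}


def consensus_recovery(seed: int, min_samples: int = 10) -> dict:
    """Sensitivity and false discoveries of the cross-sample consensus
    on a cohort with 50 planted genes per direction."""
    cohort = [annotate_sample(a, seed=0) for a in simulate_cohort(12, COHORT_CONFIG, seed=seed)]
    tables = [de_table(a) for a in cohort]
    cons = consensus_genes(tables, min_samples=min_samples)
    planted_tc = set(cohort[0].uns["gene_sets"]["core_program"])
    planted_le = set(cohort[0].uns["gene_sets"]["edge_program"])
    got_tc = set(cons.index[cons["direction"] == "TC-up"])
    got_le = set(cons.index[cons["direction"] == "LE-up"])
    tp = len(got_tc & planted_tc) + len(got_le & planted_le)
    fp = len((got_tc | got_le) - planted_tc - planted_le)
    out = {
        "sensitivity": tp / (len(planted_tc) + len(planted_le)),
        "false_consensus_genes": fp,
        "n": 12,
    }
    out["_cohort"] = cohort  # reused by correlation_structure
    return out


def correlation_structure(seed: int, cohort=None) -> dict:
    """Mean within-region cross-sample correlation vs mean TC-vs-LE
    correlation on the default 12-sample cohort."""
    if cohort is None:
        cohort = [
            annotate_sample(a, seed=0) for a in simulate_cohort(12, COHORT_CONFIG, seed=seed)
        ]
    corr = region_correlation_matrix(cohort)
    idx = corr.index
    within, between = [], []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            (si, ri), (sj, rj) = idx[i], idx[j]
            if si == sj:
                continue
            (within if ri == rj else between).append(corr.iloc[i, j])
    return {
        "within_region_mean": float(np.mean(within)),
        "between_region_mean": float(np.mean(between)),
        "n": len(cohort),
    }


def survival_recovery(seed: int, n_sims: int = 20) -> dict:
    """Cutpoint and hazard-ratio recovery at planted HR 2 (60th
    percentile split, n = 300) and null coverage of the continuous-score
    Cox fit.

    The recovery arm emulates two clearly separated risk groups in a
    mature-follow-up cohort (15% censoring); the null arm uses the
    cohort default.
    """
    seeds = _child_seeds(seed, 2 * n_sims)
    cut_hits = hr_cover = 0
    for s in seeds[:n_sims]:
        co = simulate_survival_cohort(
            SurvivalConfig(n=300, cut_quantile=0.6, hr_group=2.0, censoring=0.15),
            seed=int(s),
        )
        score = co.scores["z_LE"]
        cut = optimal_cutpoint(score, co.time, co.event)
        cut_hits += abs(float((score <= cut).mean()) - 0.6) <= 0.10
        fit = fit_signature_survival(score, co.time, co.event)
        hr_cover += fit.cox.ci_low <= 2.0 <= fit.cox.ci_high
    null_cover = 0
    for s in seeds[n_sims:]:
        co = simulate_survival_cohort(SurvivalConfig(n=300), seed=int(s))
        fit = cox_fit(co.scores["z_LE"], co.time, co.event)
        null_cover += fit.ci_low <= 1.0 <= fit.ci_high
    return {
        "cutpoint_recovery_rate": cut_hits / n_sims,
        "hr_coverage_rate": hr_cover / n_sims,
        "null_coverage_rate": null_cover / n_sims,
        "n": n_sims,
    }


def statistic_oracles(seed: int) -> dict:
    """Agreement of the shared statistical primitives with independent
    brute-force oracles."""
    from itertools import combinations
    from math import comb

    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    from ._stats import benjamini_hochberg, bonferroni, rank_sum_test, trimmed_mean
    from .lattice import generate_hex_lattice, neighbor_table

    rng = np.random.default_rng(seed)
    # rank-sum vs exact enumeration, n <= 8 per group
    ranksum_ok = True
    for _ in range(20):
        nx, ny = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        x = rng.integers(0, 6, nx).astype(float)
        y = rng.integers(0, 6, ny).astype(float)
        _, p = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = nx * (pooled.size + 1) / 2
        w_obs = ranks[:nx].sum()
        hits = sum(
            abs(ranks[list(idx)].sum() - mu) >= abs(w_obs - mu) - 1e-12
            for idx in combinations(range(pooled.size), nx)
        )
        ranksum_ok &= np.isclose(p, hits / comb(pooled.size, nx))
    # multiple-testing corrections vs reference implementations
    p = rng.uniform(size=50)
    bh_ok = np.allclose(benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1])
    bonf_ok = np.allclose(bonferroni(p), np.minimum(1, p * p.size))
    # trimmed mean vs sort-and-drop
    trim_ok = True
    for _ in range(200):
        n = int(rng.integers(1, 50))
        v = rng.uniform(size=n)
        k = int(np.floor(0.1 * n))
        trim_ok &= np.isclose(trimmed_mean(v), np.mean(np.sort(v)[k : n - k]))
    # hex adjacency vs pairwise-distance brute force
    lat = generate_hex_lattice(12, 12)
    table = neighbor_table(lat)
    hex_ok = True
    pos = lat[["array_row", "array_col"]].to_numpy()
    for i, sid in enumerate(lat.index):
        expected = {
            lat.index[j]
            for j in range(len(lat))
            if j != i
            and (pos[j, 1] - pos[i, 1]) ** 2 + 3 * (pos[j, 0] - pos[i, 0]) ** 2 == 4
        }
        hex_ok &= set(table[sid]) == expected
    return {
        "all_pass": bool(ranksum_ok and bh_ok and bonf_ok and trim_ok and hex_ok),
        "ranksum_exact": bool(ranksum_ok),
        "bh": bool(bh_ok),
        "bonferroni": bool(bonf_ok),
        "trimmed_mean": bool(trim_ok),
        "hex_adjacency": bool(hex_ok),
        "n": 4,
    }
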