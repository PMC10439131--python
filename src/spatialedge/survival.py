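"""Prognostic analysis of signature scores: maximally selected log-rank
cutpoints, Kaplan–Meier curves, proportional-hazards fits, and score
correlations.

The optimal cutpoint maximizes the absolute standardized log-rank
statistic over all candidate thresholds that leave at least a
``minprop`` fraction of patients on each side.  Hazard ratios and
p-values for the resulting dichotomy come from a Cox proportional-
hazards fit (Efron tie handling); note that the cutpoint selection is
not corrected for, so the downstream p-value is optimistic — the
selection-bias caveat applies to any maximally selected split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


def logrank_z(time, event, group) -> float:
    """Standardized two-group log-rank statistic (O - E over sqrt V for
    group 1, hypergeometric variance)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order]
    o_minus_e = 0.0
    var = 0.0
    n = time.size
    at_risk_total = n
    at_risk_g1 = int(group.sum())
    i = 0
    while i < n:
        j = i
        d = d1 = 0
        removed = removed_g1 = 0
        while j < n and time[j] == time[i]:
            d += event[j]
            d1 += event[j] * group[j]
            removed += 1
            removed_g1 += int(group[j])
            j += 1
        if d > 0 and at_risk_total > 1:
            e1 = d * at_risk_g1 / at_risk_total
            v = (
                d
                * (at_risk_g1 / at_risk_total)
                * (1 - at_risk_g1 / at_risk_total)
                * (at_risk_total - d)
                / (at_risk_total - 1)
            )
            o_minus_e += d1 - e1
            var += v
        at_risk_total -= removed
        at_risk_g1 -= removed_g1
        i = j
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


def optimal_cutpoint(score, time, event, minprop: float = 0.2) -> float:
    """Maximally selected log-rank cutpoint.

    Candidates are the unique score values whose induced split (high =
    score > c) leaves at least ``ceil(minprop * n)`` patients on each
    side; the candidate maximizing |z| wins, ties going to the smaller
    cutpoint.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = score.size
    lo = int(np.ceil(minprop * n))
    uniq = np.unique(score)
    best_c, best_z = None, -1.0
    for c in uniq:
        high = score > c
        n_high = int(high.sum())
        if n_high < lo or n - n_high < lo:
            continue
        z = abs(logrank_z(time, event, high))
        if z > best_z + 1e-12:
            best_z, best_c = z, float(c)
    if best_c is None:
        raise ValueError("no candidate cutpoint satisfies the minimum proportion")
    return best_c


def km_estimator(time, event, group=None) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier product-limit estimate per group.

    Returns ``{group_label: DataFrame(time, survival)}`` step tables;
    with ``group=None`` a single "all" curve.
    """
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise ValueError("negative survival times")
    event = np.asarray(event, dtype=int)
    if group is None:
        group = np.zeros(time.size, dtype=int)
        names = {0: "all"}
    else:
        group = np.asarray(group)
        names = {g: str(g) for g in np.unique(group)}
    out = {}
    for g, name in names.items():
        m = group == g
        if m.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        sf = kmf.survival_function_
        out[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def cox_fit(x, time, event) -> CoxResult:
    """Cox proportional-hazards fit of survival on one covariate
    (binary group indicator or continuous score), Efron tie handling.

    Monotone-likelihood / separation failures are raised with context
    rather than returned silently.
    """
    x = np.asarray(x, dtype=float)
    df = pd.DataFrame(
        {"x": x, "time": np.asarray(time, dtype=float), "event": np.asarray(event, dtype=int)}
    )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            "Cox fit did not converge (possibly monotone likelihood / "
            "complete separation)"
        ) from err
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    ci = cph.confidence_intervals_.loc["x"]
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p=float(cph.summary.loc["x", "p"]),
        coef=coef,
        se=se,
    )


@dataclass
class SurvivalFit:
    """Cutpoint-stratified survival analysis of one signature score."""

    cutpoint: float
    groups: pd.Series
    cox: CoxResult
    km: dict[str, pd.DataFrame]


def fit_signature_survival(
    score, time, event, minprop: float = 0.2
) -> SurvivalFit:
    """Cutpoint selection, high/low stratification, Cox fit and KM
    curves for one signature score."""
    score = pd.Series(score)
    cut = optimal_cutpoint(score.to_numpy(), time, event, minprop=minprop)
    groups = pd.Series(
        np.where(score > cut, "high", "low"), index=score.index, name="group"
    )
    cox = cox_fit((groups == "high").astype(float), time, event)
    km = km_estimator(np.asarray(time), np.asarray(event), groups.to_numpy())
    return SurvivalFit(cutpoint=cut, groups=groups, cox=cox, km=km)


def score_correlation(z_a, z_b) -> tuple[float, float]:
    """Pearson correlation of two score vectors with the two-sided
    t-test p-value."""
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.size != b.size:
        raise ValueError("score vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance score vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
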