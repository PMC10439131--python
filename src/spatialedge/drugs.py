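"""Drug-response aggregation and the in-silico perturbation screen.

Drug sensitivity is summarized as the area above the dose-response
curve (AAC, in [0, 1], higher = more effective).  Per drug, AAC values
are first averaged across datasets within each cell line and then
condensed to a 10% trimmed mean across cell lines; drugs profiled in
fewer than 25 cell lines are excluded.  Interaction keywords map each
drug target to an expected expression direction; targets without
directional information are removed.  The screen perturbs every
retained drug's targets in silico (M = -200 for down-regulated, +200
for up-regulated genes), rebuilds the fate-transition state graph, and
compares the edge-outgoing and core-incoming flow signatures between
drugs with above-median ("high") and below-median ("low") AAC by a
two-sided rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test, trimmed_mean
from .simulate import DOWN_KEYWORDS, UP_KEYWORDS, DrugRecord
from .velocity import PerturbationEngine, PerturbationSpec, StateGraph

_UP = {k.lower() for k in UP_KEYWORDS}
_DOWN = {k.lower() for k in DOWN_KEYWORDS}


def map_interaction_direction(keyword: str) -> str:
    """Map an interaction keyword to "up", "down" or "none"
    (exact, case-insensitive membership in the two keyword lists)."""
    kw = str(keyword).strip().lower()
    if kw in _UP:
        return "up"
    if kw in _DOWN:
        return "down"
    return "none"


def aggregate_aac(
    record: DrugRecord, min_cell_lines: int = 25, trim: float = 0.1
) -> float | None:
    """Aggregate a drug's raw AAC table to one value.

    Step 1: mean across datasets within each cell line; step 2:
    symmetric ``trim`` trimmed mean across cell lines.  Returns None
    (exclusion, not an error) below the cell-line threshold.
    """
    per_line = record.aac.groupby("cell_line", observed=True)["aac"].mean()
    if per_line.size < min_cell_lines:
        record.aggregated_aac = None
        return None
    record.aggregated_aac = trimmed_mean(per_line.to_numpy(), trim=trim)
    return record.aggregated_aac


def stratify_by_median(records: list[DrugRecord]) -> pd.Series:
    """Label drugs "high" (AAC > median) or "low" (otherwise; values
    exactly at the median fall in "low")."""
    kept = [r for r in records if r.aggregated_aac is not None]
    if len(kept) < 2:
        raise ValueError("need at least two drugs with aggregated AAC")
    values = np.array([r.aggregated_aac for r in kept])
    if np.allclose(values, values[0]):
        raise ValueError("all aggregated AAC values identical")
    med = float(np.median(values))
    labels = {}
    for r in kept:
        r.group = "high" if r.aggregated_aac > med else "low"
        labels[r.drug_id] = r.group
    return pd.Series(labels, name="group")


@dataclass
class ScreenResult:
    """Outcome of an in-silico drug screen on one sample."""

    table: pd.DataFrame            # per retained drug
    stats: pd.DataFrame            # per flow signature: W statistic, p
    baseline: StateGraph
    excluded: list[str]


def run_screen(
    engine: PerturbationEngine,
    records: list[DrugRecord],
    min_cell_lines: int = 25,
    trim: float = 0.1,
    magnitude: float = 200.0,
) -> ScreenResult:
    """In-silico perturbation screen over a drug panel.

    Per drug: map target keywords to directions (dropping "none"),
    drop targets without expression, perturb, record edge-outgoing and
    core-incoming signatures; then stratify by median aggregated AAC
    and compare high vs low groups per signature.
    """
    baseline = engine.baseline_graph()
    retained, excluded = [], []
    for rec in records:
        if aggregate_aac(rec, min_cell_lines=min_cell_lines, trim=trim) is None:
            excluded.append(rec.drug_id)
            continue
        directions = {}
        for gene, kw in rec.targets:
            d = map_interaction_direction(kw)
            if d != "none":
                directions[gene] = d
        rec.direction = directions
        expressed = engine.expressed_targets(list(directions))
        if not expressed:
            excluded.append(rec.drug_id)
            continue
        spec = PerturbationSpec.from_directions(
            {g: directions[g] for g in expressed}, magnitude=magnitude
        )
        graph = engine.perturbed_graph(spec)
        retained.append(
            {
                "drug_id": rec.drug_id,
                "aggregated_aac": rec.aggregated_aac,
                "n_targets": len(expressed),
                "edge_outgoing": graph.edge_outgoing,
                "core_incoming": graph.core_incoming,
                "_record": rec,
            }
        )
    if not retained:
        raise ValueError("no drugs retained by the screen filters")
    table = pd.DataFrame(retained)
    groups = stratify_by_median([row["_record"] for row in retained])
    table["group"] = table["drug_id"].map(groups)
    table = table.drop(columns="_record").set_index("drug_id")

    rows = []
    for sig in ("edge_outgoing", "core_incoming"):
        hi = table.loc[table["group"] == "high", sig]
        lo = table.loc[table["group"] == "low", sig]
        if hi.empty or lo.empty:
            warnings.warn(f"one AAC group empty; skipping {sig} comparison")
            continue
        w, p = rank_sum_test(hi, lo)
        rows.append(
            {
                "signature": sig,
                "statistic": w,
                "pval": p,
                "mean_high": hi.mean(),
                "mean_low": lo.mean(),
                "baseline": getattr(baseline, sig),
            }
        )
    return ScreenResult(
        table=table,
        stats=pd.DataFrame(rows).set_index("signature"),
        baseline=baseline,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# mechanism-of-action classes

def levenshtein(a: str, b: str) -> int:
    """Edit distance (insert/delete/substitute, unit costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def drug_classes(mechanisms: pd.Series, max_distance: int = 3) -> pd.Series:
    """Group drugs by mechanism-of-action strings, merging strings
    within Levenshtein distance ``max_distance``; only groups with more
    than one drug form a class (others get NA)."""
    mechs = mechanisms.dropna().astype(str)
    canon: list[str] = []
    mapping = {}
    for m in mechs.unique():
        match = next(
            (c for c in canon if levenshtein(m.lower(), c.lower()) <= max_distance),
            None,
        )
        if match is None:
            canon.append(m)
            match = m
        mapping[m] = match
    assigned = mechs.map(mapping)
    counts = assigned.value_counts()
    keep = counts[counts > 1].index
    out = assigned.where(assigned.isin(keep))
    return out.reindex(mechanisms.index)


def compare_classes(values: pd.Series, classes: pd.Series) -> tuple[float, float]:
    """Kruskal–Wallis test of a flow signature across drug classes."""
    joined = pd.DataFrame({"value": values, "class": classes}).dropna()
    groups = [g["value"].to_numpy() for _, g in joined.groupby("class", observed=True)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least two drug classes")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)
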