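import numpy as np
import pandas as pd
import pytest

import spatialedge as se
from spatialedge.drugs import compare_classes, drug_classes, levenshtein
from spatialedge.simulate import DrugRecord, DrugScreenConfig


def record(aac_values, targets=(), cell_lines=None, datasets=None, drug_id="d0"):
    rows = []
    for i, v in enumerate(aac_values):
        cl = cell_lines[i] if cell_lines else f"CL{i}"
        ds = datasets[i] if datasets else "DS0"
        rows.append((cl, ds, v))
    return DrugRecord(
        drug_id=drug_id,
        aac=pd.DataFrame(rows, columns=["cell_line", "dataset", "aac"]),
        targets=list(targets),
    )


class TestKeywordMapping:
    @pytest.mark.parametrize(
        "keyword,expected",
        [
            ("inhibitor", "down"),
            ("antagonist", "down"),
            ("inverse agonist", "down"),
            ("partial agonist", "up"),
            ("activator", "up"),
            ("Potentiator", "up"),
            ("  INHIBITOR ", "down"),
            ("binder", "none"),
            ("ligand", "none"),
            ("", "none"),
        ],
    )
    def test_mapping(self, keyword, expected):
        assert se.map_interaction_direction(keyword) == expected


class TestAggregation:
    def test_single_value_identity(self):
        rec = record([0.3])
        assert se.aggregate_aac(rec, min_cell_lines=1) == pytest.approx(0.3)

    def test_trimmed_mean_sort_and_drop(self):
        rec = record(np.arange(10) / 10)
        # drop 0.0 and 0.9, mean of the rest = 0.45
        assert se.aggregate_aac(rec, min_cell_lines=1) == pytest.approx(0.45)

    def test_dataset_averaging_within_cell_line(self):
        rec = record(
            [0.2, 0.4, 0.6],
            cell_lines=["A", "A", "B"],
            datasets=["DS0", "DS1", "DS0"],
        )
        # cell line A -> 0.3, B -> 0.6 -> mean 0.45 (no trim at n=2)
        assert se.aggregate_aac(rec, min_cell_lines=1) == pytest.approx(0.45)

    def test_cell_line_threshold_excludes(self):
        rec = record(np.linspace(0.1, 0.9, 24))
        assert se.aggregate_aac(rec) is None  # 24 < 25
        rec25 = record(np.linspace(0.1, 0.9, 25))
        assert se.aggregate_aac(rec25) is not None

    @pytest.mark.parametrize("seed", range(20))
    def test_fuzz_against_sort_and_drop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            vals = rng.uniform(size=n)
            rec = record(vals)
            got = se.aggregate_aac(rec, min_cell_lines=1)
            k = int(np.floor(0.1 * n))
            expected = float(np.mean(sorted(vals)[k : n - k]))
            assert got == pytest.approx(expected)


class TestStratify:
    def test_odd_n_median_element_goes_low(self):
        recs = [record([v], drug_id=f"d{i}") for i, v in enumerate([0.1, 0.2, 0.3])]
        for r in recs:
            se.aggregate_aac(r, min_cell_lines=1)
        groups = se.stratify_by_median(recs)
        assert groups.to_dict() == {"d0": "low", "d1": "low", "d2": "high"}

    def test_even_n_median_interpolated(self):
        recs = [
            record([v], drug_id=f"d{i}") for i, v in enumerate([0.1, 0.2, 0.3, 0.4])
        ]
        for r in recs:
            se.aggregate_aac(r, min_cell_lines=1)
        groups = se.stratify_by_median(recs)
        assert groups.to_dict() == {
            "d0": "low", "d1": "low", "d2": "high", "d3": "high"
        }

    def test_identical_values_degenerate(self):
        recs = [record([0.5], drug_id=f"d{i}") for i in range(3)]
        for r in recs:
            se.aggregate_aac(r, min_cell_lines=1)
        with pytest.raises(ValueError):
            se.stratify_by_median(recs)


class TestScreen:
    def test_all_none_targets_excluded(self, engine, annotated):
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        good = record(
            np.linspace(0.1, 0.5, 30),
            targets=[(drivers[0], "inhibitor")],
            drug_id="good",
        )
        inert = record(
            np.linspace(0.2, 0.6, 30),
            targets=[(drivers[1], "binder")],
            drug_id="inert",
        )
        other = record(
            np.linspace(0.3, 0.7, 30),
            targets=[(drivers[2], "activator")],
            drug_id="other",
        )
        res = se.run_screen(engine, [good, inert, other])
        assert "inert" in res.excluded
        assert set(res.table.index) == {"good", "other"}

    def test_unmeasured_target_drug_excluded(self, engine):
        ghost = record(
            np.linspace(0.1, 0.5, 30), targets=[("NOT_A_GENE", "inhibitor")],
            drug_id="ghost",
        )
        anchor = record(
            np.linspace(0.2, 0.6, 30), targets=[("LAMC2", "inhibitor")],
            drug_id="anchor",
        )
        anchor2 = record(
            np.linspace(0.1, 0.3, 30), targets=[("ITGA5", "inhibitor")],
            drug_id="anchor2",
        )
        res = se.run_screen(engine, [ghost, anchor, anchor2])
        assert "ghost" in res.excluded
        assert set(res.table.index) == {"anchor", "anchor2"}

    def test_planted_effect_detected_and_concordant(self, engine, annotated):
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        decoys = annotated.uns["gene_sets"]["housekeeping"]
        records, truth = se.simulate_drug_screen(
            DrugScreenConfig(effect=0.2), drivers, decoys, seed=0
        )
        res = se.run_screen(engine, records)
        assert res.stats.loc["edge_outgoing", "pval"] < 0.05
        assert (
            res.stats.loc["edge_outgoing", "mean_high"]
            > res.stats.loc["edge_outgoing", "mean_low"]
        )
        merged = res.table.join(truth.set_index("drug_id"))
        concordance = ((merged["group"] == "high") == merged["reversing"]).mean()
        assert concordance >= 0.8

    def test_no_retained_drugs_raises(self, engine):
        rec = record([0.5], targets=[("LAMC2", "inhibitor")])  # 1 < 25 lines
        with pytest.raises(ValueError):
            se.run_screen(engine, [rec])

    def test_drug_order_irrelevant(self, engine, annotated):
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        records, _ = se.simulate_drug_screen(
            DrugScreenConfig(n_drugs=10), drivers,
            annotated.uns["gene_sets"]["housekeeping"], seed=3,
        )
        r1 = se.run_screen(engine, records)
        r2 = se.run_screen(engine, records[::-1])
        assert r1.table.sort_index().equals(r2.table.sort_index())
        assert np.allclose(r1.stats["pval"], r2.stats["pval"])


class TestDrugClasses:
    @pytest.mark.parametrize(
        "a,b,d",
        [("kitten", "sitting", 3), ("abc", "abc", 0), ("", "abc", 3), ("ab", "ba", 2)],
    )
    def test_levenshtein(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_fuzzy_mechanism_grouping(self):
        mech = pd.Series(
            {
                "d0": "EGFR inhibitor",
                "d1": "EGFR inhibitr",   # distance 1: merges
                "d2": "EGFR inhibitors",  # distance 1: merges
                "d3": "proteasome blocker",  # singleton: dropped
            }
        )
        classes = drug_classes(mech)
        assert classes["d0"] == classes["d1"] == classes["d2"]
        assert pd.isna(classes["d3"])

    def test_kruskal_across_classes(self):
        rng = np.random.default_rng(0)
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)]),
            index=[f"d{i}" for i in range(20)],
        )
        classes = pd.Series(
            ["A"] * 10 + ["B"] * 10, index=values.index
        )
        stat, p = compare_classes(values, classes)
        assert p < 0.01
        with pytest.raises(ValueError):
            compare_classes(values, pd.Series("A", index=values.index))
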