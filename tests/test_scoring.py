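import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spatialedge as se
from spatialedge._stats import benjamini_hochberg


@pytest.fixture(scope="module")
def expr():
    """48 genes in 24 pairs of identical profiles (two genes per mean
    bin), 60 spots."""
    rng = np.random.default_rng(0)
    cols = {}
    for pair in range(24):
        profile = rng.normal(1.0 + 0.2 * pair, 0.3, size=60).clip(min=0)
        cols[f"a{pair:02d}"] = profile
        cols[f"b{pair:02d}"] = profile.copy()
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(60)])


class TestModuleScore:
    def test_bin_matched_signature_scores_zero(self, expr):
        # each signature gene's bin partner has the identical profile,
        # so every control draw reproduces the signature exactly
        sig = [f"a{p:02d}" for p in range(0, 24, 3)]
        score = se.module_score(expr, sig, n_bins=24, seed=0)
        assert np.allclose(score, 0.0, atol=1e-12)

    def test_shifted_spots_score_higher_by_the_shift(self):
        rng = np.random.default_rng(1)
        n_genes, n_spots, c = 300, 120, 0.7
        X = pd.DataFrame(
            rng.normal(0, 0.2, (n_spots, n_genes))
            + rng.uniform(0.5, 4.0, n_genes)[None, :],
            columns=[f"g{j}" for j in range(n_genes)],
        ).clip(lower=0)
        sig = [f"g{j}" for j in range(0, 300, 30)]
        shifted = X.copy()
        shifted.iloc[:60, [X.columns.get_loc(g) for g in sig]] += c
        score = se.module_score(shifted, sig, seed=0)
        assert score[:60].mean() - score[60:].mean() == pytest.approx(c, rel=0.15)

    def test_same_seed_reproducible_and_linear_in_expression(self, expr):
        sig = ["a01", "a05", "b09"]
        s1 = se.module_score(expr, sig, seed=3)
        s2 = se.module_score(expr, sig, seed=3)
        assert s1.equals(s2)
        s3 = se.module_score(expr * 2.5, sig, seed=3)
        assert np.allclose(s3, 2.5 * s1)

    def test_missing_genes_warn_empty_set_raises(self, expr):
        with pytest.warns(UserWarning):
            se.module_score(expr, ["a01", "NOT_A_GENE"], seed=0)
        with pytest.raises(ValueError):
            se.module_score(expr, ["NOPE"], seed=0)


class TestSignedScore:
    def test_up_equals_down_cancels_exactly(self, expr):
        sig = ["a02", "b07"]
        score = se.signed_score(expr, sig, sig, seed=1)
        assert (score == 0).all()

    def test_empty_down_set_equals_module_score(self, expr):
        sig = ["a03", "a11"]
        assert se.signed_score(expr, sig, [], seed=2).equals(
            se.module_score(expr, sig, seed=2)
        )

    def test_antisymmetry(self, expr):
        up, down = ["a01", "a04"], ["b10", "b20"]
        fwd = se.signed_score(expr, up, down, seed=5)
        rev = se.signed_score(expr, down, up, seed=5)
        assert np.allclose(fwd, -rev)

    def test_le_planted_signature_separates_regions(self, annotated):
        up = annotated.uns["gene_sets"]["edge_program"][:10]
        down = annotated.uns["gene_sets"]["core_program"][:10]
        score = se.signed_score(annotated, up, down, seed=0)
        region = annotated.obs["region"]
        assert score[region == "LE"].mean() > score[region == "TC"].mean()


class TestRankScore:
    def test_extreme_sets_hit_bounds(self):
        expr = pd.Series(np.arange(100, dtype=float), index=[f"g{j}" for j in range(100)])
        top = [f"g{j}" for j in range(95, 100)]
        bottom = [f"g{j}" for j in range(5)]
        assert se.rank_score(expr, top) == pytest.approx(0.5)
        assert se.rank_score(expr, bottom) == pytest.approx(-0.5)

    def test_random_sets_center_on_zero(self):
        rng = np.random.default_rng(2)
        expr = pd.Series(rng.normal(size=2000), index=[f"g{j}" for j in range(2000)])
        scores = []
        for _ in range(1000):
            genes = rng.choice(expr.index, 50, replace=False)
            scores.append(se.rank_score(expr, list(genes)))
        scores = np.array(scores)
        se_mean = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean()) <= 3 * se_mean

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        expr = pd.Series(rng.normal(size=500), index=[f"g{j}" for j in range(500)])
        genes = [f"g{j}" for j in range(0, 500, 25)]
        assert se.rank_score(expr, genes) == se.rank_score(np.exp(expr), genes)

    def test_frame_version_matches_scalar(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(
            rng.normal(size=(5, 200)), columns=[f"g{j}" for j in range(200)]
        )
        genes = [f"g{j}" for j in range(40, 60)]
        got = se.rank_score_frame(frame, genes)
        for i in range(5):
            assert got.iloc[i] == pytest.approx(se.rank_score(frame.iloc[i], genes))

    def test_oversized_set_raises(self):
        expr = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            se.rank_score(expr, ["a", "b", "c", "d"])
        # the full transcriptome pins the central mean rank
        assert se.rank_score(expr, ["a", "b", "c"]) == 0.0


class TestCompareRegionScores:
    def long_frame(self, rng, shift=0.0, n_samples=12, n_spots=30, within_sd=0.3):
        rows = []
        for s in range(n_samples):
            base = rng.normal(0, 1.0)
            for reg, delta in (("TC", 0.0), ("LE", shift)):
                vals = base + delta + rng.normal(0, within_sd, n_spots)
                rows += [
                    {"sample": f"s{s}", "region": reg, "score": v} for v in vals
                ]
        return pd.DataFrame(rows)

    def test_identical_scores_give_p_one(self):
        df = pd.DataFrame(
            {
                "sample": ["s1"] * 10 + ["s2"] * 10,
                "region": (["TC"] * 5 + ["LE"] * 5) * 2,
                "score": [1.0] * 20,
            }
        )
        out = se.compare_region_scores(df, paired_by_sample=True)
        assert out["pval"].iloc[0] == 1.0
        out2 = se.compare_region_scores(df, paired_by_sample=False)
        assert out2["pval"].iloc[0] == 1.0

    def test_paired_power_one_sd_shift_across_12_samples(self):
        # shift = one between-sample SD; pairing removes that SD
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            df = self.long_frame(rng, shift=1.0)
            out = se.compare_region_scores(df, paired_by_sample=True)
            hits += out["padj"].iloc[0] < 0.05
        assert hits >= 18

    def test_bh_step_up_hand_computation(self):
        # (0.01, 0.02, 0.03, 0.04) -> p * 4/k = (.04,.04,.04,.04)
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        # a second hand-worked case with a non-monotone raw sequence:
        # sorted adj (0.006, 0.045, 0.04) -> step-up monotonized to
        # (0.006, 0.04, 0.04)
        assert np.allclose(
            benjamini_hochberg([0.03, 0.002, 0.04]),
            [0.04, 0.006, 0.04],
        )
        # independent oracle on random p-values
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        assert np.allclose(
            benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_unmatched_samples_raise_in_paired_mode(self):
        df = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s2"],
                "region": ["TC", "LE", "TC"],
                "score": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            se.compare_region_scores(df, paired_by_sample=True)
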