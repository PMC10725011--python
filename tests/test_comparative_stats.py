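import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tndiva.comparative_stats import (
    compare,
    consensus,
    log2_fold_change,
    mean_ed_by_condition,
    regression_cooks,
    run_subset_analyses,
    welch_test,
)
from tndiva.errors import ValidationError
from tndiva.formats_io import SampleSheet


def make_div(ed_matrix: np.ndarray, samples: list[str]) -> pd.DataFrame:
    """Tidy diversity frame from a genes x samples ED matrix."""
    rows = []
    for g in range(ed_matrix.shape[0]):
        for j, s in enumerate(samples):
            rows.append(
                {"locus_tag": f"g{g:03d}", "sample_id": s, "S": 1,
                 "H": 0.0, "D_eff": ed_matrix[g, j], "ED": ed_matrix[g, j], "L": 1}
            )
    return pd.DataFrame(rows)


def make_sheet(n_a=3, n_b=3):
    rows = [
        {"sample_id": f"A{i}", "condition": "ref", "mapped_fraction": 0.95, "include": True}
        for i in range(n_a)
    ] + [
        {"sample_id": f"B{i}", "condition": "trt", "mapped_fraction": 0.95, "include": True}
        for i in range(n_b)
    ]
    return SampleSheet(pd.DataFrame(rows))


class TestMeanEdByCondition:
    def test_arithmetic_means(self):
        ed = np.array([[0.4, 0.6, 0.3, 0.1], [0.2, 0.2, 0.5, 0.7]])
        div = make_div(ed, ["A0", "A1", "B0", "B1"])
        means = mean_ed_by_condition(div, make_sheet(2, 2))
        assert means["mean_ED_A"].tolist() == [0.5, 0.2]
        assert means["mean_ED_B"].tolist() == [0.2, 0.6]

    def test_single_replicate_condition_warns(self, caplog):
        ed = np.array([[0.4, 0.3, 0.1]])
        div = make_div(ed, ["A0", "B0", "B1"])
        with caplog.at_level("WARNING"):
            means = mean_ed_by_condition(div, make_sheet(1, 2))
        assert means["mean_ED_A"].iloc[0] == 0.4
        assert "single replicate" in caplog.text

    def test_random_matrix_matches_direct_recomputation(self, rng):
        ed = rng.random((30, 6))
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        means = mean_ed_by_condition(make_div(ed, samples), make_sheet())
        assert np.allclose(means["mean_ED_A"], ed[:, :3].mean(axis=1))
        assert np.allclose(means["mean_ED_B"], ed[:, 3:].mean(axis=1))


class TestLog2FoldChange:
    def test_exact_twofold_is_boundary_not_hit(self):
        out = log2_fold_change(np.array([0.5]), np.array([0.25]))
        assert out["log2FC"].iloc[0] == pytest.approx(1.0)
        assert not out["log2fc_hit"].iloc[0]
        assert out["direction"].iloc[0] == "lower_in_B"

    def test_equal_means_no_signal(self):
        out = log2_fold_change(np.array([0.3]), np.array([0.3]))
        assert out["log2FC"].iloc[0] == 0.0
        assert not out["log2fc_hit"].iloc[0]
        assert out["direction"].iloc[0] == "none"

    def test_reported_condition_means_fall_below_cutoff(self):
        # condition means of a known real influential gene: a ~1.8-fold ED
        # drop is a Cook's/Welch candidate but not a fold-change hit
        out = log2_fold_change(np.array([0.518163423]), np.array([0.286886804]))
        assert out["log2FC"].iloc[0] == pytest.approx(
            math.log2(0.518163423 / 0.286886804), abs=1e-12
        )
        assert out["log2FC"].iloc[0] == pytest.approx(0.8530, abs=5e-4)
        assert not out["log2fc_hit"].iloc[0]

    def test_zero_means_give_signed_infinities(self):
        out = log2_fold_change(np.array([0.5, 0.0, 0.0]), np.array([0.0, 0.5, 0.0]))
        assert out["log2FC"].tolist() == [np.inf, -np.inf, 0.0]
        assert out["log2fc_hit"].tolist() == [True, True, False]
        assert out["direction"].tolist() == ["lower_in_B", "lower_in_A", "none"]

    def test_negative_mean_rejected(self):
        with pytest.raises(ValidationError):
            log2_fold_change(np.array([-0.1]), np.array([0.2]))


def loo_cooks_oracle(x, y):
    """Leave-one-out refit definition of Cook's distance."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    mse = np.sum((y - fitted) ** 2) / (n - 2)
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta_i, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        out[i] = np.sum((fitted - X @ beta_i) ** 2) / (2 * mse)
    return out


class TestRegressionCooks:
    def test_perfect_fit_zero_distances(self):
        x = np.linspace(0.1, 1.0, 20)
        reg = regression_cooks(x, x)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert np.all(reg.cooks_d < 1e-20)
        assert not reg.influential.any()

    def test_displaced_point_flagged(self):
        x = np.linspace(0.1, 1.0, 20)
        y = 0.5 * x + 0.1
        y[7] += 1.5
        reg = regression_cooks(x, y)
        assert reg.influential[7]
        assert reg.cooks_d[7] > 4 / 20
        others = np.delete(reg.cooks_d, 7)
        assert others.max() < reg.cooks_d[7] / 10

    def test_matches_leave_one_out_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 80))
            x = rng.random(n)
            y = 0.6 * x + 0.05 + rng.normal(0, 0.1, n)
            reg = regression_cooks(x, y)
            oracle = loo_cooks_oracle(x, y)
            assert np.allclose(reg.cooks_d, oracle, atol=1e-9, rtol=1e-9)

    def test_matches_statsmodels_influence(self, rng):
        import statsmodels.api as sm

        x = rng.random(60)
        y = 0.8 * x + rng.normal(0, 0.05, 60)
        reg = regression_cooks(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        sm_cooks = fit.get_influence().cooks_distance[0]
        assert np.allclose(reg.cooks_d, sm_cooks, rtol=1e-9)
        assert reg.adj_r2 == pytest.approx(fit.rsquared_adj, rel=1e-9)

    def test_infinite_means_excluded_but_tracked(self, rng):
        x = np.concatenate([rng.random(30), [np.inf]])
        y = np.concatenate([rng.random(30), [0.5]])
        reg = regression_cooks(x, y)
        assert reg.n == 30
        assert not reg.finite_mask[-1]

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValidationError):
            regression_cooks(np.full(20, 0.3), np.linspace(0, 1, 20))


class TestWelch:
    def test_hand_worked_example(self):
        ed = np.zeros((1, 5))
        ed[0, :3] = [0.5, 0.52, 0.48]
        ed[0, 3:] = [0.3, 0.28]
        div = make_div(ed, ["A0", "A1", "A2", "B0", "B1"])
        out = welch_test(div, make_sheet(3, 2))
        assert out["welch_t"].iloc[0] == pytest.approx(13.748, abs=1e-2)
        assert out["welch_df"].iloc[0] == pytest.approx(2.882, abs=1e-2)

    def test_identical_groups_give_t_zero_p_one(self):
        ed = np.array([[0.4, 0.5, 0.4, 0.5]])
        div = make_div(ed, ["A0", "A1", "B0", "B1"])
        out = welch_test(div, make_sheet(2, 2))
        assert out["welch_t"].iloc[0] == 0.0
        assert out["welch_p"].iloc[0] == 1.0

    def test_swapping_groups_negates_t(self, rng):
        ed = rng.random((10, 6))
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        fwd = welch_test(make_div(ed, samples), make_sheet())
        swapped = make_div(ed[:, [3, 4, 5, 0, 1, 2]], samples)
        rev = welch_test(swapped, make_sheet())
        assert np.allclose(fwd["welch_t"], -rev["welch_t"])
        assert np.allclose(fwd["welch_p"], rev["welch_p"])

    def test_matches_scipy_reference(self, rng):
        ed = rng.random((200, 8))
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        out = welch_test(make_div(ed, samples), make_sheet(4, 4))
        ref = sps.ttest_ind(ed[:, :4], ed[:, 4:], axis=1, equal_var=False)
        assert np.allclose(out["welch_t"], ref.statistic, atol=1e-10)
        assert np.allclose(out["welch_p"], ref.pvalue, atol=1e-10)
        assert np.allclose(out["welch_df"], ref.df, atol=1e-10)

    def test_degenerate_zero_variance_flagged(self):
        ed = np.array([[0.4, 0.4, 0.4, 0.4], [0.4, 0.4, 0.6, 0.6]])
        div = make_div(ed, ["A0", "A1", "B0", "B1"])
        out = welch_test(div, make_sheet(2, 2))
        assert out["degenerate"].tolist() == [True, True]
        assert out["welch_p"].tolist() == [1.0, 0.0]

    def test_sig01_implies_sig05(self, rng):
        ed = rng.random((100, 6)) * np.array([1, 1, 1, 0.5, 0.5, 0.5])
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        out = welch_test(make_div(ed, samples), make_sheet())
        assert (out["sig05"] | ~out["sig01"]).all()

    def test_too_few_replicates_rejected(self):
        ed = np.array([[0.4, 0.5, 0.3]])
        div = make_div(ed, ["A0", "B0", "B1"])
        with pytest.raises(ValidationError):
            welch_test(div, make_sheet(1, 2))


class TestCompareAndConsensus:
    @pytest.fixture
    def random_comparison(self, rng):
        n = 60
        base = rng.lognormal(-1.5, 0.5, size=n)
        ed_a = base[:, None] * rng.lognormal(0, 0.08, size=(n, 3))
        ed_b = base[:, None] * rng.lognormal(0, 0.08, size=(n, 3))
        ed_b[:5] *= 0.2  # strong depletion in a few genes
        ed = np.hstack([ed_a, ed_b])
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        return compare(make_div(ed, samples), make_sheet())

    def test_flag_consistency_invariants(self, random_comparison):
        res = random_comparison
        assert (res["sig05"] | ~res["sig01"]).all()
        assert (
            res["consensus_all3"]
            == (res["log2fc_hit"] & res["influential"] & res["sig05"])
        ).all()
        sign_ok = (
            (res["direction"] == "none") & (res["mean_ED_A"] == res["mean_ED_B"])
            | (res["direction"] == "lower_in_B") & (res["mean_ED_A"] > res["mean_ED_B"])
            | (res["direction"] == "lower_in_A") & (res["mean_ED_A"] < res["mean_ED_B"])
        )
        assert sign_ok.all()

    def test_depleted_block_is_recovered(self, random_comparison):
        res = random_comparison.set_index("locus_tag")
        depleted = [f"g{i:03d}" for i in range(5)]
        assert res.loc[depleted, "log2fc_hit"].all()
        assert res.loc[depleted, "sig05"].all()

    def test_consensus_sizes_match_brute_force(self, random_comparison):
        cons = consensus(random_comparison)
        res = random_comparison
        expected_all3 = set(
            res.loc[res["log2fc_hit"] & res["influential"] & res["sig05"], "locus_tag"]
        )
        assert cons["sets"]["all3"] == expected_all3
        assert cons["sizes"]["all3"] == len(expected_all3)
        for method in ("log2fc", "cooks", "welch05"):
            assert cons["sizes"][method] == len(cons["sets"][method])

    def test_disjoint_hit_sets_give_empty_intersections(self):
        res = pd.DataFrame(
            {
                "locus_tag": ["g1", "g2", "g3"],
                "log2fc_hit": [True, False, False],
                "influential": [False, True, False],
                "sig05": [False, False, True],
                "sig01": [False, False, False],
            }
        )
        cons = consensus(res)
        assert cons["sizes"]["all3"] == 0
        assert cons["sizes"]["cooks_welch"] == 0


class TestSubsetAnalyses:
    def test_identical_subsets_identical_results(self, rng):
        ed = rng.random((40, 8))
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        div = make_div(ed, samples)
        sheet = make_sheet(4, 4)
        results, overlap = run_subset_analyses(
            div, sheet, {"one": samples, "two": samples}
        )
        pd.testing.assert_frame_equal(results["one"], results["two"])
        assert (overlap["jaccard_distance"] == 0).all()

    def test_dropping_a_replicate_reports_overlap(self, rng):
        ed = rng.random((40, 8))
        ed[:4, 4:] *= 0.1
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        div = make_div(ed, samples)
        sheet = make_sheet(4, 4)
        results, overlap = run_subset_analyses(
            div, sheet, {"full": samples, "drop": samples[:-1]}
        )
        assert set(overlap["method"]) == {"log2fc", "cooks", "welch05", "welch01", "all3"}
        full_sets = consensus(results["full"])["sets"]
        drop_sets = consensus(results["drop"])["sets"]
        row = overlap[(overlap["method"] == "log2fc")].iloc[0]
        assert row["n_common"] == len(full_sets["log2fc"] & drop_sets["log2fc"])
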