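"""Double-entry design construction and the exchangeable GEE engine."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable
from statsmodels.genmod.generalized_estimating_equations import GEE

from icefalcon.gee import build_double_entry, fit_gee
from icefalcon.presets import calibrated_config, two_trait_config
from icefalcon.simulate import simulate_pairs

from conftest import SUITE_SEED, toy_scores


@pytest.fixture(scope="module")
def sim_scores():
    cfg = two_trait_config(
        300, causal_xy=0.4, confounder_x=0.5, confounder_y=0.4, familial_x=0.3,
        unique_x=0.7, unique_y=0.8, seed=SUITE_SEED,
    )
    return simulate_pairs(cfg)


class TestBuildDoubleEntry:
    def test_row_count_is_twice_pairs(self, study_scores):
        design = build_double_entry(study_scores, "light", "bright")
        assert design.n_pairs == 371
        assert len(design.frame) == 742

    def test_four_pair_fixture_matches_hand_expansion(self):
        scores = toy_scores(
            {"x": [(1.0, 2.0), (3.0, 4.0)], "y": [(5.0, 6.0), (7.0, 8.0)]}
        )
        design = build_double_entry(scores, "x", "y").frame
        # each twin once as self, co-twin's values attached
        expected = pd.DataFrame(
            {
                "cluster": ["P0", "P0", "P1", "P1"],
                "twin_index": [1, 2, 1, 2],
                "y_self": [5.0, 6.0, 7.0, 8.0],
                "x_self": [1.0, 2.0, 3.0, 4.0],
                "x_cotwin": [2.0, 1.0, 4.0, 3.0],
                "y_cotwin": [6.0, 5.0, 8.0, 7.0],
            }
        )
        pd.testing.assert_frame_equal(design, expected)

    def test_relabelling_twins_gives_same_rows_up_to_order(self, sim_scores):
        design = build_double_entry(sim_scores, "x", "y").frame
        flipped_scores = sim_scores.copy()
        flipped_scores["twin_index"] = 3 - flipped_scores["twin_index"]
        flipped = build_double_entry(flipped_scores, "x", "y").frame
        cols = ["cluster", "y_self", "x_self", "x_cotwin"]
        a = design[cols].sort_values(cols).reset_index(drop=True)
        b = flipped[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_incomplete_pair_raises_with_ids(self, sim_scores):
        broken = sim_scores.iloc[1:]
        with pytest.raises(ValueError, match="P00000"):
            build_double_entry(broken, "x", "y")


class TestFitGEE:
    def test_perfect_fit_recovers_unit_coefficient(self):
        scores = toy_scores(
            {"x": [(float(i), float(i + 0.5)) for i in range(40)]}
        )
        scores["y"] = scores["x"]
        design = build_double_entry(scores, "x", "y")
        fit = fit_gee(design, ("x_self",))
        assert fit.coefficients["x_self"] == pytest.approx(1.0, abs=1e-10)

    def test_independence_working_equals_ols(self, sim_scores):
        design = build_double_entry(sim_scores, "x", "y")
        fit = fit_gee(design, ("x_self", "x_cotwin"), working="independence")
        X = sm.add_constant(design.frame[["x_self", "x_cotwin"]])
        ols = sm.OLS(design.frame["y_self"], X).fit()
        np.testing.assert_allclose(
            list(fit.coefficients.values()), ols.params.to_numpy(), atol=1e-10
        )

    @pytest.mark.parametrize(
        "terms", [("x_self",), ("x_cotwin",), ("x_self", "x_cotwin")]
    )
    def test_matches_statsmodels_gee(self, sim_scores, terms):
        design = build_double_entry(sim_scores, "x", "y")
        fit = fit_gee(design, terms)
        df = design.frame
        ref = GEE(
            df["y_self"], sm.add_constant(df[list(terms)]), groups=df["cluster"],
            cov_struct=Exchangeable(),
        ).fit()
        mine = np.array([fit.coefficients[t] for t in ("intercept",) + terms])
        np.testing.assert_allclose(mine, ref.params.to_numpy(), atol=1e-7)
        se_mine = np.array([fit.robust_se[t] for t in ("intercept",) + terms])
        np.testing.assert_allclose(se_mine, ref.bse.to_numpy(), rtol=1e-5)
        assert fit.working_correlation == pytest.approx(ref.cov_struct.dep_params, abs=1e-6)

    def test_pvalues_and_se_sane(self, sim_scores):
        design = build_double_entry(sim_scores, "x", "y")
        fit = fit_gee(design, ("x_self",))
        assert 0 < fit.p_values["x_self"] <= 1
        assert fit.robust_se["x_self"] > 0
        assert fit.n_clusters == 300

    def test_singular_design_raises(self):
        scores = toy_scores({"x": [(1.0, 1.0)] * 40})
        scores["y"] = 1.0
        design = build_double_entry(scores, "x", "y")
        with pytest.raises((ValueError, RuntimeError)):
            fit_gee(design, ("x_self", "x_cotwin"))

    def test_few_clusters_warns(self):
        scores = toy_scores({"x": [(1.0, 2.0), (2.0, 4.0), (3.0, 1.0), (0.5, 2.5)]})
        scores["y"] = scores["x"] * 0.5 + 0.1 * scores["twin_index"]
        design = build_double_entry(scores, "x", "y")
        with pytest.warns(UserWarning, match="clusters"):
            fit_gee(design, ("x_self",))
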