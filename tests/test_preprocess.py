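"""Box-Cox fitting, transforms, residualization and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icefalcon.config import TransformSpec
from icefalcon.preprocess import (
    apply_transform,
    build_risk_scores,
    fit_boxcox,
    residualize_standardize,
    variance_explained,
)
from icefalcon.presets import two_trait_config
from icefalcon.simulate import simulate_pairs

from conftest import SUITE_SEED


class TestFitBoxcox:
    @pytest.mark.parametrize(
        "draw, expected, tol",
        [
            (lambda r, n: np.exp(r.standard_normal(n)), 0.0, 0.1),  # log-normal
            (lambda r, n: r.standard_normal(n) + 10.0, 1.0, 0.15),  # already normal
            (lambda r, n: (r.standard_normal(n) + 10.0) ** 3, 1 / 3, 0.1),  # cubed
        ],
    )
    def test_recovers_known_exponent(self, rng, draw, expected, tol):
        values = draw(rng, 5000)
        spec = fit_boxcox(values)
        assert abs(spec.lam - expected) < tol

    def test_rejects_nonpositive_shifted_values(self):
        with pytest.raises(ValueError, match="positive"):
            fit_boxcox(np.linspace(-1.0, 5.0, 50))

    def test_rejects_too_few_values(self):
        with pytest.raises(ValueError, match="20"):
            fit_boxcox(np.ones(5) + np.arange(5))


class TestApplyTransform:
    def test_exact_worked_values(self):
        assert apply_transform(np.array([27.0]), TransformSpec("t", lam=1 / 3))[0] == pytest.approx(3.0)
        # reference mean Cirrus value under the shifted-square transform
        got = apply_transform(np.array([2910.32]), TransformSpec("cirrus", lam=2.0, shift=-2907.0))[0]
        assert got == pytest.approx(3.32**2, abs=1e-9)
        # reference mean brightest-areas value under the fifth root
        got = apply_transform(np.array([2.32]), TransformSpec("brightest", lam=1 / 5))[0]
        assert got == pytest.approx(2.32**0.2, abs=1e-12)
        assert got == pytest.approx(1.1833, abs=1e-4)

    def test_log_branch(self):
        np.testing.assert_allclose(
            apply_transform(np.array([1.0, np.e]), TransformSpec("t", lam=0.0)), [0.0, 1.0]
        )

    def test_domain_violation_raises(self):
        with pytest.raises(ValueError, match="domain"):
            apply_transform(np.array([1.0, 2906.0]), TransformSpec("c", lam=2.0, shift=-2907.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.05, 3.0),
        seed=st.integers(0, 10_000),
    )
    def test_positive_exponent_preserves_ranks(self, lam, seed):
        r = np.random.default_rng(seed)
        v = r.uniform(0.1, 50.0, size=40)
        t = apply_transform(v, TransformSpec("t", lam=lam))
        assert np.array_equal(np.argsort(v), np.argsort(t))


class TestResidualizeStandardize:
    def _frame(self, rng, n=2000, slope=0.3):
        age = rng.uniform(40, 70, n)
        return pd.DataFrame({"age": age, "t": slope * age + rng.standard_normal(n)})

    def test_residuals_orthogonal_to_covariate_and_standardized(self, rng):
        df = self._frame(rng)
        scores = residualize_standardize(df, "t", ["age"])
        assert abs(np.corrcoef(scores, df["age"])[0, 1]) < 1e-8
        assert abs(scores.mean()) < 1e-8
        assert abs(scores.std(ddof=1) - 1) < 1e-8

    def test_idempotent_on_own_output(self, rng):
        df = self._frame(rng)
        once = residualize_standardize(df, "t", ["age"])
        df2 = df.assign(t=once)
        twice = residualize_standardize(df2, "t", ["age"])
        np.testing.assert_allclose(once, twice, atol=1e-8)

    def test_independent_covariate_reduces_to_centering_scaling(self, rng):
        n = 5000
        df = pd.DataFrame({"age": rng.uniform(40, 70, n), "t": rng.standard_normal(n)})
        scores = residualize_standardize(df, "t", ["age"])
        direct = (df["t"] - df["t"].mean()) / df["t"].std(ddof=1)
        assert np.corrcoef(scores, direct)[0, 1] > 0.999

    def test_third_score_adjustment_removes_shared_component(self, rng):
        n = 5000
        z = rng.standard_normal(n)
        df = pd.DataFrame(
            {"age": rng.uniform(40, 70, n), "z": z, "t": 0.5 * z + rng.standard_normal(n)}
        )
        scores = residualize_standardize(df, "t", ["age", "z"])
        assert abs(np.corrcoef(scores, z)[0, 1]) < 1e-8

    def test_collinear_covariates_raise(self, rng):
        df = self._frame(rng, n=100)
        df["age2"] = 2 * df["age"]
        with pytest.raises(ValueError, match="collinear"):
            residualize_standardize(df, "t", ["age", "age2"])

    def test_constant_covariate_raises(self, rng):
        df = self._frame(rng, n=100)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            residualize_standardize(df, "t", ["c"])


class TestVarianceExplained:
    def test_exact_copy_gives_one(self, rng):
        df = pd.DataFrame({"t": rng.standard_normal(100)})
        df["c"] = df["t"]
        assert variance_explained(df, "t", ["c"]) == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self, rng):
        df = pd.DataFrame({"t": rng.standard_normal(20000), "c": rng.standard_normal(20000)})
        assert variance_explained(df, "t", ["c"]) < 0.002

    def test_recovers_configured_age_r2(self):
        # age slope sized for R^2 = 0.10: a = sqrt(0.1/0.9/Var(age))
        cfg = two_trait_config(5000, familial_x=0.6, unique_x=0.8, seed=SUITE_SEED)
        cfg.age_slope = {"x": np.sqrt(0.1 / 0.9 / 75.0)}
        data = simulate_pairs(cfg)
        r2 = variance_explained(data, "x", ["age"])
        assert abs(r2 - 0.10) < 0.02


class TestBuildRiskScores:
    def test_scores_standardized_and_age_free(self, study_scores):
        for trait in ("light", "bright", "brightest", "cirrus"):
            col = study_scores[trait]
            assert abs(col.mean()) < 1e-8
            assert abs(col.std(ddof=1) - 1) < 1e-8
            assert abs(np.corrcoef(col, study_scores["age"])[0, 1]) < 1e-8

    def test_incomplete_pairs_dropped_and_counted(self, study_raw, printed_transforms):
        broken = study_raw.iloc[1:].reset_index(drop=True)  # orphan first pair
        scores = build_risk_scores(broken, printed_transforms)
        assert scores.attrs["n_dropped_pairs"] == 1
        assert len(scores) == len(study_raw) - 2
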