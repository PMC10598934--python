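"""The three-model procedure, bootstrap, Pr decomposition and decision rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icefalcon.config import SimulationConfig
from icefalcon.falcon import (
    IceFalconTriplet,
    bootstrap_changes,
    classify_direction,
    decompose,
    fit_models,
    infer_conclusion,
    run_pair_analysis,
    stratified_analysis,
)
from icefalcon.correlations import within_pair_correlation
from icefalcon.presets import calibrated_config, two_trait_config
from icefalcon.simulate import simulate_pairs

from conftest import SUITE_SEED


def _triplet(bs, bsp, bct, bctp, p_cotwin=1e-6):
    return IceFalconTriplet(
        beta_self=bs, beta_cotwin=bct, beta_self_prime=bsp, beta_cotwin_prime=bctp,
        p={"beta_cotwin": p_cotwin},
    )


class TestFitModels:
    def test_pure_causation_pattern_at_large_n(self):
        cfg = two_trait_config(
            50000, causal_xy=0.3, familial_x=0.7, unique_x=np.sqrt(0.51), seed=SUITE_SEED
        )
        trip = fit_models(simulate_pairs(cfg), "x", "y")
        # co-twin coefficient collapses under mutual adjustment, self stays
        assert abs(trip.beta_cotwin_prime) < 3 * trip.se["beta_cotwin_prime"]
        assert trip.beta_self_prime == pytest.approx(trip.beta_self, abs=0.02)
        assert trip.beta_cotwin > 5 * trip.se["beta_cotwin"]

    def test_pure_confounding_pattern_at_large_n(self):
        cfg = two_trait_config(
            50000, confounder_x=0.6, confounder_y=0.5, unique_x=0.8,
            unique_y=np.sqrt(0.75), seed=SUITE_SEED,
        )
        trip = fit_models(simulate_pairs(cfg), "x", "y")
        assert trip.beta_self_prime == pytest.approx(trip.beta_cotwin_prime, abs=0.02)
        assert abs(trip.beta_self_prime) < abs(trip.beta_self)
        assert abs(trip.beta_cotwin_prime) < abs(trip.beta_cotwin)

    def test_independent_traits_all_null(self):
        cfg = two_trait_config(20000, familial_x=0.5, familial_y=0.5,
                               unique_x=0.8, unique_y=0.8, seed=SUITE_SEED)
        trip = fit_models(simulate_pairs(cfg), "x", "y")
        for k in ("beta_self", "beta_cotwin", "beta_self_prime", "beta_cotwin_prime"):
            assert abs(getattr(trip, k)) < 4 * trip.se[k]


class TestDecompose:
    @pytest.mark.parametrize(
        "coeffs, rho, expected_pct",
        [
            ((0.802, 0.770, 0.513, 0.070), 0.59, 89),  # light -> bright
            ((0.680, 0.653, 0.378, 0.058), 0.53, 85),  # bright -> brightest
        ],
    )
    def test_reference_coefficient_sets(self, coeffs, rho, expected_pct):
        dec = decompose(_triplet(*coeffs), rho)
        assert round(dec.pr * 100) == expected_pct

    def test_pure_causation_identity(self):
        for b, rho in ((0.3, 0.5), (-0.7, 0.2), (1.2, 0.9)):
            dec = decompose(_triplet(b, b, rho * b, 0.0), rho)
            assert dec.pr == pytest.approx(1.0, abs=1e-12)

    def test_equal_changes_cancel_to_zero(self):
        b, d, rho = 0.6, 0.2, 0.5
        dec = decompose(_triplet(b, b - d, b, b - d), rho)
        assert dec.pr == pytest.approx(0.0, abs=1e-12)

    def test_consistency_identities(self):
        trip = _triplet(0.5, 0.45, 0.3, 0.1)
        dec = decompose(trip, 0.5)
        assert dec.change_self == trip.beta_self - trip.beta_self_prime  # exact
        assert dec.causal_effect + trip.beta_self * dec.confounding_fraction == pytest.approx(
            trip.beta_self, abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        bs=st.floats(0.05, 1.5), bsp=st.floats(-1.0, 1.5), bct=st.floats(-1.0, 1.0),
        bctp=st.floats(-1.0, 1.0), rho=st.floats(0.05, 0.95),
        cx=st.floats(0.1, 10.0), cy=st.floats(0.1, 10.0),
    )
    def test_pr_invariant_to_rescaling_either_variable(self, bs, bsp, bct, bctp, rho, cx, cy):
        base = decompose(_triplet(bs, bsp, bct, bctp), rho).pr
        # rescale predictor by cx: betas divide by cx, rho unchanged
        scaled_x = decompose(_triplet(bs / cx, bsp / cx, bct / cx, bctp / cx), rho).pr
        # rescale outcome by cy: betas multiply by cy
        scaled_y = decompose(_triplet(bs * cy, bsp * cy, bct * cy, bctp * cy), rho).pr
        assert scaled_x == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled_y == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_out_of_range_flagged_never_clamped(self):
        dec = decompose(_triplet(0.3, 0.35, 0.1, 0.25), 0.5)  # increases
        assert dec.out_of_range
        assert dec.pr < 0  # kept at face value

    def test_guards(self):
        with pytest.raises(ValueError, match="rho"):
            decompose(_triplet(0.5, 0.4, 0.3, 0.1), 0.0)
        with pytest.raises(ValueError, match="beta_self"):
            decompose(_triplet(0.0, 0.0, 0.3, 0.1), 0.5)


@pytest.fixture(scope="module")
def confounded():
    cfg = two_trait_config(
        400, confounder_x=0.6, confounder_y=0.5, unique_x=0.8,
        unique_y=np.sqrt(0.75), seed=SUITE_SEED,
    )
    return simulate_pairs(cfg)


class TestBootstrap:
    def test_same_seed_reproduces_pvalues(self, confounded):
        a = bootstrap_changes(confounded, "x", "y", B=300, seed=5)
        b = bootstrap_changes(confounded, "x", "y", B=300, seed=5)
        assert a.change_p_self == b.change_p_self
        assert a.change_p_cotwin == b.change_p_cotwin

    def test_confounding_changes_both_significant(self, confounded):
        res = bootstrap_changes(confounded, "x", "y", B=400, seed=1)
        assert res.change_p_self < 0.01
        assert res.change_p_cotwin < 0.01
        assert res.n_dropped == 0

    def test_small_B_warns(self, confounded):
        with pytest.warns(UserWarning, match="B="):
            bootstrap_changes(confounded, "x", "y", B=50, seed=2)


class TestClassification:
    def test_causation_label(self):
        trip = _triplet(0.68, 0.653, 0.378, 0.058)
        dec = decompose(trip, 0.53, change_p_self=0.06, change_p_cotwin=5e-25)
        assert classify_direction(trip, dec) == "causation"

    def test_combination_label(self):
        trip = _triplet(0.802, 0.770, 0.513, 0.070)
        dec = decompose(trip, 0.59, change_p_self=0.02, change_p_cotwin=8e-34)
        assert classify_direction(trip, dec) == "combination"

    def test_familial_confounding_label(self):
        # proportional attenuation of both coefficients
        trip = _triplet(0.6, 0.42, 0.6, 0.42)
        dec = decompose(trip, 0.6, change_p_self=1e-4, change_p_cotwin=1e-4)
        assert classify_direction(trip, dec) == "familial_confounding"

    def test_no_evidence_label(self):
        trip = _triplet(0.3, 0.3, 0.02, 0.01, p_cotwin=0.4)
        dec = decompose(trip, 0.5, change_p_self=0.9, change_p_cotwin=0.9)
        assert classify_direction(trip, dec) == "no_evidence"

    def test_increasing_coefficients_are_inconsistent(self):
        trip = _triplet(0.285, 0.303, 0.091, 0.135)
        dec = decompose(trip, 0.48, change_p_self=0.02, change_p_cotwin=0.003)
        assert classify_direction(trip, dec) == "inconsistent"

    def test_summary_reports_pr_only_from_causal_directions(self):
        from icefalcon.falcon import DirectionResult

        fwd_trip = _triplet(0.68, 0.653, 0.378, 0.058)
        fwd = DirectionResult(
            "x", "y", fwd_trip, 0.53,
            decompose(fwd_trip, 0.53, change_p_self=0.06, change_p_cotwin=5e-25), None,
        )
        rev_trip = _triplet(0.619, 0.606, 0.136, 0.202)
        rev = DirectionResult(
            "y", "x", rev_trip, 0.34,
            decompose(rev_trip, 0.34, change_p_self=0.2, change_p_cotwin=0.02), None,
        )
        summary = infer_conclusion(fwd, rev)
        assert summary["forward_label"] == "causation"
        assert summary["reverse_label"] == "inconsistent"
        assert not summary["bidirectional"]
        assert [d["predictor"] for d in summary["causal_directions"]] == ["x"]


class TestRunPairAnalysis:
    def test_relabelling_twins_leaves_estimates_unchanged(self):
        cfg = two_trait_config(
            300, causal_xy=0.4, confounder_x=0.5, confounder_y=0.4,
            familial_x=0.3, unique_x=0.7, unique_y=0.8, seed=SUITE_SEED,
        )
        data = simulate_pairs(cfg)
        flipped = data.copy()
        flipped["twin_index"] = 3 - flipped["twin_index"]
        a = run_pair_analysis(data, "x", "y", B=200, seed=3)
        b = run_pair_analysis(flipped, "x", "y", B=200, seed=3)
        assert a.forward.triplet.beta_self == pytest.approx(b.forward.triplet.beta_self, abs=1e-10)
        assert a.forward.rho == pytest.approx(b.forward.rho, abs=1e-12)
        assert a.forward.decomposition.pr == pytest.approx(b.forward.decomposition.pr, abs=1e-8)

    def test_adjusting_for_independent_trait_is_noop(self):
        cfg = SimulationConfig(
            n_pairs=4000,
            traits=["x", "y", "w"],
            causal_paths={("x", "y"): 0.4},
            familial_loading={"x": 0.6, "y": 0.4, "w": 0.6},
            unique_sd={"x": 0.8, "y": 0.8, "w": 0.8},
            seed=SUITE_SEED,
        )
        data = simulate_pairs(cfg)
        plain = run_pair_analysis(data, "x", "y", B=200, seed=4)
        adjusted = run_pair_analysis(data, "x", "y", adjust_for="w", B=200, seed=4)
        assert adjusted.forward.decomposition.pr == pytest.approx(
            plain.forward.decomposition.pr, abs=0.05
        )
        assert adjusted.forward.rho == pytest.approx(plain.forward.rho, abs=0.05)

    def test_adjusting_for_mediator_blocks_the_association(self):
        # X -> Z -> Y only: after residualizing on Z there is nothing left
        cfg = SimulationConfig(
            n_pairs=8000,
            traits=["x", "z", "y"],
            causal_paths={("x", "z"): 0.5, ("z", "y"): 0.5},
            familial_loading={"x": 0.6, "z": 0.3, "y": 0.3},
            unique_sd={"x": 0.8, "z": 0.7, "y": 0.8},
            seed=SUITE_SEED,
        )
        data = simulate_pairs(cfg)
        res = run_pair_analysis(data, "x", "y", adjust_for="z", B=200, seed=5)
        # both associations collapse to sampling noise (population value 0)
        trip = res.forward.triplet
        assert abs(trip.beta_self) < 4 * trip.se["beta_self"]
        assert abs(trip.beta_self) < 0.05 and abs(trip.beta_cotwin) < 0.05
        # causal effect (beta_self * Pr) vanishes with the association
        assert abs(res.forward.decomposition.causal_effect) < 0.05
        assert res.forward.label in ("no_evidence", "inconsistent")

    def test_invalid_trait_combinations_raise(self, study_scores):
        with pytest.raises(ValueError):
            run_pair_analysis(study_scores, "light", "light", B=200)
        with pytest.raises(ValueError):
            run_pair_analysis(study_scores, "light", "bright", adjust_for="light", B=200)


class TestStratifiedAnalysis:
    def test_median_split_balances_pairs(self, study_raw, printed_transforms):
        res = stratified_analysis(
            study_raw, printed_transforms, "light", "bright", B=200, seed=6
        )
        assert set(res) == {"low", "high"}

    def test_identical_structure_gives_similar_pr(self, printed_transforms):
        cfg = calibrated_config(n_pairs=800, seed=SUITE_SEED)
        data = simulate_pairs(cfg)
        res = stratified_analysis(
            data, printed_transforms, "light", "bright", B=200, seed=7
        )
        lo = res["low"].forward.decomposition.pr
        hi = res["high"].forward.decomposition.pr
        assert abs(lo - hi) < 0.35  # same data-generating process in both strata

    def test_constant_stratifier_raises(self, study_raw, printed_transforms):
        flat = study_raw.copy()
        flat["stratifier"] = 30.5
        with pytest.raises(ValueError, match="constant"):
            stratified_analysis(flat, printed_transforms, "light", "bright", B=200)

    def test_tiny_stratum_raises(self, printed_transforms):
        cfg = calibrated_config(n_pairs=8, seed=1)
        data = simulate_pairs(cfg)
        with pytest.raises(ValueError, match="pairs"):
            stratified_analysis(data, printed_transforms, "light", "bright",
                                cutpoint=data["stratifier"].min() - 1, B=200)
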