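"""Shipped configurations: the Table-2-calibrated four-trait twin model.

``calibrated_config`` reproduces, in population, the reference correlation
structure of the four mammogram risk scores (light, bright and brightest
dense areas plus the Cirrus texture score) in MZ twin pairs:

* within-pair within-trait correlations 0.59 / 0.53 / 0.34 / 0.48,
* within-twin cross-trait correlations 0.38-0.81,
* cross-twin cross-trait correlations 0.28-0.52.

The calibration was solved offline: with causal-path coefficients on the
seven inferred directed edges chosen so that the individual-specific shock
covariance is exactly diagonal, the pair-shared covariance (decomposed into
four latent confounders by Cholesky) and the unique SDs then reproduce the
target within-individual and cross-twin correlation matrices exactly.  Raw
scales invert the printed power transforms (cube for the two lighter area
measures, fifth power for the brightest areas, a shifted square for Cirrus)
with location/scale set from the reference quartiles of the raw measures,
and age slopes sized so age explains ~2% of the light-areas variance and
~8-10% of the others.
"""

from __future__ import annotations

from .config import RawScale, SimulationConfig

__all__ = [
    "TRAITS",
    "REFERENCE_CORRELATIONS",
    "calibrated_config",
    "two_trait_config",
    "recovery_config",
]

TRAITS = ["light", "bright", "brightest", "cirrus"]

#: Target correlation structure: within-pair r (diagonal of `cross`),
#: within-twin cross-trait (`within`) and cross-twin cross-trait (`cross`).
REFERENCE_CORRELATIONS = {
    "within_pair": {"light": 0.59, "bright": 0.53, "brightest": 0.34, "cirrus": 0.48},
    "within_pair_ci": {
        "light": (0.54, 0.64),
        "bright": (0.47, 0.58),
        "brightest": (0.27, 0.40),
        "cirrus": (0.42, 0.53),
    },
    "within_twin_cross": {
        ("light", "bright"): 0.81,
        ("light", "brightest"): 0.49,
        ("light", "cirrus"): 0.38,
        ("bright", "brightest"): 0.69,
        ("bright", "cirrus"): 0.45,
        ("brightest", "cirrus"): 0.43,
    },
    "cross_twin_cross": {
        ("light", "bright"): 0.52,
        ("light", "brightest"): 0.35,
        ("light", "cirrus"): 0.28,
        ("bright", "brightest"): 0.40,
        ("bright", "cirrus"): 0.33,
        ("brightest", "cirrus"): 0.28,
    },
}

_CAUSAL_PATHS = {
    ("light", "bright"): 0.6638597353722749,
    ("bright", "light"): 0.06421170910553649,
    ("light", "brightest"): -0.18705989248125862,
    ("bright", "brightest"): 0.6902778829408632,
    ("cirrus", "brightest"): 0.1651396986446581,
    ("light", "cirrus"): 0.11233885819521541,
    ("bright", "cirrus"): 0.18600368324124844,
}

_UNIQUE_SD = {
    "light": 0.6121234239957888,
    "bright": 0.5154147361746506,
    "brightest": 0.6791441997822163,
    "cirrus": 0.6974565736958314,
}

_SHARED_CONFOUNDERS = [
    {
        "light": 0.724848321120327,
        "bright": 0.16066380011203035,
        "brightest": 0.06931389236171025,
        "cirrus": 0.1460849275153802,
    },
    {
        "bright": 0.2716464062214671,
        "brightest": 0.10734030829307041,
        "cirrus": 0.264538436439147,
    },
    {"brightest": 0.14083351459500776, "cirrus": -0.23936943240651581},
    {"cirrus": 0.4395706648447211},
]

# latent -> raw inverse links (loc/scale on the transformed scale chosen from
# the reference quartiles of the raw measures; lam is the forward exponent)
_RAW_SCALES = {
    "light": RawScale(lam=1 / 3, shift=0.0, loc=2.59, scale=0.59),
    "bright": RawScale(lam=1 / 3, shift=0.0, loc=2.07, scale=0.42),
    "brightest": RawScale(lam=1 / 5, shift=0.0, loc=1.10, scale=0.23),
    "cirrus": RawScale(lam=2.0, shift=-2907.0, loc=11.56, scale=3.66),
}

# age slopes on the standardized latent scale; with age ~ U(40, 70) these put
# the variance explained by age at ~2% (light) and ~8-10% (others)
_AGE_SLOPES = {"light": -0.0165, "bright": -0.034, "brightest": -0.0385, "cirrus": -0.0363}


def calibrated_config(
    n_pairs: int = 371, seed: int = 0, raw_scale: bool = True
) -> SimulationConfig:
    """Four-trait config whose population moments match the reference table.

    ``raw_scale=False`` emits standardized latent scores directly (useful for
    estimation checks that do not exercise preprocessing).
    """
    return SimulationConfig(
        n_pairs=n_pairs,
        traits=list(TRAITS),
        causal_paths=dict(_CAUSAL_PATHS),
        familial_loading={},
        unique_sd=dict(_UNIQUE_SD),
        shared_confounders=[dict(c) for c in _SHARED_CONFOUNDERS],
        age_range=(40.0, 70.0),
        age_slope=dict(_AGE_SLOPES) if raw_scale else {},
        raw_transform=dict(_RAW_SCALES) if raw_scale else {},
        stratifier_range=(10.0, 60.0),
        seed=seed,
    )


def two_trait_config(
    n_pairs: int,
    causal_xy: float = 0.0,
    causal_yx: float = 0.0,
    confounder_x: float = 0.0,
    confounder_y: float = 0.0,
    familial_x: float = 0.0,
    familial_y: float = 0.0,
    unique_x: float = 1.0,
    unique_y: float = 1.0,
    seed: int = 0,
) -> SimulationConfig:
    """Minimal predictor/outcome config on the latent scale.

    ``confounder_*`` are the loadings of a single pair-shared confounder;
    ``familial_*`` add trait-specific pair-shared variance that is not a
    confounder of the X-Y association.
    """
    paths = {}
    if causal_xy:
        paths[("x", "y")] = causal_xy
    if causal_yx:
        paths[("y", "x")] = causal_yx
    return SimulationConfig(
        n_pairs=n_pairs,
        traits=["x", "y"],
        causal_paths=paths,
        familial_loading={"x": familial_x, "y": familial_y},
        unique_sd={"x": unique_x, "y": unique_y},
        shared_confounders=(
            [{"x": confounder_x, "y": confounder_y}] if (confounder_x or confounder_y) else []
        ),
        seed=seed,
    )


def recovery_config(
    causal_fraction: float, n_pairs: int = 50000, seed: int = 0
) -> SimulationConfig:
    """Two-trait config whose population Pr equals ``causal_fraction``.

    The confounder loadings are held fixed and the causal-path coefficient is
    solved (Brent root-finding on the moment oracle, exchangeable estimand)
    so the population value of the Pr statistic — the quantity the estimator
    converges to — is exactly the requested fraction.  At 0 the path is zero
    by construction and the decomposition numerator vanishes identically.
    """
    from scipy.optimize import brentq

    from .moments import theoretical_coefficients

    if not 0.0 <= causal_fraction <= 1.0:
        raise ValueError("causal_fraction must be in [0, 1]")
    base = dict(confounder_x=0.6, confounder_y=0.5, familial_x=0.2, familial_y=0.1,
                unique_x=0.75, unique_y=0.85)
    if causal_fraction == 0.0:
        return two_trait_config(n_pairs, causal_xy=0.0, seed=seed, **base)
    if causal_fraction == 1.0:
        # Pr = 1 exactly requires no confounding of the outcome
        return two_trait_config(
            n_pairs, causal_xy=0.4, confounder_x=0.6, confounder_y=0.0,
            familial_x=0.2, familial_y=0.1, unique_x=0.75, unique_y=0.85, seed=seed,
        )

    def pr_at(b: float) -> float:
        cfg = two_trait_config(n_pairs, causal_xy=b, seed=seed, **base)
        return theoretical_coefficients(cfg, "x", "y")[2].pr - causal_fraction

    b_star = brentq(pr_at, 1e-6, 3.0, xtol=1e-12)
    return two_trait_config(n_pairs, causal_xy=b_star, seed=seed, **base)
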