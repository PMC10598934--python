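"""The ICE FALCON procedure: three regressions, a bootstrap, a decomposition.

Inference about Causation from Examination of FAmilial CONfounding uses a
relative's exposure as a proxy instrument.  For each ordered pair of risk
scores (X predictor, Y outcome) on MZ twin data, three GEE models are fitted
on the double-entered design:

    Model 1:  Y_self = beta_self      * X_self
    Model 2:  Y_self = beta_cotwin    * X_cotwin
    Model 3:  Y_self = beta'_self * X_self + beta'_cotwin * X_cotwin

If X causes Y, the co-twin coefficient attenuates toward zero under mutual
adjustment while the self coefficient is stable; under familial confounding
both attenuate to a similar proportional extent.  Wright's path-tracing rules
give the fraction of the Model 1 association attributable to causation:

    Pr = ((d_cotwin - (d_self / beta_self) * beta_cotwin) / rho) / beta_self

with d_* the Model 1/2 -> Model 3 coefficient changes and rho the within-pair
correlation of the predictor.  The causal effect is beta_self * Pr and the
familial-confounding fraction is 1 - Pr.  Change significance is assessed by
a pairwise cluster bootstrap (pairs resampled with replacement, all three
models refitted per replicate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess
from .correlations import within_pair_correlation
from .gee import (
    GEEFit,
    PairedDesign,
    build_double_entry,
    cluster_suffstats,
    fit_gee,
    solve_gee_batch,
)

__all__ = [
    "IceFalconTriplet",
    "Decomposition",
    "BootstrapChanges",
    "DirectionResult",
    "PairAnalysisResult",
    "fit_models",
    "bootstrap_changes",
    "bootstrap_triplets",
    "decompose",
    "classify_direction",
    "infer_conclusion",
    "run_pair_analysis",
    "stratified_analysis",
]

CONCLUSIONS = ("causation", "familial_confounding", "combination", "no_evidence", "inconsistent")


@dataclass
class IceFalconTriplet:
    """The six coefficients of Models 1-3 with robust SEs and p-values."""

    beta_self: float
    beta_cotwin: float
    beta_self_prime: float
    beta_cotwin_prime: float
    se: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    fits: Optional[tuple[GEEFit, GEEFit, GEEFit]] = None

    def __post_init__(self) -> None:
        for name in ("beta_self", "beta_cotwin", "beta_self_prime", "beta_cotwin_prime"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @property
    def change_self(self) -> float:
        return self.beta_self - self.beta_self_prime

    @property
    def change_cotwin(self) -> float:
        return self.beta_cotwin - self.beta_cotwin_prime


@dataclass
class Decomposition:
    """Pr split of one directed association into causation vs confounding."""

    change_self: float
    change_cotwin: float
    rho: float
    pr: float
    causal_effect: float
    confounding_fraction: float
    out_of_range: bool
    change_p_self: float = float("nan")
    change_p_cotwin: float = float("nan")
    conclusion: Optional[str] = None


@dataclass
class BootstrapChanges:
    change_p_self: float
    change_p_cotwin: float
    boot_se_self: float
    boot_se_cotwin: float
    n_replicates: int
    n_dropped: int


@dataclass
class DirectionResult:
    predictor: str
    outcome: str
    triplet: IceFalconTriplet
    rho: float
    decomposition: Decomposition
    bootstrap: Optional[BootstrapChanges]
    label: Optional[str] = None


@dataclass
class PairAnalysisResult:
    forward: DirectionResult
    reverse: DirectionResult
    adjust_for: Optional[str]
    summary: dict


# ---------------------------------------------------------------------------


def fit_models(
    scores: pd.DataFrame,
    predictor: str,
    outcome: str,
    conditional_on_cotwin_outcome: bool = False,
    working: str = "independence",
) -> IceFalconTriplet:
    """Fit Models 1-3 on the double-entered design and assemble the triplet.

    The default working correlation is independence: point estimates are the
    marginal (OLS) projection coefficients — the quantities the path-tracing
    decomposition is derived for — with pair-clustered sandwich SEs.  An
    exchangeable working correlation is available, but because Models 1-2
    deliberately omit one twin's predictor their mean models are
    misspecified, and exchangeable weighting then shifts the Model 1/2
    estimands substantially (enough to push the population Pr outside [0, 1]
    for strongly cross-correlated traits), so it does not reproduce the
    decomposition's intended coefficients.

    ``conditional_on_cotwin_outcome`` adds the co-twin's outcome as a
    covariate in every model (a conditional variant of the procedure).
    """
    design = build_double_entry(scores, predictor, outcome)
    extra = ("y_cotwin",) if conditional_on_cotwin_outcome else ()
    m1 = fit_gee(design, ("x_self",) + extra, working=working)
    m2 = fit_gee(design, ("x_cotwin",) + extra, working=working)
    m3 = fit_gee(design, ("x_self", "x_cotwin") + extra, working=working)
    return IceFalconTriplet(
        beta_self=m1.coefficients["x_self"],
        beta_cotwin=m2.coefficients["x_cotwin"],
        beta_self_prime=m3.coefficients["x_self"],
        beta_cotwin_prime=m3.coefficients["x_cotwin"],
        se={
            "beta_self": m1.robust_se["x_self"],
            "beta_cotwin": m2.robust_se["x_cotwin"],
            "beta_self_prime": m3.robust_se["x_self"],
            "beta_cotwin_prime": m3.robust_se["x_cotwin"],
        },
        p={
            "beta_self": m1.p_values["x_self"],
            "beta_cotwin": m2.p_values["x_cotwin"],
            "beta_self_prime": m3.p_values["x_self"],
            "beta_cotwin_prime": m3.p_values["x_cotwin"],
        },
        fits=(m1, m2, m3),
    )


def _batch_triplet(
    design: PairedDesign, idx: np.ndarray, working: str = "independence"
) -> tuple[dict, np.ndarray]:
    """Model 1-3 slope estimates for bootstrap index matrix idx (B, m).

    Returns (betas, keep_mask) where betas maps the four coefficient names to
    per-replicate arrays.  Each replicate's sufficient statistics are formed
    as multiplicity-weighted sums over pairs (a (B, m) weight matrix times the
    per-pair statistics), so memory stays linear in B + m even at large m.
    Replicates whose resampled predictor has (near) zero variance are dropped.
    """
    m = design.n_pairs
    n = 2 * m
    B = len(idx)
    w = np.zeros((B, m))
    np.add.at(w, (np.repeat(np.arange(B), m), idx.ravel()), 1.0)

    specs = {
        "m1": ("x_self",),
        "m2": ("x_cotwin",),
        "m3": ("x_self", "x_cotwin"),
    }

    def weighted(stats: tuple, wk: np.ndarray) -> tuple:
        out = []
        for arr in stats:
            flat = arr.reshape(m, -1)
            out.append((wk @ flat).reshape((len(wk),) + arr.shape[1:]))
        return tuple(out)

    stats_per_model = {}
    for key, terms in specs.items():
        Xc, yc = design.cluster_arrays(terms)
        stats_per_model[key] = cluster_suffstats(Xc, yc)

    # variance guard uses Model 3 stats (has both predictor columns)
    A3 = weighted((stats_per_model["m3"][0],), w)[0]  # (B, 3, 3)
    keep = np.ones(B, dtype=bool)
    for j in (1, 2):
        var = A3[:, j, j] / n - (A3[:, 0, j] / n) ** 2
        keep &= var > 1e-12
    w_kept = w[keep]

    fits = {}
    for key in specs:
        summed = weighted(stats_per_model[key], w_kept)
        beta, _alpha, _conv, _it = solve_gee_batch(*summed, n_clusters=m, working=working)
        fits[key] = beta
    betas = {
        "beta_self": fits["m1"][:, 1],
        "beta_cotwin": fits["m2"][:, 1],
        "beta_self_prime": fits["m3"][:, 1],
        "beta_cotwin_prime": fits["m3"][:, 2],
    }
    return betas, keep


def bootstrap_triplets(
    scores: pd.DataFrame,
    predictor: str,
    outcome: str,
    B: int = 1000,
    seed: int = 0,
    working: str = "independence",
) -> dict[str, np.ndarray]:
    """Pair-bootstrap replicates of all four Model 1-3 coefficients.

    The bootstrap SDs of these arrays estimate the full sampling variability
    of the coefficients — including the component propagated through the
    estimated working correlation, which the analytic sandwich misses for the
    (deliberately misspecified) Models 1 and 2.
    """
    design = build_double_entry(scores, predictor, outcome)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, design.n_pairs, size=(B, design.n_pairs))
    betas, keep = _batch_triplet(design, idx, working=working)
    betas["n_dropped"] = int((~keep).sum())
    return betas


def bootstrap_changes(
    scores: pd.DataFrame,
    predictor: str,
    outcome: str,
    B: int = 1000,
    seed: int = 0,
    working: str = "independence",
) -> BootstrapChanges:
    """Cluster-bootstrap p-values for the Model 1->3 coefficient changes.

    Pairs are resampled with replacement; Models 1-3 are refitted on each
    replicate and the two change statistics recomputed.  Two-sided p-values
    come from the normal approximation with the bootstrap SE.
    """
    if B < 200:
        warnings.warn(f"B={B} is below the reporting default of 200", stacklevel=2)
    betas = bootstrap_triplets(scores, predictor, outcome, B=B, seed=seed, working=working)
    d_self = betas["beta_self"] - betas["beta_self_prime"]
    d_cotwin = betas["beta_cotwin"] - betas["beta_cotwin_prime"]
    n_dropped = betas["n_dropped"]
    if n_dropped > 0.05 * B:
        raise RuntimeError(
            f"{n_dropped}/{B} bootstrap replicates degenerate (zero predictor variance)"
        )
    triplet = fit_models(scores, predictor, outcome, working=working)
    se_self = float(np.std(d_self, ddof=1))
    se_cotwin = float(np.std(d_cotwin, ddof=1))
    p_self = 2.0 * float(stats.norm.sf(abs(triplet.change_self) / se_self)) if se_self > 0 else 1.0
    p_cotwin = (
        2.0 * float(stats.norm.sf(abs(triplet.change_cotwin) / se_cotwin)) if se_cotwin > 0 else 1.0
    )
    return BootstrapChanges(
        change_p_self=p_self,
        change_p_cotwin=p_cotwin,
        boot_se_self=se_self,
        boot_se_cotwin=se_cotwin,
        n_replicates=B - n_dropped,
        n_dropped=n_dropped,
    )


def decompose(
    triplet: IceFalconTriplet,
    rho: float,
    change_p_self: float = float("nan"),
    change_p_cotwin: float = float("nan"),
) -> Decomposition:
    """Evaluate the path-tracing Pr split for one directed assignment.

    Pr is kept at full precision on the [0, 1] fraction scale; values outside
    [0, 1] (possible with noisy or increase-type coefficient patterns) are
    returned as-is with ``out_of_range=True``, never clamped.
    """
    if rho == 0:
        raise ValueError("rho (within-pair predictor correlation) must be nonzero")
    if triplet.beta_self == 0:
        raise ValueError("beta_self must be nonzero to decompose the association")
    d_self = triplet.change_self
    d_cotwin = triplet.change_cotwin
    pr = ((d_cotwin - (d_self / triplet.beta_self) * triplet.beta_cotwin) / rho) / triplet.beta_self
    return Decomposition(
        change_self=d_self,
        change_cotwin=d_cotwin,
        rho=rho,
        pr=pr,
        causal_effect=triplet.beta_self * pr,
        confounding_fraction=1.0 - pr,
        out_of_range=not (0.0 <= pr <= 1.0),
        change_p_self=change_p_self,
        change_p_cotwin=change_p_cotwin,
    )


def classify_direction(
    triplet: IceFalconTriplet,
    decomposition: Decomposition,
    alpha: float = 0.05,
    similar_tol: float = 0.25,
) -> str:
    """Label one direction by the coefficient-pattern decision rules.

    causation: the co-twin coefficient is nonzero, attenuates toward zero
    under mutual adjustment, and the self coefficient is stable.
    familial_confounding: both coefficients attenuate significantly and to a
    similar proportional extent (|difference| < similar_tol).
    combination: both attenuate significantly but the self change is
    proportionally smaller.  no_evidence: no co-twin association to explain.
    inconsistent: any other pattern (e.g. coefficients that increase under
    adjustment), which is not consistent with X causing Y.
    """
    p_cotwin = triplet.p.get("beta_cotwin", float("nan"))
    if not (p_cotwin < alpha):
        return "no_evidence"
    sig_ct = decomposition.change_p_cotwin < alpha
    sig_self = decomposition.change_p_self < alpha
    toward_zero = abs(triplet.beta_cotwin_prime) < abs(triplet.beta_cotwin)
    if sig_ct and toward_zero:
        if not sig_self:
            return "causation"
        prop_self = decomposition.change_self / triplet.beta_self
        prop_ct = decomposition.change_cotwin / triplet.beta_cotwin
        if abs(prop_self - prop_ct) < similar_tol:
            return "familial_confounding"
        if abs(prop_self) < abs(prop_ct):
            return "combination"
    return "inconsistent"


def infer_conclusion(
    forward: DirectionResult,
    reverse: DirectionResult,
    alpha: float = 0.05,
    similar_tol: float = 0.25,
) -> dict:
    """Label both directions and reconcile them into a summary.

    Pr and the causal effect are reported only for directions whose pattern
    suggests the predictor causes the outcome (causation or combination);
    a direction whose coefficients move away from zero is never used.
    """
    for d in (forward, reverse):
        d.label = classify_direction(d.triplet, d.decomposition, alpha, similar_tol)
        d.decomposition.conclusion = d.label
    causal_dirs = [
        d for d in (forward, reverse) if d.label in ("causation", "combination")
    ]
    summary = {
        "forward_label": forward.label,
        "reverse_label": reverse.label,
        "bidirectional": len(causal_dirs) == 2,
        "causal_directions": [
            {
                "predictor": d.predictor,
                "outcome": d.outcome,
                "pr": d.decomposition.pr,
                "causal_effect": d.decomposition.causal_effect,
                "confounding_fraction": d.decomposition.confounding_fraction,
            }
            for d in causal_dirs
        ],
    }
    return summary


def _one_direction(
    scores: pd.DataFrame,
    predictor: str,
    outcome: str,
    B: int,
    seed: int,
    conditional: bool,
    working: str,
) -> DirectionResult:
    triplet = fit_models(scores, predictor, outcome, conditional, working=working)
    rho = within_pair_correlation(scores, predictor).r
    boot = bootstrap_changes(scores, predictor, outcome, B=B, seed=seed, working=working)
    dec = decompose(triplet, rho, boot.change_p_self, boot.change_p_cotwin)
    return DirectionResult(predictor, outcome, triplet, rho, dec, boot)


def run_pair_analysis(
    scores: pd.DataFrame,
    predictor: str,
    outcome: str,
    adjust_for: Optional[str] = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    similar_tol: float = 0.25,
    conditional_on_cotwin_outcome: bool = False,
    working: str = "independence",
) -> PairAnalysisResult:
    """Full bidirectional ICE FALCON analysis of one trait pair.

    With ``adjust_for`` set, both scores are first re-residualized on age and
    the third risk score (and re-standardized), and rho is recomputed on the
    adjusted predictor — this probes the causal pathway that does not run
    through the third score.
    """
    if predictor == outcome:
        raise ValueError("predictor and outcome must differ")
    if adjust_for in (predictor, outcome):
        raise ValueError("adjust_for must differ from predictor and outcome")
    work = scores
    if adjust_for is not None:
        covs = ["age", adjust_for] if "age" in scores.columns else [adjust_for]
        work = scores.copy()
        for trait in (predictor, outcome):
            work[trait] = preprocess.residualize_standardize(scores, trait, covs).to_numpy()
    fwd = _one_direction(work, predictor, outcome, B, seed, conditional_on_cotwin_outcome, working)
    rev = _one_direction(work, outcome, predictor, B, seed + 1, conditional_on_cotwin_outcome, working)
    summary = infer_conclusion(fwd, rev, alpha, similar_tol)
    summary["adjust_for"] = adjust_for
    return PairAnalysisResult(forward=fwd, reverse=rev, adjust_for=adjust_for, summary=summary)


def stratified_analysis(
    dataset: pd.DataFrame,
    transforms: dict,
    predictor: str,
    outcome: str,
    stratifier: str = "stratifier",
    cutpoint: Optional[float] = None,
    covariates: list[str] = ("age",),
    **analysis_kwargs,
) -> dict[str, PairAnalysisResult]:
    """Median-split (or custom cutpoint) subgroup analysis at the pair level.

    Pairs are assigned to strata by the pair mean of the stratifier (e.g.
    percent mammographic density), so twins are never separated.  The full
    pipeline — risk-score construction included — is re-run within each
    stratum.
    """
    if stratifier not in dataset.columns:
        raise ValueError(f"stratifier column {stratifier!r} not in dataset")
    pair_level = dataset.groupby("pair_id")[stratifier].mean()
    if np.isclose(pair_level.std(ddof=0), 0.0):
        raise ValueError(f"stratifier {stratifier!r} is constant across pairs")
    cut = float(pair_level.median()) if cutpoint is None else float(cutpoint)
    groups = {
        "low": pair_level.index[pair_level <= cut],
        "high": pair_level.index[pair_level > cut],
    }
    results: dict[str, PairAnalysisResult] = {}
    for name, pair_ids in groups.items():
        n = len(pair_ids)
        if n < 5:
            raise ValueError(f"stratum {name!r} has only {n} pairs (< 5)")
        if n < 30:
            warnings.warn(f"stratum {name!r} has only {n} pairs", stacklevel=2)
        sub = dataset[dataset["pair_id"].isin(pair_ids)]
        scores = preprocess.build_risk_scores(sub, transforms, covariates=list(covariates))
        results[name] = run_pair_analysis(scores, predictor, outcome, **analysis_kwargs)
    return results
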