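"""From raw mammographic measures to standardized risk scores.

The pipeline is: power-transform each raw measure toward normality (Box-Cox,
with the exponent either profiled from the data or forced to a known value),
regress the transformed value on age at mammography (and optionally a third
risk score), and standardize the residuals to mean 0, SD 1.  Those
standardized residuals are the "risk scores" every downstream analysis uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .config import TransformSpec

__all__ = [
    "fit_boxcox",
    "apply_transform",
    "residualize_standardize",
    "variance_explained",
    "build_risk_scores",
]


def fit_boxcox(
    values: np.ndarray,
    shift: float | None = None,
    trait: str = "",
    grid: tuple[float, float, float] = (-2.0, 3.0, 0.05),
) -> TransformSpec:
    """Profile-likelihood Box-Cox exponent for ``(values + shift)**lam``.

    A coarse grid over lam is scanned first, then the maximizer is refined
    with bounded scalar optimization.  ``shift`` defaults to 0; it is the
    caller's responsibility when data need an offset to become positive.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError(f"need >= 20 values to profile lambda, got {v.size}")
    shift = 0.0 if shift is None else float(shift)
    shifted = v + shift
    if np.any(shifted <= 0):
        raise ValueError(
            f"shifted values must be positive; minimum is {shifted.min():.6g} "
            f"(shift={shift})"
        )
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(lam, shifted) for lam in lams])
    best = lams[int(np.argmax(llf))]
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, shifted),
        bounds=(max(lo, best - step), min(hi, best + step)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return TransformSpec(trait=trait, lam=float(res.x), shift=shift)


def apply_transform(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Elementwise (v + shift)**lam, with lam = 0 meaning log(v + shift)."""
    v = np.asarray(values, dtype=float) + spec.shift
    if np.any(v <= 0):
        raise ValueError(
            f"transform domain violation for {spec.trait or 'trait'}: minimum "
            f"shifted value {v.min():.6g} <= 0 (shift={spec.shift})"
        )
    if spec.lam == 0.0:
        return np.log(v)
    return np.power(v, spec.lam)


def _design(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} not in data")
        if np.isclose(df[c].std(ddof=0), 0.0):
            raise ValueError(f"covariate {c!r} is constant")
    X = sm.add_constant(df[list(covariates)].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear covariates: {covariates}")
    return X


def residualize_standardize(
    df: pd.DataFrame,
    trait: str,
    covariates: list[str],
    ddof: int = 1,
) -> pd.Series:
    """OLS residuals of ``trait`` on an intercept plus covariates, scaled to SD 1.

    Fitting is on individuals, ignoring the pair clustering: the residuals
    (and hence the scores) are identical either way, and clustering is
    handled downstream by the GEE and the pair bootstrap.
    """
    y = df[trait].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"missing or non-finite values in {trait!r}")
    X = _design(df, covariates)
    resid = sm.OLS(y, X).fit().resid
    sd = resid.std(ddof=ddof)
    if sd == 0:
        raise ValueError(f"zero residual variance for {trait!r}")
    out = (resid - resid.mean()) / sd
    out = out - out.mean()  # exact recentering after the scale step
    return pd.Series(out, index=df.index, name=trait)


def variance_explained(df: pd.DataFrame, trait: str, covariates: list[str]) -> float:
    """R-squared of the adjustment regression for one trait."""
    y = df[trait].to_numpy(dtype=float)
    X = _design(df, covariates)
    return float(sm.OLS(y, X).fit().rsquared)


def build_risk_scores(
    dataset: pd.DataFrame,
    transforms: dict[str, TransformSpec],
    covariates: list[str] = ("age",),
    ddof: int = 1,
) -> pd.DataFrame:
    """Transform, age-adjust and standardize every trait of a twin dataset.

    Returns a frame with pair_id, twin_index, age, the score columns, and any
    stratifier column carried through.  Incomplete pairs are dropped (the
    analyses require both twins) and the number dropped is recorded in
    ``frame.attrs['n_dropped_pairs']``.
    """
    df = dataset.copy()
    traits = list(transforms)
    complete = df.groupby("pair_id")["twin_index"].transform("count") == 2
    n_dropped = int(df.loc[~complete, "pair_id"].nunique())
    df = df[complete].sort_values(["pair_id", "twin_index"]).reset_index(drop=True)

    out = df[[c for c in ("pair_id", "twin_index", "age", "stratifier") if c in df]].copy()
    for trait in traits:
        transformed = apply_transform(df[trait].to_numpy(dtype=float), transforms[trait])
        tmp = out.copy()
        tmp["_t"] = transformed
        out[trait] = residualize_standardize(tmp, "_t", list(covariates), ddof=ddof).to_numpy()
    out.attrs["n_dropped_pairs"] = n_dropped
    out.attrs["transforms"] = {t: (transforms[t].shift, transforms[t].lam) for t in traits}
    out.attrs["covariates"] = list(covariates)
    return out
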