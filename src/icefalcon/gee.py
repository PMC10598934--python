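"""Gaussian GEE with an exchangeable working correlation on twin-pair clusters.

The regressions all share one layout: the analysis table is double-entered
(each twin appears once as "self", with her co-twin's values attached), so
every cluster has exactly two rows.  For that special case the estimating
equations have closed-form per-cluster contributions, which this module
vectorizes both across clusters and across bootstrap replicates.  The batch
solver is what makes a pairwise cluster bootstrap with thousands of refits
affordable; tests cross-check the estimates against statsmodels' GEE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedDesign", "GEEFit", "build_double_entry", "fit_gee"]


@dataclass
class PairedDesign:
    """Double-entered regression table: one row per individual-as-outcome."""

    frame: pd.DataFrame  # columns: cluster, y_self, x_self, x_cotwin, y_cotwin
    predictor: str
    outcome: str

    @property
    def n_pairs(self) -> int:
        return self.frame["cluster"].nunique()

    def cluster_arrays(self, terms: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        """Return (Xc, yc): Xc is (n_pairs, 2, 1 + len(terms)) with intercept."""
        df = self.frame
        m = len(df) // 2
        cols = [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms]
        X = np.column_stack(cols)
        return X.reshape(m, 2, -1), df["y_self"].to_numpy(dtype=float).reshape(m, 2)


@dataclass
class GEEFit:
    coefficients: dict[str, float]
    robust_se: dict[str, float]
    p_values: dict[str, float]
    working_correlation: float
    n_clusters: int
    converged: bool = True
    n_iter: int = 0


def build_double_entry(scores: pd.DataFrame, predictor: str, outcome: str) -> PairedDesign:
    """Expand per-individual risk scores into the double-entered design.

    ``scores`` must have columns pair_id, twin_index (1/2) and one column per
    trait.  Each complete pair contributes two rows, one per twin as "self".
    """
    for col in ("pair_id", "twin_index", predictor, outcome):
        if col not in scores.columns:
            raise ValueError(f"scores is missing column {col!r}")
    counts = scores.groupby("pair_id")["twin_index"].agg(["count", "nunique"])
    bad = counts.index[(counts["count"] != 2) | (counts["nunique"] != 2)].tolist()
    if bad:
        raise ValueError(f"incomplete or duplicated pairs: {bad}")

    df = scores.sort_values(["pair_id", "twin_index"]).reset_index(drop=True)
    t1 = df[df["twin_index"] == df.groupby("pair_id")["twin_index"].transform("min")]
    t2 = df[df["twin_index"] == df.groupby("pair_id")["twin_index"].transform("max")]
    t1, t2 = t1.reset_index(drop=True), t2.reset_index(drop=True)

    rows = []
    for self_df, co_df in ((t1, t2), (t2, t1)):
        rows.append(
            pd.DataFrame(
                {
                    "cluster": self_df["pair_id"].to_numpy(),
                    "twin_index": self_df["twin_index"].to_numpy(),
                    "y_self": self_df[outcome].to_numpy(dtype=float),
                    "x_self": self_df[predictor].to_numpy(dtype=float),
                    "x_cotwin": co_df[predictor].to_numpy(dtype=float),
                    "y_cotwin": co_df[outcome].to_numpy(dtype=float),
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["cluster", "twin_index"], kind="mergesort")
        .reset_index(drop=True)
    )
    return PairedDesign(frame=frame, predictor=predictor, outcome=outcome)


# ---------------------------------------------------------------------------
# batched estimating equations


def cluster_suffstats(Xc: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-cluster sufficient statistics for the exchangeable GEE.

    With 2-row clusters, both the weighted normal equations and the moment
    estimator of the working correlation are functions of these six arrays,
    so bootstrap refits reduce to re-summing them over resampled pairs.
    """
    x1, x2 = Xc[:, 0, :], Xc[:, 1, :]
    y1, y2 = yc[:, 0], yc[:, 1]
    A = np.einsum("cji,cjk->cik", Xc, Xc)  # X_c' X_c
    Cr = np.einsum("ci,ck->cik", x1, x2)  # x1 x2'
    b = np.einsum("cji,cj->ci", Xc, yc)  # X_c' y_c
    bx = x1 * y2[:, None] + x2 * y1[:, None]
    s = y1**2 + y2**2
    q = y1 * y2
    return A, Cr, b, bx, s, q


def solve_gee_batch(
    A: np.ndarray,
    Cr: np.ndarray,
    b: np.ndarray,
    bx: np.ndarray,
    s: np.ndarray,
    q: np.ndarray,
    n_clusters: int,
    working: str = "exchangeable",
    maxiter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Solve a batch of GEE systems from summed sufficient statistics.

    Inputs are stacked over replicates: A (B,p,p), Cr (B,p,p), b (B,p),
    bx (B,p), s (B,), q (B,).  Returns (beta (B,p), alpha (B,), converged, iters).
    """
    p = A.shape[-1]
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # OLS start == alpha 0
    alpha = np.zeros(len(A))
    if working == "independence":
        return beta, alpha, True, 0
    if working != "exchangeable":
        raise ValueError(f"unknown working correlation {working!r}")
    Crs = Cr + np.transpose(Cr, (0, 2, 1))
    nobs = 2 * n_clusters
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        rss = (
            s
            - 2 * np.einsum("bi,bi->b", b, beta)
            + np.einsum("bi,bik,bk->b", beta, A, beta)
        )
        phi = rss / max(nobs - p, 1)
        cross = (
            q
            - np.einsum("bi,bi->b", bx, beta)
            + np.einsum("bi,bik,bk->b", beta, Cr, beta)
        )
        alpha_new = cross / max(n_clusters - p, 1) / np.maximum(phi, 1e-300)
        alpha_new = np.clip(alpha_new, -0.95, 0.95)
        XtVX = A - alpha_new[:, None, None] * Crs
        XtVy = b - alpha_new[:, None] * bx
        beta_new = np.linalg.solve(XtVX, XtVy[..., None])[..., 0]
        delta = max(
            float(np.max(np.abs(beta_new - beta))),
            float(np.max(np.abs(alpha_new - alpha))),
        )
        beta, alpha = beta_new, alpha_new
        if delta < tol:
            converged = True
            break
    return beta, alpha, converged, it


def _sandwich(
    Xc: np.ndarray, yc: np.ndarray, beta: np.ndarray, alpha: float
) -> np.ndarray:
    """Cluster-robust covariance of beta for one fitted GEE."""
    r = yc - np.einsum("cji,i->cj", Xc, beta)
    x1, x2 = Xc[:, 0, :], Xc[:, 1, :]
    r1, r2 = r[:, 0], r[:, 1]
    denom = 1.0 - alpha**2
    g = (x1 * (r1 - alpha * r2)[:, None] + x2 * (r2 - alpha * r1)[:, None]) / denom
    bread = (
        np.einsum("cji,cjk->ik", Xc, Xc)
        - alpha
        * (np.einsum("ci,ck->ik", x1, x2) + np.einsum("ci,ck->ik", x2, x1))
    ) / denom
    meat = g.T @ g
    binv = np.linalg.inv(bread)
    return binv @ meat @ binv


def fit_gee(
    design: PairedDesign,
    terms: tuple[str, ...] = ("x_self",),
    working: str = "exchangeable",
) -> GEEFit:
    """Fit y_self on the requested terms with pair-clustered robust SEs.

    Mean model is Gaussian with identity link and an intercept; the working
    correlation is exchangeable within pairs unless ``working`` says
    "independence" (in which case the point estimates equal OLS).
    """
    if not terms:
        raise ValueError("terms must be a non-empty subset of {'x_self', 'x_cotwin'}")
    for t in terms:
        if t not in ("x_self", "x_cotwin"):
            raise ValueError(f"unknown term {t!r}")
    m = design.n_pairs
    if m < 30:
        warnings.warn(f"only {m} clusters; robust SEs may be unreliable", stacklevel=2)
    Xc, yc = design.cluster_arrays(terms)
    A, Cr, b, bx, s, q = cluster_suffstats(Xc, yc)
    stats_sum = tuple(arr.sum(axis=0)[None, ...] for arr in (A, Cr, b, bx, s, q))
    try:
        beta, alpha, converged, n_iter = solve_gee_batch(
            *stats_sum, n_clusters=m, working=working
        )
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design for terms {terms}: {exc}") from exc
    beta, alpha_val = beta[0], float(alpha[0])
    if not converged:
        raise RuntimeError(
            f"GEE did not converge in {n_iter} iterations (terms={terms}, "
            f"n_pairs={m}, last alpha={alpha_val:.6f})"
        )
    cov = _sandwich(Xc, yc, beta, alpha_val if working == "exchangeable" else 0.0)
    se = np.sqrt(np.diag(cov))
    names = ("intercept",) + terms
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return GEEFit(
        coefficients=dict(zip(names, beta.tolist())),
        robust_se=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, np.clip(pvals, 1e-300, 1.0).tolist())),
        working_correlation=alpha_val if working == "exchangeable" else 0.0,
        n_clusters=m,
        converged=converged,
        n_iter=n_iter,
    )
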