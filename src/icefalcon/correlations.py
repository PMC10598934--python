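"""Twin-pair correlation structure of the risk scores.

Three kinds of Pearson correlation summarize a pair of traits (X, Y) in MZ
twin data: the within-twin within-trait (within-pair) correlation of one
trait, the within-twin cross-trait correlation (X and Y of the same woman),
and the cross-twin cross-trait correlation (X of one twin with Y of her
co-twin).  Pair-level quantities are computed on double-entered data — each
pair contributes both orderings — which makes them invariant to twin
labelling; confidence intervals use Fisher's z with the number of pairs as
the effective sample size by default (the double-entered rows duplicate
information, so using 2n would be anti-conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationEntry",
    "within_pair_correlation",
    "cross_trait_correlations",
    "correlation_table",
]


@dataclass(frozen=True)
class CorrelationEntry:
    kind: str  # within_twin_within_trait | within_twin_cross_trait | cross_twin_cross_trait
    trait_x: str
    trait_y: str
    r: float
    ci_low: float
    ci_high: float
    n_units: int


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3:
        return (-1.0, 1.0)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _pair_wide(scores: pd.DataFrame, trait: str) -> tuple[np.ndarray, np.ndarray]:
    df = scores.sort_values(["pair_id", "twin_index"])
    counts = df.groupby("pair_id")[trait].count()
    if (counts != 2).any():
        raise ValueError(f"incomplete pairs: {counts.index[counts != 2].tolist()}")
    v = df[trait].to_numpy(dtype=float).reshape(-1, 2)
    return v[:, 0], v[:, 1]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.isclose(a.std(), 0) or np.isclose(b.std(), 0):
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def within_pair_correlation(
    scores: pd.DataFrame, trait: str, n_convention: str = "pairs"
) -> CorrelationEntry:
    """Within-twin within-trait correlation on double-entered pairs."""
    v1, v2 = _pair_wide(scores, trait)
    r = _pearson(np.concatenate([v1, v2]), np.concatenate([v2, v1]))
    n_pairs = len(v1)
    n_units = n_pairs if n_convention == "pairs" else 2 * n_pairs
    lo, hi = _fisher_ci(r, n_units)
    return CorrelationEntry("within_twin_within_trait", trait, trait, r, lo, hi, n_units)


def cross_trait_correlations(
    scores: pd.DataFrame, trait_x: str, trait_y: str, n_convention: str = "pairs"
) -> tuple[CorrelationEntry, CorrelationEntry]:
    """(within-twin cross-trait, cross-twin cross-trait) entries for (X, Y)."""
    x1, x2 = _pair_wide(scores, trait_x)
    y1, y2 = _pair_wide(scores, trait_y)
    n_pairs = len(x1)

    # X and Y of the same woman: one row per individual
    r_within = _pearson(np.concatenate([x1, x2]), np.concatenate([y1, y2]))
    lo_w, hi_w = _fisher_ci(r_within, 2 * n_pairs)
    within = CorrelationEntry(
        "within_twin_cross_trait", trait_x, trait_y, r_within, lo_w, hi_w, 2 * n_pairs
    )

    # X of one twin with Y of her co-twin, double-entered
    r_cross = _pearson(np.concatenate([x1, x2]), np.concatenate([y2, y1]))
    n_units = n_pairs if n_convention == "pairs" else 2 * n_pairs
    lo_c, hi_c = _fisher_ci(r_cross, n_units)
    cross = CorrelationEntry(
        "cross_twin_cross_trait", trait_x, trait_y, r_cross, lo_c, hi_c, n_units
    )
    return within, cross


def correlation_table(
    scores: pd.DataFrame, traits: list[str], n_convention: str = "pairs"
) -> pd.DataFrame:
    """All within-pair and pairwise cross-trait entries, one row per entry."""
    entries: list[CorrelationEntry] = []
    for t in traits:
        entries.append(within_pair_correlation(scores, t, n_convention))
    for i, tx in enumerate(traits):
        for ty in traits[i + 1 :]:
            entries.extend(cross_trait_correlations(scores, tx, ty, n_convention))
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "trait_x": e.trait_x,
                "trait_y": e.trait_y,
                "r": e.r,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_units": e.n_units,
            }
            for e in entries
        ]
    )
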