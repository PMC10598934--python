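"""Synthetic MZ twin-pair data under a linear structural model.

Each individual's trait vector T solves the simultaneous system
T = B T + u (reduced form T = (I - B)^{-1} u), where B holds the directed
within-individual causal paths (possibly bidirectional between two traits)
and the exogenous shock u decomposes into pair-shared parts — a
trait-specific familial component plus latent confounders loading on several
traits — and an individual-specific part.  Twins are exchangeable; nothing a
twin has acts directly on her co-twin's traits.  Age at mammography is drawn
once per pair and enters each trait's latent scale linearly before the
inverse power transform carries the score to a right-skewed raw scale, so the
full preprocessing pipeline (power transform, age adjustment,
standardization) is exercised on realistic-looking input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = ["simulate_pairs", "reduced_form", "write_dataset_csv", "read_dataset_csv"]


def _cyclic_paths(config: SimulationConfig) -> list[str]:
    B = config.path_matrix() != 0
    reach = B.copy()
    for _ in range(len(config.traits)):
        reach = reach | (reach @ B)
    in_cycle = {config.traits[i] for i in range(len(config.traits)) if reach[i, i]}
    return [
        f"{s}->{t}"
        for (s, t) in config.causal_paths
        if s in in_cycle and t in in_cycle
    ]


def reduced_form(config: SimulationConfig) -> np.ndarray:
    """(I - B)^{-1}, failing loudly when the cyclic system has no solution."""
    B = config.path_matrix()
    eig = np.max(np.abs(np.linalg.eigvals(B)))
    if eig >= 1.0:
        raise ValueError(
            f"structural system is not invertible (spectral radius {eig:.3f} >= 1); "
            f"cyclic paths: {_cyclic_paths(config)}"
        )
    return np.linalg.inv(np.eye(len(config.traits)) - B)


def _latent_sd(config: SimulationConfig) -> np.ndarray:
    R = reduced_form(config)
    within = R @ (config.shared_cov() + config.unique_cov()) @ R.T
    return np.sqrt(np.diag(within))


def simulate_pairs(config: SimulationConfig) -> pd.DataFrame:
    """Draw a complete-pair dataset; same seed gives byte-identical output.

    Returns a long-format frame with columns pair_id, twin_index, age, one
    column per trait (raw scale when the config carries inverse transforms,
    standardized latent scale otherwise) and optionally a stratifier.  The
    count of latent draws clamped at the raw-transform domain edge is stored
    in ``frame.attrs['n_clamped']``.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.traits)
    m = config.n_pairs
    R = reduced_form(config)
    S, U = config.shared_cov(), config.unique_cov()

    # pair-shared shock: one draw per pair, copied to both twins
    L_shared = np.linalg.cholesky(S + 1e-12 * np.eye(k))
    shared = rng.standard_normal((m, k)) @ L_shared.T
    unique = rng.standard_normal((m, 2, k)) * np.sqrt(np.diag(U))
    u = shared[:, None, :] + unique  # (m, 2, k)
    latent = np.einsum("ij,mtj->mti", R, u)
    latent = latent / _latent_sd(config)  # standardized latent scores

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=m)  # shared within pair
    age_c = age - (lo + hi) / 2.0

    frame = pd.DataFrame(
        {
            "pair_id": np.repeat([f"P{i:05d}" for i in range(m)], 2),
            "twin_index": np.tile([1, 2], m),
            "age": np.repeat(age, 2),
        }
    )
    n_clamped = 0
    for j, trait in enumerate(config.traits):
        z = latent[:, :, j].reshape(-1)
        z = z + config.age_slope.get(trait, 0.0) * np.repeat(age_c, 2)
        transform = config.raw_transform.get(trait)
        if transform is None:
            frame[trait] = z
        else:
            n_clamped += transform.n_clamped(z)
            frame[trait] = transform.inverse(z)
    if config.stratifier_range is not None:
        s_lo, s_hi = config.stratifier_range
        frame["stratifier"] = np.repeat(rng.uniform(s_lo, s_hi, size=m), 2)
    frame.attrs["n_clamped"] = n_clamped
    frame.attrs["seed"] = config.seed
    return frame


def write_dataset_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def read_dataset_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"pair_id", "twin_index", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    return df
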