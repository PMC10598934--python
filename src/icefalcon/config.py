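"""Configuration objects for the simulator, preprocessing and pipeline runs.

All configs are plain dataclasses with YAML/JSON round-trips so that a whole
analysis (simulation -> risk scores -> correlations -> causal decomposition)
is reproducible from a single text file plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "RawScale",
    "SimulationConfig",
    "TransformSpec",
    "AnalysisSpec",
    "RunConfig",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class RawScale:
    """Inverse link carrying a standardized latent score to a skewed raw scale.

    The latent (plus age effect) z is mapped to t = loc + scale * z and then
    to the raw measure ``t**(1/lam) - shift`` (``exp(t) - shift`` for lam=0).
    Applying the forward power transform ``(raw + shift)**lam`` therefore
    recovers t, an affine function of the latent, so preprocessing can be
    exercised end to end.
    """

    lam: float
    shift: float = 0.0
    loc: float = 0.0
    scale: float = 1.0

    def inverse(self, z: np.ndarray) -> np.ndarray:
        t = self.loc + self.scale * np.asarray(z, dtype=float)
        if self.lam == 0.0:
            return np.exp(t) - self.shift
        # power family needs t > 0; callers count any clamped values
        return np.power(np.maximum(t, 1e-12), 1.0 / self.lam) - self.shift

    def n_clamped(self, z: np.ndarray) -> int:
        if self.lam == 0.0:
            return 0
        t = self.loc + self.scale * np.asarray(z, dtype=float)
        return int(np.sum(t <= 1e-12))


@dataclass
class SimulationConfig:
    """Structural model for multi-trait MZ twin-pair data.

    The per-individual trait vector T solves T = B T + u where B holds the
    within-individual causal paths and the exogenous shock u is the sum of a
    trait-specific pair-shared component (``familial_loading``), pair-shared
    latent confounders (``shared_confounders``, unit variance, one loading per
    trait) and an individual-specific component (``unique_sd``).  Twins are
    exchangeable by construction; a twin's score never acts directly on her
    co-twin's scores.
    """

    n_pairs: int
    traits: list[str]
    causal_paths: dict[tuple[str, str], float] = field(default_factory=dict)
    familial_loading: dict[str, float] = field(default_factory=dict)
    unique_sd: dict[str, float] = field(default_factory=dict)
    shared_confounders: list[dict[str, float]] = field(default_factory=list)
    age_range: tuple[float, float] = (40.0, 70.0)
    age_slope: dict[str, float] = field(default_factory=dict)
    raw_transform: dict[str, RawScale] = field(default_factory=dict)
    stratifier_range: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError(f"n_pairs must be >= 2, got {self.n_pairs}")
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("duplicate trait names")
        for t in self.traits:
            sd = self.unique_sd.get(t, 1.0)
            if not sd > 0:
                raise ValueError(f"unique_sd for {t!r} must be > 0, got {sd}")
            if self.familial_loading.get(t, 0.0) < 0:
                raise ValueError(f"familial_loading for {t!r} must be >= 0")
        for (src, dst) in self.causal_paths:
            for name in (src, dst):
                if name not in self.traits:
                    raise ValueError(f"causal path references unknown trait {name!r}")
            if src == dst:
                raise ValueError(f"self-loop {src!r} -> {dst!r} not allowed")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age_range must be (min, max) with max > min")

    # -- matrix views used by both the sampler and the moment oracle --------

    def path_matrix(self) -> np.ndarray:
        """B with B[target, source] = path coefficient."""
        idx = {t: i for i, t in enumerate(self.traits)}
        B = np.zeros((len(self.traits), len(self.traits)))
        for (src, dst), coef in self.causal_paths.items():
            B[idx[dst], idx[src]] = coef
        return B

    def shared_cov(self) -> np.ndarray:
        """Covariance of the pair-shared part of the exogenous shock u."""
        k = len(self.traits)
        S = np.diag([self.familial_loading.get(t, 0.0) ** 2 for t in self.traits])
        for conf in self.shared_confounders:
            lam = np.array([conf.get(t, 0.0) for t in self.traits])
            S = S + np.outer(lam, lam)
        return S

    def unique_cov(self) -> np.ndarray:
        return np.diag([self.unique_sd.get(t, 1.0) ** 2 for t in self.traits])


@dataclass(frozen=True)
class TransformSpec:
    """Power transform (v + shift)**lam applied to a raw measure (log for lam=0)."""

    trait: str
    lam: float
    shift: float = 0.0

    def __call__(self, values: np.ndarray) -> np.ndarray:
        from .preprocess import apply_transform

        return apply_transform(values, self)


@dataclass
class AnalysisSpec:
    predictor: str
    outcome: str
    adjust_for: Optional[str] = None

    def __post_init__(self) -> None:
        if self.predictor == self.outcome:
            raise ValueError("predictor and outcome must be distinct traits")
        if self.adjust_for in (self.predictor, self.outcome):
            raise ValueError("adjust_for must differ from predictor and outcome")


@dataclass
class RunConfig:
    """One end-to-end run: input, transforms, analyses, inference settings."""

    input_csv: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    transforms: dict[str, TransformSpec] = field(default_factory=dict)
    analyses: list[AnalysisSpec] = field(default_factory=list)
    n_bootstrap: int = 1000
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "falcon_out"
    standardize_ddof: int = 1
    ci_n_convention: str = "pairs"  # or "double_entry"

    def __post_init__(self) -> None:
        if self.input_csv is None and self.simulation is None:
            raise ValueError("RunConfig needs either input_csv or simulation")


# ---------------------------------------------------------------------------
# serialization


def _sim_to_dict(sim: SimulationConfig) -> dict:
    d = asdict(sim)
    d["causal_paths"] = {f"{s}->{t}": c for (s, t), c in sim.causal_paths.items()}
    d["raw_transform"] = {t: asdict(r) for t, r in sim.raw_transform.items()}
    d["age_range"] = list(sim.age_range)
    if sim.stratifier_range is not None:
        d["stratifier_range"] = list(sim.stratifier_range)
    return d


def _sim_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    paths = {}
    for key, coef in (d.get("causal_paths") or {}).items():
        src, _, dst = key.partition("->")
        paths[(src.strip(), dst.strip())] = float(coef)
    d["causal_paths"] = paths
    d["raw_transform"] = {
        t: RawScale(**r) for t, r in (d.get("raw_transform") or {}).items()
    }
    d["age_range"] = tuple(d.get("age_range", (40.0, 70.0)))
    if d.get("stratifier_range") is not None:
        d["stratifier_range"] = tuple(d["stratifier_range"])
    return SimulationConfig(**d)


def run_config_to_dict(cfg: RunConfig) -> dict:
    d = {
        "input_csv": cfg.input_csv,
        "simulation": _sim_to_dict(cfg.simulation) if cfg.simulation else None,
        "transforms": {t: asdict(s) for t, s in cfg.transforms.items()},
        "analyses": [asdict(a) for a in cfg.analyses],
        "n_bootstrap": cfg.n_bootstrap,
        "alpha": cfg.alpha,
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
        "standardize_ddof": cfg.standardize_ddof,
        "ci_n_convention": cfg.ci_n_convention,
    }
    return d


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if d.get("simulation"):
        d["simulation"] = _sim_from_dict(d["simulation"])
    d["transforms"] = {
        t: TransformSpec(**s) for t, s in (d.get("transforms") or {}).items()
    }
    d["analyses"] = [AnalysisSpec(**a) for a in (d.get("analyses") or [])]
    return RunConfig(**d)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return run_config_from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = run_config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
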