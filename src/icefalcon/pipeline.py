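"""Orchestration: simulate -> risk scores -> correlations -> decompositions.

One RunConfig drives the whole analysis and everything lands in an output
directory as plain text: the dataset (when simulated), the correlation table,
one coefficient table per analysis, a JSON bundle of full-precision
decompositions, the causal diagram in DOT and JSON, and a log of seeds and
software versions.  Formatted tables round by fixed rules (coefficients to 3
decimals, Pr to integer percent); the JSON keeps full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import RunConfig, TransformSpec
from .correlations import correlation_table, within_pair_correlation
from .falcon import (
    Decomposition,
    DirectionResult,
    IceFalconTriplet,
    PairAnalysisResult,
    decompose,
    infer_conclusion,
    run_pair_analysis,
)
from .preprocess import build_risk_scores, fit_boxcox, variance_explained
from .simulate import read_dataset_csv, simulate_pairs, write_dataset_csv

logger = logging.getLogger("icefalcon")

__all__ = [
    "CausalGraph",
    "run_pipeline",
    "export_graph",
    "direction_from_reported",
    "bidirectional_from_reported",
    "format_conclusion",
    "format_table",
]


# ---------------------------------------------------------------------------
# worked-example entry point: build results from already-reported coefficients


def direction_from_reported(
    predictor: str,
    outcome: str,
    beta_self: float,
    beta_self_prime: float,
    beta_cotwin: float,
    beta_cotwin_prime: float,
    rho: float,
    p_beta_cotwin: float,
    change_p_self: float,
    change_p_cotwin: float,
) -> DirectionResult:
    """Assemble one direction's result from externally reported coefficients.

    Bypasses fitting entirely: used to re-derive decompositions and
    conclusions from a printed coefficient table.
    """
    triplet = IceFalconTriplet(
        beta_self=beta_self,
        beta_cotwin=beta_cotwin,
        beta_self_prime=beta_self_prime,
        beta_cotwin_prime=beta_cotwin_prime,
        p={"beta_cotwin": p_beta_cotwin},
    )
    dec = decompose(triplet, rho, change_p_self, change_p_cotwin)
    return DirectionResult(predictor, outcome, triplet, rho, dec, bootstrap=None)


def bidirectional_from_reported(
    forward: DirectionResult,
    reverse: DirectionResult,
    adjust_for: Optional[str] = None,
    alpha: float = 0.05,
) -> PairAnalysisResult:
    summary = infer_conclusion(forward, reverse, alpha)
    summary["adjust_for"] = adjust_for
    return PairAnalysisResult(forward=forward, reverse=reverse, adjust_for=adjust_for, summary=summary)


# ---------------------------------------------------------------------------
# formatting


def _display(trait: str, names: Optional[dict[str, str]]) -> str:
    return (names or {}).get(trait, trait)


def _verb(subject: str) -> str:
    # "light areas cause ...", "Cirrus causes ..."
    return "cause" if subject.lower().endswith("areas") else "causes"


def format_conclusion(
    result: PairAnalysisResult,
    names: Optional[dict[str, str]] = None,
    object_names: Optional[dict[str, str]] = None,
) -> str:
    """One-line conclusion in the style of the published coefficient tables.

    ``names`` maps trait keys to subject-position display names and
    ``object_names`` (defaulting to ``names``) to object-position spelling.
    """
    object_names = object_names or names
    parts = []
    for d in (result.forward, result.reverse):
        if d.label in ("causation", "combination"):
            x, y = _display(d.predictor, names), _display(d.outcome, object_names)
            tail = (
                f" not through {_display(result.adjust_for, object_names)}"
                if result.adjust_for
                else ""
            )
            parts.append(f"{x} {_verb(x)} {y}{tail} ({round(d.decomposition.pr * 100)}%)")
    if not parts:
        return "No evidence of causation"
    return "; ".join(parts)


def format_table(
    result: PairAnalysisResult, names: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Coefficient table for one analysis: both directions, both roles."""
    rows = []
    for d in (result.forward, result.reverse):
        t, dec = d.triplet, d.decomposition
        assignment = f"{_display(d.predictor, names)}-{_display(d.outcome, names)}"
        for role, m1_est, m3_est, m1_key, m3_key, change, change_p in (
            ("self", t.beta_self, t.beta_self_prime, "beta_self", "beta_self_prime",
             dec.change_self, dec.change_p_self),
            ("cotwin", t.beta_cotwin, t.beta_cotwin_prime, "beta_cotwin", "beta_cotwin_prime",
             dec.change_cotwin, dec.change_p_cotwin),
        ):
            rows.append(
                {
                    "assignment": assignment,
                    "role": role,
                    "model12_coef": round(m1_est, 3),
                    "model12_se": round(t.se.get(m1_key, float("nan")), 3),
                    "model12_p": t.p.get(m1_key, float("nan")),
                    "model3_coef": round(m3_est, 3),
                    "model3_se": round(t.se.get(m3_key, float("nan")), 3),
                    "model3_p": t.p.get(m3_key, float("nan")),
                    "change": round(change, 3),
                    "change_p": change_p,
                    "rho": round(d.rho, 3),
                    "pr_percent": round(dec.pr * 100),
                    "causal_effect": round(dec.causal_effect, 3),
                    "confounding_fraction": round(dec.confounding_fraction, 3),
                    "label": d.label,
                    "conclusion": format_conclusion(result, names),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# causal diagram


@dataclass
class CausalGraph:
    """Directed diagram of the inferred causal pathways between risk scores.

    Edge weights are the causal effects (beta_self * Pr); familial-confounding
    links are deliberately not drawn, only noted in the metadata.
    """

    nodes: list[str]
    edges: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"nodes": self.nodes, "edges": self.edges, "metadata": self.metadata}

    @classmethod
    def from_json_dict(cls, d: dict) -> "CausalGraph":
        return cls(nodes=list(d["nodes"]), edges=list(d["edges"]), metadata=dict(d.get("metadata", {})))

    def to_dot(self) -> str:
        lines = ["digraph causal_pathways {", "  rankdir=LR;"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for e in self.edges:
            width = 1.0 + 4.0 * abs(e["causal_effect"])
            lines.append(
                f'  "{e["source"]}" -> "{e["target"]}" '
                f'[label="{e["causal_effect"]:.2f} (Pr={round(e["pr"] * 100)}%)", '
                f"penwidth={width:.2f}];"
            )
        lines.append("}")
        return "\n".join(lines)

    @classmethod
    def from_dot(cls, text: str) -> "CausalGraph":
        """Parse the subset of DOT emitted by :meth:`to_dot` (round-trip aid)."""
        import re

        nodes, edges = [], []
        for line in text.splitlines():
            line = line.strip()
            m = re.match(r'^"([^"]+)" -> "([^"]+)" \[label="(-?[\d.]+) \(Pr=(-?\d+)%\)"', line)
            if m:
                edges.append(
                    {
                        "source": m.group(1),
                        "target": m.group(2),
                        "causal_effect": float(m.group(3)),
                        "pr": int(m.group(4)) / 100,
                    }
                )
            else:
                m2 = re.match(r'^"([^"]+)";$', line)
                if m2:
                    nodes.append(m2.group(1))
        return cls(nodes=nodes, edges=edges)


def export_graph(
    results: list[PairAnalysisResult], names: Optional[dict[str, str]] = None
) -> CausalGraph:
    """Collect causation/combination directions into a weighted digraph."""
    nodes: list[str] = []
    edges: list[dict] = []
    omitted: list[dict] = []
    for res in results:
        for d in (res.forward, res.reverse):
            for t in (d.predictor, d.outcome):
                disp = _display(t, names)
                if disp not in nodes:
                    nodes.append(disp)
            entry = {
                "source": _display(d.predictor, names),
                "target": _display(d.outcome, names),
                "pr": d.decomposition.pr,
                "causal_effect": d.decomposition.causal_effect,
                "confounding_fraction": d.decomposition.confounding_fraction,
                "adjust_for": res.adjust_for,
                "label": d.label,
            }
            if d.label in ("causation", "combination"):
                edges.append(entry)
            else:
                omitted.append({k: entry[k] for k in ("source", "target", "label")})
    if not edges:
        logger.warning("no causation/combination directions: graph is empty")
    meta = {
        "note": "familial-confounding links between score pairs are not drawn",
        "omitted_directions": omitted,
    }
    return CausalGraph(nodes=nodes, edges=edges, metadata=meta)


# ---------------------------------------------------------------------------
# pipeline


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "icefalcon": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(cfg: RunConfig, names: Optional[dict[str, str]] = None) -> dict:
    """Run every configured analysis end to end and write the report bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"versions: {_versions()}", f"seed: {cfg.seed}", f"B: {cfg.n_bootstrap}", f"alpha: {cfg.alpha}"]

    try:
        if cfg.simulation is not None:
            sim_cfg = cfg.simulation
            dataset = simulate_pairs(sim_cfg)
            write_dataset_csv(dataset, out / "dataset.csv")
            log_lines.append(f"simulated n_pairs: {sim_cfg.n_pairs} (clamped draws: {dataset.attrs['n_clamped']})")
        else:
            dataset = read_dataset_csv(cfg.input_csv)
            log_lines.append(f"input: {cfg.input_csv}")
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    traits = sorted(
        {a.predictor for a in cfg.analyses}
        | {a.outcome for a in cfg.analyses}
        | {a.adjust_for for a in cfg.analyses if a.adjust_for}
    )
    try:
        transforms: dict[str, TransformSpec] = {}
        for t in traits:
            if t in cfg.transforms:
                transforms[t] = cfg.transforms[t]
            else:
                transforms[t] = fit_boxcox(dataset[t].to_numpy(dtype=float), trait=t)
                log_lines.append(
                    f"fitted transform {t}: lambda={transforms[t].lam:.4f} shift={transforms[t].shift}"
                )
        scores = build_risk_scores(dataset, transforms, ddof=cfg.standardize_ddof)
        log_lines.append(f"dropped incomplete pairs: {scores.attrs['n_dropped_pairs']}")
        for t in traits:
            tmp = dataset.copy()
            tmp["_t"] = transforms[t](dataset[t].to_numpy(dtype=float))
            r2 = variance_explained(tmp, "_t", ["age"])
            log_lines.append(f"age R^2 for {t}: {r2:.4f}")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        corr = correlation_table(scores, traits, n_convention=cfg.ci_n_convention)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6f")
    except Exception as exc:
        raise RuntimeError(f"stage 'correlations' failed: {exc}") from exc

    results: list[PairAnalysisResult] = []
    decomposition_bundle = []
    for i, spec in enumerate(cfg.analyses):
        try:
            res = run_pair_analysis(
                scores,
                spec.predictor,
                spec.outcome,
                adjust_for=spec.adjust_for,
                B=cfg.n_bootstrap,
                seed=cfg.seed + 1000 * (i + 1),
                alpha=cfg.alpha,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'analysis {spec.predictor}->{spec.outcome}' failed: {exc}"
            ) from exc
        results.append(res)
        tag = f"{spec.predictor}_{spec.outcome}" + (f"_adj_{spec.adjust_for}" if spec.adjust_for else "")
        format_table(res, names).to_csv(out / f"coefficients_{tag}.tsv", sep="\t", index=False)
        for d in (res.forward, res.reverse):
            log_lines.append(
                f"analysis {d.predictor}->{d.outcome}"
                + (f" (adjusted for {res.adjust_for})" if res.adjust_for else "")
                + f": rho={d.rho:.6f} computed on the "
                + ("third-score-adjusted" if res.adjust_for else "age-adjusted")
                + " predictor score"
            )
            decomposition_bundle.append(
                {
                    "predictor": d.predictor,
                    "outcome": d.outcome,
                    "adjust_for": res.adjust_for,
                    "beta_self": d.triplet.beta_self,
                    "beta_cotwin": d.triplet.beta_cotwin,
                    "beta_self_prime": d.triplet.beta_self_prime,
                    "beta_cotwin_prime": d.triplet.beta_cotwin_prime,
                    "rho": d.rho,
                    "pr": d.decomposition.pr,
                    "causal_effect": d.decomposition.causal_effect,
                    "confounding_fraction": d.decomposition.confounding_fraction,
                    "change_p_self": d.decomposition.change_p_self,
                    "change_p_cotwin": d.decomposition.change_p_cotwin,
                    "out_of_range": d.decomposition.out_of_range,
                    "label": d.label,
                }
            )

    (out / "decompositions.json").write_text(json.dumps(decomposition_bundle, indent=2))
    graph = export_graph(results, names)
    (out / "graph.dot").write_text(graph.to_dot())
    (out / "graph.json").write_text(json.dumps(graph.to_json_dict(), indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "dataset": dataset,
        "scores": scores,
        "correlations": corr,
        "results": results,
        "graph": graph,
        "output_dir": str(out),
    }
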