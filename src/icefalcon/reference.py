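"""Reference coefficient table for the MZ-twin mammogram risk-score study.

These are the reported GEE coefficients (Models 1-3), model p-values and
change p-values for every ordered assignment of the four risk scores —
light, bright and brightest dense areas and the Cirrus texture score — on
371 monozygotic twin pairs, plus the within-pair correlations of each score.
They serve as worked-example inputs: feeding them through
:func:`icefalcon.falcon.decompose` and the conclusion rules re-derives the
reported causal fractions and conclusions without refitting anything.
"""

from __future__ import annotations

from .pipeline import bidirectional_from_reported, direction_from_reported

__all__ = [
    "N_PAIRS",
    "REPORTED_RHO",
    "REPORTED_RHO_ADJUSTED",
    "REPORTED_MODELS",
    "DISPLAY_NAMES",
    "OBJECT_NAMES",
    "reported_pair_results",
]

N_PAIRS = 371

#: within-pair (double-entry) correlation of each risk score
REPORTED_RHO = {"light": 0.59, "bright": 0.53, "brightest": 0.34, "cirrus": 0.48}

#: within-pair correlations after additionally adjusting for Cirrus
REPORTED_RHO_ADJUSTED = {"light": 0.55, "bright": 0.41, "brightest": 0.22}

DISPLAY_NAMES = {
    "light": "Light areas",
    "bright": "Bright areas",
    "brightest": "Brightest areas (Cirrocumulus)",
    "cirrus": "Cirrus",
}

#: object-position spelling used in conclusion sentences
OBJECT_NAMES = {
    "light": "light areas",
    "bright": "bright areas",
    "brightest": "brightest areas (Cirrocumulus)",
    "cirrus": "Cirrus",
}

#: one entry per ordered assignment (predictor, outcome); "adjusted" marks the
#: Cirrus-adjusted reruns.  p_cotwin is the Model 2 p-value; change_p_* are
#: the reported p-values of the Model 1->3 / Model 2->3 coefficient changes.
REPORTED_MODELS = [
    dict(predictor="light", outcome="bright", adjusted=False,
         beta_self=0.802, beta_self_prime=0.770, beta_cotwin=0.513, beta_cotwin_prime=0.070,
         p_cotwin=4e-35, change_p_self=2e-2, change_p_cotwin=8e-34),
    dict(predictor="bright", outcome="light", adjusted=False,
         beta_self=0.770, beta_self_prime=0.727, beta_cotwin=0.404, beta_cotwin_prime=0.144,
         p_cotwin=1e-19, change_p_self=5e-5, change_p_cotwin=1e-13),
    dict(predictor="light", outcome="cirrus", adjusted=False,
         beta_self=0.352, beta_self_prime=0.328, beta_cotwin=0.176, beta_cotwin_prime=0.087,
         p_cotwin=4e-6, change_p_self=2e-2, change_p_cotwin=1e-5),
    dict(predictor="cirrus", outcome="light", adjusted=False,
         beta_self=0.285, beta_self_prime=0.303, beta_cotwin=0.091, beta_cotwin_prime=0.135,
         p_cotwin=6e-3, change_p_self=2e-2, change_p_cotwin=3e-3),
    dict(predictor="bright", outcome="cirrus", adjusted=False,
         beta_self=0.398, beta_self_prime=0.367, beta_cotwin=0.215, beta_cotwin_prime=0.139,
         p_cotwin=1e-8, change_p_self=2e-3, change_p_cotwin=2e-4),
    dict(predictor="cirrus", outcome="bright", adjusted=False,
         beta_self=0.361, beta_self_prime=0.355, beta_cotwin=0.165, beta_cotwin_prime=0.163,
         p_cotwin=6e-6, change_p_self=0.5, change_p_cotwin=0.9),
    dict(predictor="brightest", outcome="cirrus", adjusted=False,
         beta_self=0.351, beta_self_prime=0.356, beta_cotwin=0.138, beta_cotwin_prime=0.166,
         p_cotwin=9e-5, change_p_self=0.5, change_p_cotwin=8e-2),
    dict(predictor="cirrus", outcome="brightest", adjusted=False,
         beta_self=0.389, beta_self_prime=0.360, beta_cotwin=0.191, beta_cotwin_prime=0.114,
         p_cotwin=5e-7, change_p_self=4e-3, change_p_cotwin=3e-5),
    dict(predictor="light", outcome="brightest", adjusted=False,
         beta_self=0.470, beta_self_prime=0.424, beta_cotwin=0.284, beta_cotwin_prime=0.103,
         p_cotwin=2e-12, change_p_self=8e-3, change_p_cotwin=9e-13),
    dict(predictor="brightest", outcome="light", adjusted=False,
         beta_self=0.347, beta_self_prime=0.395, beta_cotwin=0.113, beta_cotwin_prime=0.221,
         p_cotwin=8e-4, change_p_self=6e-5, change_p_cotwin=3e-9),
    dict(predictor="bright", outcome="brightest", adjusted=False,
         beta_self=0.680, beta_self_prime=0.653, beta_cotwin=0.378, beta_cotwin_prime=0.058,
         p_cotwin=2e-22, change_p_self=6e-2, change_p_cotwin=5e-25),
    dict(predictor="brightest", outcome="bright", adjusted=False,
         beta_self=0.619, beta_self_prime=0.606, beta_cotwin=0.136, beta_cotwin_prime=0.202,
         p_cotwin=4e-4, change_p_self=0.2, change_p_cotwin=2e-2),
    dict(predictor="light", outcome="brightest", adjusted=True,
         beta_self=0.386, beta_self_prime=0.365, beta_cotwin=0.198, beta_cotwin_prime=0.051,
         p_cotwin=5e-6, change_p_self=0.2, change_p_cotwin=5e-10),
    dict(predictor="brightest", outcome="light", adjusted=True,
         beta_self=0.287, beta_self_prime=0.339, beta_cotwin=0.046, beta_cotwin_prime=0.165,
         p_cotwin=0.2, change_p_self=2e-5, change_p_cotwin=7e-11),
    dict(predictor="bright", outcome="brightest", adjusted=True,
         beta_self=0.608, beta_self_prime=0.597, beta_cotwin=0.268, beta_cotwin_prime=0.033,
         p_cotwin=2e-9, change_p_self=0.3, change_p_cotwin=2e-13),
    dict(predictor="brightest", outcome="bright", adjusted=True,
         beta_self=0.562, beta_self_prime=0.569, beta_cotwin=0.058, beta_cotwin_prime=0.153,
         p_cotwin=0.2, change_p_self=0.3, change_p_cotwin=1e-3),
]


def _direction(entry: dict):
    rho_table = REPORTED_RHO_ADJUSTED if entry["adjusted"] else REPORTED_RHO
    return direction_from_reported(
        predictor=entry["predictor"],
        outcome=entry["outcome"],
        beta_self=entry["beta_self"],
        beta_self_prime=entry["beta_self_prime"],
        beta_cotwin=entry["beta_cotwin"],
        beta_cotwin_prime=entry["beta_cotwin_prime"],
        rho=rho_table[entry["predictor"]],
        p_beta_cotwin=entry["p_cotwin"],
        change_p_self=entry["change_p_self"],
        change_p_cotwin=entry["change_p_cotwin"],
    )


def reported_pair_results(include_adjusted: bool = True):
    """Bidirectional results for every reported trait pair, from the table.

    Returns a list of PairAnalysisResult built purely from the reported
    coefficients (no fitting), with conclusions re-derived by the decision
    rules.
    """
    results = []
    seen = set()
    for entry in REPORTED_MODELS:
        if entry["adjusted"] and not include_adjusted:
            continue
        key = (frozenset((entry["predictor"], entry["outcome"])), entry["adjusted"])
        if key in seen:
            continue
        seen.add(key)
        reverse_entry = next(
            e
            for e in REPORTED_MODELS
            if e["predictor"] == entry["outcome"]
            and e["outcome"] == entry["predictor"]
            and e["adjusted"] == entry["adjusted"]
        )
        results.append(
            bidirectional_from_reported(
                _direction(entry),
                _direction(reverse_entry),
                adjust_for="cirrus" if entry["adjusted"] else None,
            )
        )
    return results
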