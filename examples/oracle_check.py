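"""Moment oracle vs estimation: exact population values against a large fit.

Builds a two-trait structural model (causal path plus a pair-shared
confounder), computes the exact population Model 1-3 coefficients and Pr
from the covariance algebra, then checks that estimates on a 50,000-pair
simulation agree within bootstrap Monte-Carlo error.

Run:  python examples/oracle_check.py
"""

from icefalcon.correlations import within_pair_correlation
from icefalcon.falcon import bootstrap_triplets, decompose, fit_models
from icefalcon.moments import theoretical_coefficients
from icefalcon.presets import two_trait_config
from icefalcon.simulate import simulate_pairs

cfg = two_trait_config(
    50000, causal_xy=0.4, confounder_x=0.5, confounder_y=0.4,
    familial_x=0.3, unique_x=0.7, unique_y=0.8, seed=42,
)
mom, theory, theory_dec = theoretical_coefficients(cfg, "x", "y")
data = simulate_pairs(cfg)
trip = fit_models(data, "x", "y")
boot = bootstrap_triplets(data, "x", "y", B=200, seed=42)
rho = within_pair_correlation(data, "x").r
est_dec = decompose(trip, rho)

print(f"{'coefficient':20s}{'population':>12s}{'estimate':>12s}{'boot SE':>10s}{'z':>7s}")
for k in ("beta_self", "beta_cotwin", "beta_self_prime", "beta_cotwin_prime"):
    th, est, se = getattr(theory, k), getattr(trip, k), boot[k].std(ddof=1)
    print(f"{k:20s}{th:12.4f}{est:12.4f}{se:10.4f}{(est - th) / se:7.2f}")
print(f"{'rho (within-pair X)':20s}{mom.rho_x:12.4f}{rho:12.4f}")
print(f"{'Pr':20s}{theory_dec.pr:12.4f}{est_dec.pr:12.4f}")

print(
    "\n|z| values around 1 mean the estimator sits on its population target\n"
    "at Monte-Carlo precision.  The population coefficients are the marginal\n"
    "projection coefficients (covariance ratios for Models 1-2, 2x2 normal\n"
    "equations for Model 3) that the path-tracing decomposition is derived\n"
    "for; the fitted models estimate exactly these under the default\n"
    "independence working correlation with pair-clustered robust SEs."
)
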