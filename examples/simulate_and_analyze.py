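"""Full pipeline on synthetic twin data: simulate -> risk scores -> ICE FALCON.

Draws a study-sized sample (371 MZ pairs) from the calibrated four-trait
structural model, builds the standardized age-adjusted risk scores with the
published power transforms, and runs the bidirectional three-model analysis
for the light-areas / bright-areas pair.

Run:  python examples/simulate_and_analyze.py
"""

from icefalcon.config import TransformSpec
from icefalcon.falcon import run_pair_analysis
from icefalcon.preprocess import build_risk_scores
from icefalcon.presets import calibrated_config
from icefalcon.simulate import simulate_pairs

cfg = calibrated_config(n_pairs=371, seed=7)
raw = simulate_pairs(cfg)
print(f"simulated {cfg.n_pairs} twin pairs; raw light-areas median "
      f"{raw['light'].median():.1f} cm^2, ages {raw['age'].min():.0f}-{raw['age'].max():.0f}")

transforms = {
    "light": TransformSpec("light", lam=1 / 3),
    "bright": TransformSpec("bright", lam=1 / 3),
}
scores = build_risk_scores(raw, transforms)

res = run_pair_analysis(scores, "light", "bright", B=1000, seed=7)
for d in (res.forward, res.reverse):
    t, dec = d.triplet, d.decomposition
    print(f"\n{d.predictor} -> {d.outcome}:  rho = {d.rho:.3f}")
    print(f"  Model 1 beta_self    = {t.beta_self:.3f} (se {t.se['beta_self']:.3f})")
    print(f"  Model 2 beta_cotwin  = {t.beta_cotwin:.3f} (se {t.se['beta_cotwin']:.3f})")
    print(f"  Model 3 beta'_self   = {t.beta_self_prime:.3f}, beta'_cotwin = {t.beta_cotwin_prime:.3f}")
    print(f"  changes: self {dec.change_self:+.3f} (p={dec.change_p_self:.3g}), "
          f"cotwin {dec.change_cotwin:+.3f} (p={dec.change_p_cotwin:.3g})")
    print(f"  Pr = {dec.pr * 100:.0f}%  causal effect = {dec.causal_effect:.2f}  label = {d.label}")

print(
    "\nAt this sample size the per-direction labels are noisy; the population\n"
    "truth for this calibrated model has bidirectional causation between the\n"
    "light and bright areas with most of the association causal in the\n"
    "light->bright direction."
)
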