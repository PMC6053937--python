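"""Simulate a playback experiment and fit the response-model suite.

The community's ground truth puts a strong positive effect of caller
consistency (+1.74 on the logit scale) on response probability; the fitted
binomial mixed model should recover it, while the null covariates stay
non-significant.
"""

import alarmnet as an
from alarmnet import models

cfg = an.generate_community(seed=1)
idx = an.true_indices(cfg)
pb = an.simulate_playbacks(cfg, idx, n_per_pair=17, seed=5)
print(f"{len(pb)} playback trials, "
      f"{(pb['call_kind'] == 'control').sum()} control")

prelim, filtered = models.preliminary_calltype_model(pb, include_interaction=False)
print("\nPreliminary call-type model (contrasts vs control sound):")
print(prelim.coefficients.loc[["conspecific", "heterospecific"],
                              ["estimate", "se", "p"]].round(3))

fits = an.fit_response_models(filtered, idx, cfg.body_masses)
resp = fits["responded"]
print(f"\nResponse-probability mixed model (n = {resp.n}, "
      f"random-intercept SD = {resp.sigma:.2f}):")
show = ["consistency", "reliability", "similarity", "abundance", "size_ratio"]
print(resp.coefficients.loc[show, ["estimate", "se", "p"]].round(3))
print("\nThe consistency coefficient should be positive and significant "
      "(truth includes it); reliability and abundance effects were "
      "generated at zero.  The five other fits cover latency, duration and "
      "head-lift speed (log-linear mixed) and head-up / scratch counts "
      "(negative binomial):")
for name, f in fits.items():
    print(f"  {name:15s} n={f.n:5d}  AICc={f.aicc:9.1f}  converged={f.converged}")
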