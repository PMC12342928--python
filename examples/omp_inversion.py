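"""Estimate water-mass mixing fractions for a synthetic hydrographic section.

Generates a 10-station section from Kuroshio/Oyashio-style endmembers with
measurement-scale noise, inverts the six-property conservation system per
sample, and compares the recovered fractions with the generator's truth.
"""

import numpy as np

from oceanch4 import omp_section
from oceanch4 import synthetic as syn

cfg = syn.default_scenario(seed=1, n_stations=10)
samples, truth = syn.generate_section(cfg)
section = omp_section(samples, cfg.endmembers)

frac_cols = [f"frac_{n}" for n in cfg.endmembers.names]
mae = np.abs(section[frac_cols].to_numpy() - truth[frac_cols].to_numpy()).mean()

print(section[["station", "depth_m", *frac_cols, "R_mass", "dominant_mass"]].head(8))
print(f"\nmean absolute fraction error vs truth: {mae:.4f}")
print(f"worst mass-balance deviation |sum(x)-1|: "
      f"{np.abs(section[frac_cols].sum(axis=1) - 1).max():.2e}")
# Fractions are the contribution of each water mass to every sample; a mean
# absolute error of a few thousandths means property noise at instrument
# scale barely disturbs the inversion for these endmember contrasts.
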