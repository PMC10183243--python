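"""Case-dropping bootstrap: can we trust the centrality ordering?

Re-estimates the whole pipeline on subsamples with 10%...75% of
respondents removed and correlates each subsample's strength vector with
the full-sample one. The CS-coefficient is the largest drop fraction at
which that correlation stays >= 0.7 with 95% probability: below 0.25 the
index should not be interpreted, above 0.50 is preferred.

B is kept small here so the example runs in seconds; analyses should use
the default B = 1000 (or 250 for quick checks).
"""

import numpy as np

import symptomnet as sn

model = sn.make_truth(seed=1)
x = sn.sample_ordinal(model, n=318, seed=2)

res = sn.case_drop_bootstrap(
    x, "strength", proportions=np.arange(0.1, 0.71, 0.2), B=50, seed=5
)
for prop, mean_c in zip(res.proportions, res.mean_correlations()):
    print(f"drop {prop:.0%}: mean correlation with full sample {mean_c:+.2f}")

cs = sn.cs_coefficient(res)
print(f"CS-coefficient = {cs:.2f} -> {sn.interpret_cs(cs)}")
# In this weak-edged synthetic world the n = 318 strength ordering is
# fragile; published student-survey networks are considerably denser and
# reach CS values of 0.5 and above.
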