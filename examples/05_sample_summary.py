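"""Descriptive sample table: counts to percentages at print precision.

Reproduces the style of a socio-demographic sample description: category
counts within each variable are converted to percentages of the retained
sample, rounded half-away-from-zero to two decimals, and checked to sum
to 100 within rounding.
"""

import symptomnet as sn

counts = [
    ("worked_past_month", "yes", 284),
    ("worked_past_month", "no", 34),
    ("sex", "female", 279),
    ("sex", "male", 39),
]
summary = sn.summarize_sample(counts, n=318)
print(summary.table.to_string(index=False))
for variable in ("worked_past_month", "sex"):
    total = summary.table.query("variable == @variable").percent.sum()
    print(f"{variable}: percentages sum to {total:.2f}")
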