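"""Statistics of the published 42-sample reference cohort.

Loads the bundled cohort fixture (theoretical and measured shifts as
printed) and computes sensitivity, the minimum identified shift, and the
measured-vs-theoretical OLS under both conventions: detected samples only,
and all samples with not-detected entries at zero measured shift — the
convention that reproduces the published scatter-plot fit.
"""

import ttrscreen as t

table1 = t.load_table1()
sens = t.sensitivity_summary(table1)
print(f"sensitivity: {sens.detected}/{sens.total} "
      f"= {100 * sens.fraction:.1f}% (half-up {sens.percent}%; published 91%)")
print(f"minimum identified shift: {t.min_identified_shift(table1)} Da")

for conv in ("detected", "as_figure"):
    reg = t.table1_regression(table1, convention=conv)
    print(f"OLS [{conv:>9}] n={reg.n}: y = {reg.slope:.4f}x + {reg.intercept:+.4f}, "
          f"r^2 = {reg.r_squared:.4f}")
print("\nThe published fit (y = 0.9937x + 0.0834, r^2 = 0.9969) matches the"
      "\nall-42 convention: r^2 agrees exactly at printed precision.")
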