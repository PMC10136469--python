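"""Directional coupling: bivariate Granger causality per block.

A VAR with BIC-selected order is fit to the two members' task-period
HbO at the coupled channel pair; G-causality in each direction is the
log ratio of restricted to full residual variances.  A direction x
block repeated-measures ANOVA asks whether the information flow is
asymmetric and whether the asymmetry changes across blocks.
"""

import hyperdyad as hd
from hyperdyad.gca import cohort_granger, direction_test
from hyperdyad.preprocess import preprocess_cohort

config = hd.AnalysisConfig()
cohort = hd.gen_cohort(10, 0, seed=3)
kept, pairs, _ = preprocess_cohort(cohort, config)

gc = cohort_granger(kept, pairs, (3, 6), config)
print(gc.groupby("block")[["gc_m_to_f", "gc_f_to_m"]].mean().round(4))
print(f"(VAR order {gc['order'].iloc[0]} chosen by BIC)")

ftab, simple = direction_test(gc)
print("\ndirection x block repeated-measures ANOVA:")
print(ftab.table.round(4).to_string(index=False))
print("\nper-block direction contrasts (paired t):")
print(simple.round(4).to_string(index=False))
print("\nWith the generator's symmetric zero-lag coupling both "
      "directions are equal in expectation; a real male-led dynamic "
      "would show gc_m_to_f > gc_f_to_m.")
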