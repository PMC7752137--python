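"""Skull-normalized brain morphometry and a two-group comparison.

Builds a small two-group cohort (mutant brains 15% shorter, 5% biological
CV), measures each specimen's brain length from its landmark table,
normalizes to skull width, and runs the pooled-variance t-test.
"""
from zfmri import compare_groups
from zfmri.synthetic import simulate_morphometry_cohort

wildtype, mutant = simulate_morphometry_cohort(n_per_group=6,
                                               length_effect=0.85,
                                               cv=0.05, seed=1)
res = compare_groups(wildtype, mutant)
print(f"wild-type normalized length: {res.mean_a:.3f} +/- {res.sd_a:.3f} (n={res.n_a})")
print(f"mutant normalized length:    {res.mean_b:.3f} +/- {res.sd_b:.3f} (n={res.n_b})")
print(f"t = {res.t_statistic:.2f}, df = {res.degrees_of_freedom:.0f}, "
      f"p = {res.p_value:.2e}")
# the 15% true group difference is recovered and significant at n = 6 vs 6
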