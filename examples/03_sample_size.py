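"""Sample-size planning from test-retest summaries.

Two planning questions: how many subjects to pin down an agreement
index to a target CI width, and how many for a paired pre-post study
powered on the within-subject SD.
"""

import retest as rt

# How many subjects to estimate an ICC believed to be 0.9 with a full
# 95% CI width of at most 0.2?
spec = rt.PrecisionSpec(metric="icc", assumed_value=0.9, target_ci_width=0.2)
n = rt.n_for_precision(spec)
print(f"ICC precision   : rho=0.9, width<=0.2  ->  n = {n}")
print(f"  expected width at n   : {rt.expected_ci_width(spec, n):.4f}")
print(f"  expected width at n-1 : {rt.expected_ci_width(spec, n - 1):.4f}")

# Same precision logic for WSCV, driven by sigma_e and mu
wspec = rt.PrecisionSpec(metric="wscv", sigma_e=0.6, mu=12.0, target_ci_width=0.03)
print(f"WSCV precision  : sigma_e=0.6, mu=12, width<=0.03 -> n = {rt.n_for_precision(wspec)}")

# Paired pre-post design: the test-retest sigma_e supplies the paired
# difference SD sqrt(2)*sigma_e.
pspec = rt.PrePostSpec(effect_size=0.4, sigma_e=0.6, alpha=0.05, power=0.80)
print(f"pre-post design : delta=0.4, sigma_e=0.6, power 80% -> n = {rt.n_prepost(pspec)}")
print()
print("The precision search inverts the same interval formulas the package")
print("applies to data, with the F or chi-square statistic at its expected")
print("value under the assumed parameters.")
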