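"""Why PTRT can hide a bad scan that WSCV and ICC expose.

Simulates a seven-subject region where one subject's retest is inflated
by a kinetic-model identifiability failure (multiplicative outlier) and
contrasts the indices on clean vs. contaminated versions of the same
draw.  With a strong outlier the pattern of a poorly identified
quantification method appears: WSCV blows up toward ~0.7 and ICC
collapses, while the locally scaled PTRT stays near 0.2.
"""

import retest as rt

cfg = rt.SimulationConfig(
    n_subjects=7,
    regions=(rt.region_spec_from_targets("amygdala", mu=12.3, wscv=0.05, icc=0.93),),
    seed=2,
    contamination=rt.Contamination(n_outlier_subjects=1, multiplier=4.2,
                                   affected_scan=2),
)

df = rt.outlier_sensitivity_experiment(cfg, gammas=[1.0, 2.0, 3.0, 4.2], n_reps=200)
summary = df.groupby("gamma")[
    ["wscv_clean", "wscv_contaminated", "ptrt_clean", "ptrt_contaminated",
     "icc_clean", "icc_contaminated"]
].mean()
print(summary.round(3).to_string())
print()
at_top = df[df["gamma"] == 4.2]
frac = (at_top["rel_change_wscv"] > at_top["rel_change_ptrt"]).mean()
print(f"reps where WSCV inflates more than PTRT at gamma=4.2: {frac:.1%}")
print()
print("One x4.2 outlier among 7 subjects drives mean WSCV from ~0.05 to")
print("~0.6-0.7 and ICC toward ~0, while PTRT only reaches ~0.2 — a single")
print("summary statistic (PTRT) can make a corrupted dataset look healthy,")
print("which is why the ANOVA-based indices and a Bland-Altman plot should")
print("be reported alongside it.")
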