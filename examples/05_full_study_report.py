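"""Simulate a five-dataset corpus and produce a per-group report.

Emulates a multi-tracer test-retest corpus (5 datasets of 7, 10, 7, 5
and 8 subjects; 10 regions; 3 quantification methods) with the 2TC
method of the first dataset contaminated, then evaluates every group.
"""

import tempfile
from pathlib import Path

import retest as rt
from retest import io, report

df = rt.simulate_study(seed=0)
print(f"simulated {len(df)} rows, "
      f"{df.groupby(['dataset_id', 'method_id', 'region']).ngroups} groups")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "study.csv"
    io.write_long(df, path)
    groups = io.read_long(path, strict=True)

rep = report.run_report(groups, alpha=0.05)
amygdala_ds1 = rep.query("dataset_id == 'DS1' and region == 'amygdala'")
print()
print("DS1 amygdala, per quantification method (machine values):")
print(amygdala_ds1[["method_id", "WSCV", "PTRT", "ICC", "RC", "grand_mean"]]
      .round(3).to_string(index=False))
print()
print("The contaminated 2TC row shows the signature dissociation: WSCV and")
print("ICC degrade sharply while PTRT moves far less.")
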