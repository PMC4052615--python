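#!/usr/bin/env python
"""Detect MMPVs on the demo study and compare against the planted truth.

Expects results/demo/ from 01_simulate_demo.py. Writes the per-pair MMPV
table (correlations, q-values, class, pattern) and the summary counts, then
prints the confusion against the truth table.
"""

import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

import pandas as pd

from mmpv.pipeline import PipelineConfig, run_pipeline
from mmpv.synth import read_truth_table

out = REPO / "results" / "demo"
cfg = PipelineConfig(out_dir=out, seed=11, features=["ER"])
run_pipeline(cfg, ["detect"])

truth = read_truth_table(out / "truth.tsv")
mmpvs = pd.read_csv(out / "mmpv_ER.tsv", sep="\t")
detected = dict(zip(mmpvs["mirna_id"], mmpvs["mmpv_class"]))

print(f"detected {len(mmpvs)} MMPVs "
      f"({(mmpvs['mmpv_class'] == 'sign_change').sum()} sign-change, "
      f"{(mmpvs['mmpv_class'] == 'fold_change').sum()} fold-change)")
print(mmpvs[["mirna_id", "mrna_id", "r_status1", "r_status2",
             "mmpv_class", "pattern"]].to_string(index=False))

agree = sum(
    detected.get(row.mirna_id, "none") == row.expected_class
    for row in truth.itertuples(index=False)
)
print(f"agreement with planted truth: {agree}/{len(truth)}")
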