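#!/usr/bin/env python
"""Permutation differential expression and DE-MMPV selection on the demo.

Expects results/demo/ from scripts 01-02. Runs the moderated permutation
test (200 label permutations) on both matrices, BH-adjusts, and keeps
MMPVs whose miRNA and mRNA are both significant; these are the pairs whose
regulatory pattern AND expression level track the feature.
"""

import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

import pandas as pd

from mmpv.pipeline import PipelineConfig, run_pipeline

out = REPO / "results" / "demo"
cfg = PipelineConfig(out_dir=out, seed=11, features=["ER"])
run_pipeline(cfg, ["de"])

de = pd.read_csv(out / "de_mmpv_ER.tsv", sep="\t")
print(f"{len(de)} DE-MMPVs (miRNA and mRNA both q < 0.05):")
print(de.to_string(index=False))
print("direction letters: U = higher in status1 (ER+), D = higher in status2")
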