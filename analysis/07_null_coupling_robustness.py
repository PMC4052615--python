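#!/usr/bin/env python
"""How null-pair co-expression affects false discovery of the ratio rule.

The fold-change rule compares the ratio of the two stratum correlations to
a factor-2 threshold. When pairs that do NOT change their regulation still
share a weak common correlation (as validated targeting pairs often do in
bulk arrays), sampling noise in that ratio produces spurious fold-change
calls. This script measures null contamination of the standard recovery
experiment as the common null correlation spreads from 0 to 0.3, and
writes results/robustness/null_coupling.tsv.
"""

import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

import pandas as pd

from mmpv.experiments import parameter_recovery

OUT = REPO / "results" / "robustness"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for spread in (0.0, 0.1, 0.2, 0.3):
    r = parameter_recovery(seed=1, null_rho_spread=spread)
    rows.append(
        {
            "null_rho_spread": spread,
            "null_contamination": round(r["null_contamination"], 4),
            "n_null_reported": r["n_null_reported"],
            "n_reported": r["n_reported"],
            "sensitivity_sign": r["sensitivity_sign_change"],
            "sensitivity_fold": r["sensitivity_fold_change"],
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "null_coupling.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(
    "contamination grows with null co-expression: the PCC-ratio rule is "
    "only selective when unchanged pairs are weakly coupled"
)
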