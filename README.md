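# mmpv — differential correlation of miRNA–mRNA targeting pairs

`mmpv` detects **miRNA–mRNA paired variations (MMPVs)**: experimentally
validated targeting pairs whose *pattern of regulation* — the sign and
strength of the correlation between miRNA and mRNA expression — differs
between the two statuses of a binary biopathological feature (ER+/ER−,
mutant/wild-type TP53, HER2+/HER2−, five-year survival, basal/non-basal
subtype). It is aimed at transcriptomics analysts who have paired miRNA and
mRNA expression matrices over the same tumour samples, a binary sample
annotation, and a list of validated targeting pairs, and who want to ask
*where the regulatory relationship itself changes*, not merely which genes
change level.

## The statistic

For a targeting pair (miRNA *m*, mRNA *g*) and a feature with statuses
*s₁*, *s₂*, the package computes the Pearson correlation of the two
expression profiles within each stratum,

  r₁ = corr(mₛ₁, gₛ₁),  r₂ = corr(mₛ₂, gₛ₂),

with a two-sided t-test on n−2 degrees of freedom per stratum and
Benjamini–Hochberg FDR control across all pairs of the stratum. Pairs
insignificant in **both** strata (q ≥ α = 0.05 twice) are removed. The rest
are classified:

* **sign-change pair** — r₁ and r₂ have opposite signs;
* **fold-change pair** — same sign but r₁/r₂ ≥ 2 or ≤ ½.

Each detected pair is summarised as a pattern string such as `D_U_U*`:
healthy-population sign first (U = positive, D = negative regulation, from
the validated pair list), then the status1 and status2 signs, `*` marking
FDR-significant strata.

Downstream stages: a SAM-style moderated permutation test
d = (mean₁−mean₂)/(s+s₀) selects **DE-MMPVs** (pairs whose miRNA *and*
mRNA are differentially expressed at q < 0.05); cross-feature overlap
counting; hypergeometric enrichment of target genes against the pair-list
background (P(X ≥ k), raw p < 10⁻³); and a one-tailed one-sample t-test of
target-gene degree against the mean degree of a protein-interaction
network.

A synthetic-data module generates paired expression with exact population
correlations per stratum, planted mean shifts, and a ground-truth label
per pair, so every stage is verifiable without any external download.

## Worked example

The `analysis/` scripts walk one simulated study end to end. After
`python analysis/01_simulate_demo.py` (12 pairs, 100 samples per ER
status: 6 sign-change, 2 fold-change, 4 null pairs),
`python analysis/02_detect_mmpvs.py` prints:

```
detected 8 MMPVs (6 sign-change, 2 fold-change)
   mirna_id mrna_id  r_status1  r_status2  mmpv_class pattern
hsa-miR-101  GENE01   0.723134  -0.564680 sign_change D_U*_D*
hsa-miR-102  GENE02   0.683495  -0.807300 sign_change D_U*_D*
hsa-miR-103  GENE03  -0.695365   0.749761 sign_change D_D*_U*
hsa-miR-104  GENE04   0.790884  -0.686082 sign_change U_U*_D*
hsa-miR-105  GENE05  -0.695258   0.674950 sign_change U_D*_U*
hsa-miR-106  GENE06   0.692561  -0.735095 sign_change D_U*_D*
hsa-miR-107  GENE07   0.848936   0.245559 fold_change D_U*_U*
hsa-miR-108  GENE08  -0.142886  -0.816063 fold_change  D_D_D*
agreement with planted truth: 12/12
```

Reading the first row: a pair negatively regulated in the healthy
population (`D`) is significantly *positively* correlated in ER+ tumours
(r₁ = 0.72, `U*`) and significantly negatively correlated in ER− tumours
(r₂ = −0.56, `D*`) — a sign-change MMPV. All 12 planted classes (including
the 4 nulls) are recovered. `03_differential_expression.py` then keeps the
4 pairs whose members also carry planted expression shifts:

```
4 DE-MMPVs (miRNA and mRNA both q < 0.05):
feature          mirna      mrna pattern
     ER hsa-miR-101(U) GENE01(D) D_U*_D*
     ER hsa-miR-102(D) GENE02(U) D_U*_D*
     ER hsa-miR-104(U) GENE04(U) U_U*_D*
     ER hsa-miR-107(U) GENE07(D) D_U*_U*
```

Scripts 04–07 cover multi-feature overlap, enrichment, network degree, and
a robustness analysis of the ratio rule under weakly co-expressed nulls.
The same stages are available as a CLI over a YAML config:

```sh
mmpv report --config configs/demo.yaml --stages simulate,detect,de,overlap
```

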