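# Methods

## Model and procedure

The unit of analysis is a validated miRNA–mRNA targeting pair carrying a
known regulatory sign in the healthy population (U = positive, D =
negative). Within each status stratum of a binary biopathological feature,
the pair's regulatory pattern is summarised by the Pearson correlation
coefficient (PCC) of the two log-scale expression profiles; the sign of
the PCC is read as the direction of regulation in that stratum. The
procedure per feature is:

1. **Stratified correlation.** Samples are split by the feature's two
   statuses. Per pair and stratum, the PCC is computed over
   pairwise-complete samples (a sample is dropped for a pair only where
   either member's value is missing — this maximises usable n and is the
   standard treatment in correlation matrices). Significance is the exact
   two-sided t-test under bivariate normality, t = r·√(n−2)/√(1−r²) with
   n−2 degrees of freedom; r = ±1 maps to p = 0. The test is not named in
   the field's informal usage of "significant PCC", so the package fixes
   this standard choice.
2. **FDR.** Benjamini–Hochberg step-up adjustment is applied per feature
   *per stratum* across all retained pairs: each stratum's correlations
   form one family of simultaneous tests.
3. **Removal.** A pair insignificant in both strata (q ≥ α in both) is
   removed regardless of its correlations — a large but doubly
   insignificant contrast is noise.
4. **Classification.** Opposite signs → *sign-change*; same (nonzero)
   sign with ratio r₁/r₂ ≥ fold or ≤ 1/fold → *fold-change* (fold = 2).
   The ratio compares the two condition PCCs directly; no
   healthy-population expression is involved, because no such expression
   data accompany the pair list — only a sign does. Exactly one zero
   correlation is treated as an infinite ratio (fold-change); two zeros
   are unclassifiable (none). r = 0 is a measure-zero event; the
   convention only exists so the classifier is total.
5. **Pattern encoding.** `H_S1_S2` with H the healthy sign, S1/S2 the
   stratum signs (`U`/`D`), `*` appended where q < α. The feature registry
   fixes which status is "status1" and hence occupies the middle token;
   swapping the registry order swaps the tokens and leaves the class
   unchanged.

### Differential expression (DE-MMPV selection)

Each entity receives the moderated statistic d = (mean₁ − mean₂)/(s + s₀),
where s is the unpaired pooled standard error of the mean difference and
s₀ the exchangeability constant, set to the median of the per-entity
pooled standard errors (falling back to the smallest positive value when
the median is zero). The null is n_perm = 200 uniform random permutations
of the status labels, with s₀ held at its observed value; the empirical
p-value uses the add-one correction p = (1 + #{|d_b| ≥ |d_obs|})/(n_perm+1),
so p ≥ 1/(n_perm+1) and is never zero. q is BH across all rows of a
matrix. This is a self-contained reading of "SAM-style" analysis: the full
SAM q-value machinery (π₀ estimation, quantile calibration) is deliberately
not reimplemented; BH on permutation p-values is the declared substitute.
A DE-MMPV is a detected pair with miRNA q < α **and** mRNA q < α.
Direction letters are U when mean(status1) > mean(status2), else D, with
status1 fixed by the registry — the convention is the package's own and is
stated wherever directions are printed.

### Overlap, enrichment, network

Overlap between two features counts shared (miRNA, mRNA) pair identities
(a gene-level mode is available). Two-feature shared-gene extraction
returns the mRNAs of pairs detected under both features; an optional
exclusivity filter additionally drops mRNAs whose miRNA partners appear in
any third feature's MMPVs — the inclusion-vs-exclusion reading of
"associated with other features" is genuinely ambiguous, so both are
exposed and neither is asserted as canonical.

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) of k
term genes among n targets drawn from an N-gene background containing K
term genes, computed through scipy's log-space survival function. The
background is the union of mRNAs in the supplied pair list — enrichment is
asked relative to what was detectable, not the genome. Raw p < 10⁻³ with
no correction is the reporting threshold (a BH column is emitted for
information only). The term map is taken flat; no ontology-hierarchy
propagation.

The network stage maps target genes onto an undirected
protein-interaction graph. Degree is the number of *distinct neighbours*
(a self-loop adds 1, not 2). Genes absent from the network are treated as
missing, not as degree-0: absence from a curated interaction database is
non-observation, not isolation. The test is a one-sample, one-tailed
t-test of the mapped genes' degrees against the network mean degree,
treated as a fixed population constant; a Welch two-sample variant against
all network degrees is available behind a separate function.

## Synthetic data

Each pair is generated from a bivariate normal on the log scale: both
members share standard deviation `noise_sd` (default 1, roughly one
log2-intensity unit), a baseline mean of 8, per-stratum population
correlations (rho_status1, rho_status2) built by Cholesky construction
(exact population control), and optional status1-minus-status2 mean shifts
for differential expression. The truth label per pair is produced by the
*same* decision rule as the classifier applied to the population
correlations with significance ignored, so generator and detector cannot
drift apart. Seeding derives one substream per (seed, pair index), so
extending a design never perturbs earlier pairs. A pleiotropy mode reuses
a miRNA's latent driver so one miRNA can target several mRNAs at each
pair's specified correlation.

What the generator does **not** emulate: probe-level effects, batch
structure, heteroscedastic array noise, non-Gaussian tails, or the
dependence among pairs sharing a stratum. Passing tests therefore show the
statistics behave as designed under the stated model — not that the
pipeline is robust to array artefacts.

## Standard evaluation conditions

The seeded experiments in `mmpv.experiments` fix the package's benchmark:

* **Detection recovery** — 100 sign-change pairs (rho +0.7/−0.7), 100
  fold-change pairs (0.6/0.2), 1,000 null pairs with equal per-stratum
  correlation, 60 samples per stratum, α = 0.05. Default nulls are
  uncoupled (rho = 0): the selectivity bound this benchmark carries is
  attainable only when unchanged pairs are essentially uncorrelated, and
  the ratio rule's behaviour under residual co-expression is measured
  separately (below) rather than folded into the headline number.
* **Permutation calibration** — 500 uncoupled entities, 30 per stratum,
  200 permutations: raw rejection at p < 0.05; power on 50 entities with
  2-sd shifts planted among 450 nulls at q < 0.05.
* **Null-coupling robustness** (`analysis/07`) — the recovery experiment
  repeated with null-pair common rho spread over [−s, s] for s up to 0.3.
  Contamination of the reported MMPV set grows steadily with s: the
  PCC-ratio rule is intrinsically unstable when its denominator is a
  small, noisy correlation, and this is a real limitation of the method on
  data where unchanged pairs retain weak co-expression.

## Numerical and interface choices

* Correlations are clamped to [−1, 1] against floating-point overshoot;
  constant vectors raise a degenerate-data signal and the pair is dropped
  with a counter, never silently.
* BH is implemented as the literal step-up recursion (stable sort,
  reverse cumulative minimum); statsmodels serves as an independent
  cross-check in the tests, not as the implementation.
* Minimum stratum size is 3 (the smallest n with a defined correlation
  p-value); pairs failing it are dropped and counted.
* Duplicate probe collapsing defaults to keeping the most variable row —
  the pipeline scores correlation, and the most variable probe preserves
  the most signal; element-wise mean is the alternative. Identifier
  matching is exact after a read-time normalisation that trims whitespace
  and unifies the "hsa-miR"/"has-mir" prefix spellings that appear in the
  wild.
* All thresholds (α = 0.05, fold = 2, n_perm = 200, enrichment p = 10⁻³)
  are config defaults, overridable per run; every random draw descends
  from the single run seed, and a run manifest records each output file
  with a content hash, so identical config + seed reproduces numeric
  outputs byte for byte.

## Known limitations

* The fold-change ratio is noisy when both correlations are weak (see the
  robustness analysis); interpret fold-change MMPVs with small |r| in
  both strata cautiously.
* BH on permutation p-values is granular (multiples of 1/(n_perm+1));
  with few truly changed entities the attainable q floor can sit near α.
* The bivariate-normal generator cannot certify behaviour under real
  array artefacts, and the flat term map ignores ontology structure.
* Five-feature studies are supported but each feature is tested
  marginally; no joint modelling of feature correlation is attempted.
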