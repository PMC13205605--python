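# Methods

## Scope and model

`ferrosig` implements two linked procedures for studying BET-inhibitor
resistance through the lens of ferroptosis regulation.

**Signature derivation and FR20.** Given a genes × cells UMI count matrix
with a two-level condition label (sensitive / resistant) and a catalog of
ferroptosis regulators (gene → driver or suppressor), the pipeline is:

1. *QC* — cells first, genes second. A cell is kept if it covers at least
   `min_genes_per_cell` genes (default 200) and at most `max_mito_fraction`
   (default 0.20) of its UMIs come from genes whose symbol starts with
   `mito_prefix` (default `MT-`). A gene is then kept if it has a nonzero
   count in at least `min_cells_per_gene` (default 3) of the *surviving*
   cells. The cell-then-gene order is fixed; reversing it changes which
   genes see the detection threshold.
2. *Normalization* — library-size scaling to `scale_factor` (default 1e4)
   counts per cell followed by `ln(1 + x)`.
3. *Differential expression* — per gene detected (> 0) in ≥ `min_pct`
   (default 0.1) of either group: a two-sided Wilcoxon rank-sum test on the
   log-normalized values, with exact enumeration when both groups have ≤ 25
   observations and no ties, and the tie-corrected normal approximation
   otherwise (the switch keeps small bulk designs exact while staying fast
   and platform-stable at single-cell scale). Fold change uses the
   pseudocount convention `log2((mean_a + 1) / (mean_b + 1))` on de-logged
   normalized means, so lowly expressed genes are shrunk toward zero.
   Benjamini–Hochberg FDR is computed across tested genes; a gene is *up*
   when `log2FC > 0.25` and `FDR < 0.01`, *down* symmetrically.
4. *Catalog intersection* — the signature's arms are {up ∧ suppressor} and
   {down ∧ driver}, each ordered by ascending FDR. A one-sided Fisher exact
   test reports whether each direction is enriched for each role; its
   universe is the set of DE-tested genes (the natural background for a
   detection-filtered single-cell experiment; other choices — whole genome,
   all catalog genes — give different p-values, which is why specific
   enrichment p-values are not treated as portable across studies).

FR20 for an observation is the signed sum of its normalized expression over
the signature genes (+1 suppressors, −1 drivers). "Normalized" is resolved
by modality: log-normalized values for single-cell input, per-gene z-scores
across the cohort for bulk input (sample sd, ddof = 1; zero-variance genes
become zero rows). Both are exposed; the choice is stamped into the output.
Signature genes absent from a matrix are dropped with a warning by default
(bulk platforms lack genes); strict mode errors instead.

Validation helpers mirror the score's intended use: two-group Wilcoxon or
t comparisons, one-way ANOVA for more groups, and top-vs-bottom-quartile
stratification of external samples (type-7 linear-interpolation
percentiles; the high group is score ≥ Q3, the low group score ≤ Q1,
responses compared by two-sided Wilcoxon).

**D-FR20 connectivity screen.** Each library instance is a per-gene ranking
statistic vector. Genes are sorted by statistic descending, ties broken by
gene symbol ascending so rankings are identical across platforms. The
weighted KS running sum adds `|stat|^p / Σ_set |stat|^p` at member positions
(weight exponent `p` default 1; `p = 0` gives the unweighted KS variant) and
subtracts `1/(N − m)` elsewhere; the enrichment score is the walk's signed
maximum absolute deviation, clamped to [−1, 1] against floating-point
spill. If every member statistic is zero the member weights fall back to
uniform `1/m`.

The null model permutes gene sets: `n_perm` (default 1000) random same-size
sets drawn without replacement from the profile's genes, scored with the
same walk. NES divides the ES by the mean |null ES| of the same sign; the
p-value is the add-one estimator over same-sign permutations,
`p = (1 + #{same-sign |ES_null| ≥ |ES|}) / (1 + #{same-sign})`. Two
consequences worth knowing: `p ≥ 1/(n_perm + 1)` always, and because the
gene-set null splits signs roughly evenly, the smallest *attainable* p is
`1/(1 + #same-sign) ≈ 2/n_perm`. When no same-sign permutation exists the
ES is normalized by the all-null mean and p is set to `1/(n_perm + 1)`,
flagged as degenerate. Phenotype permutation is not offered — rank-only
profiles carry no replicate structure to permute.

BH FDR is computed separately per signature arm across all instances and
combined by the AND rule (an instance is retained only if both arms pass
`fdr_threshold`, default 0.05); the scope is recorded in the result
metadata. WTCS is `(NES_up − NES_down)/2` when the signs differ and 0
otherwise; retained instances are ranked by ascending WTCS with instance-id
tie-breaks, and the `top_k` (default 10) lowest form the candidate list.
Instances are ranked individually; collapsing multiple instances of one
compound is left to the user, since the right aggregation (best, median,
cell-line-matched) is application-dependent.

## Synthetic data

The generators emulate the statistical structure the method assumes, not
any particular dataset.

*scRNA-seq* (`simulate_sc`): counts are negative-binomial with mean
`libsize_c · baseline_g · 2^(lfc_g · [resistant])` and gamma-Poisson
dispersion 0.3 (variance `μ + 0.3 μ²`, typical of UMI data); baselines are
log-normal (meanlog 0.5, sdlog 1.0) and per-cell library-size factors
log-normal (sdlog 0.3). The 8 packaged suppressors carry lfc +1 and the 12
drivers lfc −1; 50 decoy catalog genes carry lfc 0; 100 non-catalog
background genes carry ±1; the rest are null. Baselines for the 20 planted
regulator genes are redrawn until they exceed the baseline median: the
regulators this design emulates are reliably detected, DE-testable genes,
whereas an unconstrained draw occasionally places a planted gene so low
that its pseudocount-shrunk fold change cannot clear 0.25 regardless of the
true effect. Defaults are 2000 genes and 500 cells per condition.

*Bulk* (`simulate_bulk`): Gaussian log-expression (gene baselines
N(5, 2²), residual sd 0.5) with ±`shift` (default 1.0) on the signature
genes in the resistant condition, 3 replicates per condition by default —
the scale of typical induced-resistance cell-line cohorts.

*Perturbation library* (`simulate_perturbations`): instance statistics are
iid N(0, 1); reversers add −3 to the suppressor genes and +3 to the driver
genes, aggravators the opposite; defaults are 200 nulls, 5 reversers, 5
aggravators over 1000 genes, with classes assigned to shuffled positions.
Library metadata exposes only neutral names; the truth lives in a separate
ground-truth table so screens cannot leak it.

What passing tests on these data do **not** show: robustness to doublets,
ambient RNA, batch effects, varying capture efficiency, compositional
shifts between conditions, or correlated gene modules — none are simulated.
Real LINCS profiles also have heavy-tailed, gene-correlated statistics
rather than iid Gaussian noise, so real-screen FDRs will be less well
calibrated than the synthetic ones.

## Numerical and design choices

- Gene symbols are upper-cased at load; matching is case-insensitive; no
  alias resolution. Catalog genes annotated as both driver and suppressor
  are excluded (the ±1 weighting is undefined for them) and logged; roles
  other than driver/suppressor are rejected by the loader.
- TSV floats are written with 17 significant digits and parsed with
  round-trip precision, so write-then-read is bit-exact.
- Fisher odds ratios use the sample cross-product with a 0.5 continuity
  correction only when a cell is zero (flagged).
- All randomness flows from explicit integer seeds (package default 20, a
  mnemonic for the signature size); identical seeds give bit-identical
  matrices, permutation p-values and rankings. Determinism in the screen
  additionally relies on the fixed tie-breaks (statistic ties by symbol,
  WTCS ties by instance id).
- Degenerate inputs error early with stage-specific counts: zero surviving
  cells/genes in QC, zero-total cells in normalization, single observations
  in z-scoring, empty catalog∩universe in the Fisher test, gene sets that
  miss or cover the whole profile in enrichment, coincident quartile
  boundaries in stratification.
- Unit tests run the generators at reduced sizes (hundreds of genes, tens
  to hundreds of cells, 100–500 permutations) chosen to keep each property
  adequately powered; the end-to-end checks in `tests/test_acceptance.py`
  use the full default problem sizes (2000 × 1000 counts; 210-instance
  screen at 1000 permutations).

## Limitations

- The 20-gene signature is a fixed, transcriptome-level proxy for
  ferroptosis inhibition; it does not model post-transcriptional control
  of ferroptosis (e.g. lipid composition, iron handling).
- FR20 sums are unnormalized by signature size, so scores computed with
  different numbers of matched genes are not directly comparable; the
  dropped-gene list in the output is there to check this.
- The DE stage is a per-gene two-group test; pseudobulk/mixed-model DE,
  batch correction and imputation are out of scope.
- The screen treats instances independently and the gene-set permutation
  null assumes exchangeable genes; correlated gene modules inflate the
  effective significance of sets that align with a module.
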