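# Methods

This note records the statistical models, default parameters, and numerical
conventions implemented in `snmux`, in pipeline order. Symbols: a pool has
`K` donors, `C` nuclei (barcodes), `S` genotyped sites, `G` genes.

## Synthetic data generator

The generator (`snmux.simulate`) produces a complete pooled experiment with
ground truth; it is the substrate for all property tests and the end-to-end
pipeline. Scope: it models the signals the callers rely on — it is not a
general-purpose sequencing simulator (no ambient RNA in expression, no batch
effects, no empty droplets).

- **Donor genotypes.** Per site, a minor-allele frequency is drawn uniformly
  from `maf_range = (0.05, 0.5)`; each donor's genotype is
  Binomial(2, MAF) ∈ {0, 1, 2}.
- **Pool structure.** `nuclei_per_donor = 500` per donor (default
  `n_donors = 8`); a fraction `doublet_rate = 0.05` of barcodes contain a
  second donor; a fraction `untagged_rate = 0.2` of nuclei carry no hashtag
  signal (the failure mode that motivates genotype rescue).
- **Hashtag counts.** Every tag contributes Poisson ambient counts (mean
  `hto_ambient_mean = 2`); a tagged nucleus additionally receives Poisson
  signal (mean `hto_signal_mean = 200`) on its own tag(s). Defaults give an
  extreme signal-to-noise regime by design.
- **Allele counts.** Each nucleus's total read count is Poisson
  (`reads_per_cell_mean = 50`) spread multinomially over sites; at a covered
  site, ALT reads are Binomial(depth, p) with p ∈ {ε, ½, 1−ε} by the true
  genotype (doublets: the mean of the two donors' p), ε =
  `base_error_rate = 0.01`.
- **Expression.** Gene rates are per-gene LogNormal baselines times a
  cell-type multiplier; each nucleus draws a cell type from its sample's
  composition (compositions differ between tumor groups, deliberately
  confounding naive DE), a LogNormal(0, 0.3) size effect, and Poisson
  counts.

## Quality control

Per-nucleus detected-feature count and (opt-in, by feature-id prefix)
mitochondrial fraction. Default filter keeps nuclei with
`200 < features < 10,000` and mito fraction `< 0.05` (strict inequalities).

## Hashtag classification

On raw tag counts `x`, the CLR transform is `ln(x+1)` minus its per-tag mean
over cells. Cells are clustered by k-means with `k = n_tags + 1` on CLR
profiles. Initialization is deterministic and cell-order invariant: one
center per tag from that tag's strongly positive cells (CLR argmax equals
the tag, top quartile within them) plus one negative center from low-maximum
cells; centroids are afterwards relabeled in lexicographic order so cluster
identities cannot depend on row order. Per tag, the background population is
the cluster with the lowest mean CLR for that tag; a negative binomial is
fitted to the tag's *raw* background counts by moments
(`r = m²/(v−m)`, Poisson fallback when `v ≤ m`), and a cell is positive for
the tag when its raw count exceeds the fitted distribution's 0.99 quantile.
Cells with one positive tag are singlets, two or more are doublets, none are
negatives.

## Genotype-based donor assignment

For each singlet hypothesis (donor `d`) the expected ALT fraction at a site
is `p ∈ {ε, ½, 1−ε}` by the donor's genotype; a doublet hypothesis `(a, b)`
uses the mean of the two donors' values. The per-cell log-likelihood sums
Binomial(depth, p) log-pmfs over covered sites (zero-depth sites contribute
nothing). Priors: singlets share `1 − doublet_prior`, pairs share
`doublet_prior = 0.05`. A cell is a singlet (doublet) when the top posterior
hypothesis is a donor (pair) with posterior mass ≥ 0.9, otherwise
unassigned; cells with zero informative sites are always unassigned.

## Consensus integration and yield

Per barcode, with `H` the hashtag call and `G` the genotype call:

| H | G | outcome |
| --- | --- | --- |
| singlet | singlet, same sample | concordant, assigned |
| singlet | singlet, other sample / doublet | discordant, discarded |
| singlet | unassigned | discarded (strict) or kept (lenient) |
| doublet or negative | confident singlet | *rescued*, assigned to the genotype donor |
| doublet or negative | otherwise | unassigned / discarded |

Yield accounting compares the integrated assignment count against the two
single-method baselines: `gain = 100 · (n_integrated − n_baseline) /
n_baseline`, reported to one decimal; a zero baseline reports a null gain.

## Composition and module scores

Composition tables are per-sample cell-type proportions (rows sum to 1).
Module scores use log-normalized expression `ln(1 + 10⁴ · x / total)`:
genes are ranked by mean log-normalized expression into `n_bins = 24`
equal-size bins; each set gene draws `n_ctrl = 100` control genes without
replacement from its bin excluding the set (the full complement when the
bin is smaller); the per-cell score is mean over set genes minus mean over
the pooled controls. Per-sample summaries use the median (midpoint
convention for even counts).

## Differential expression

- **Variable genes.** log10 variance is regressed on log10 mean with a
  tricube-weighted degree-2 local polynomial (span 0.3, windowed normal
  equations); counts are z-scored by the predicted standard deviation,
  clipped at √n, and genes are ranked by the variance of the clipped
  z-scores (ties broken by gene id for determinism).
- **Model.** Per gene, a Poisson log-link GLM of counts on an intercept and
  a tumor-type indicator, with centered log total counts as offset; the
  *adjusted* model adds cell-type indicator columns. Quasi-Poisson
  dispersion `φ = Pearson χ² / (n − p)` is floored at 1; standard errors are
  `√φ` times the Poisson errors; two-sided p-values use the normal reference
  on the Wald statistic (t reference optional). Non-convergence and
  separation (|β| > 20) are flagged with null p-values rather than dropped
  silently.
- **Multiplicity.** Benjamini–Hochberg within each (tumor type, model)
  stratum; significance at q < 0.05.
- **Model comparison.** Per tumor type, the counts of genes significant
  only adjusted / only unadjusted / in both, plus the genes whose estimate
  flips sign between models.

## Direction concordance

For `T` tumor types each contrasted with the same referent, a gene
significant in all `T` contrasts is concordant when every effect sign
agrees. Under a null where each contrast's sign is an independent fair
coin, the expected concordant fraction is `2 / 2^T` (the two all-same
vectors among the `2^T` equiprobable sign vectors). The observed fraction
is compared with a one-sample χ² proportion test (no continuity
correction); an exact binomial test is available.

## Numerical conventions

- Per-stage seeds derive from the master seed as
  `(seed + crc32(stage_name)) mod 2³¹`, recorded in the run manifest
  together with SHA-256 digests of every output.
- Reported percentages round half-up (so the `2/2⁶` null is 3.13%, not the
  banker's-rounding 3.12%).
- k-means uses the deterministic initialization above specifically so that
  classification is invariant to cell order; stock k-means++ seeding is not.

## Limitations

- The hashtag background threshold is estimated from the data, so calls are
  weakly coupled across cells: perturbing one cell can move thresholds
  enough to change a small number of borderline calls.
- With ambient mean 2 and a 0.99-quantile threshold, a small fraction of
  ambient-only counts exceed the threshold per tag; the scheme therefore
  trades a little singlet recall for high assignment precision.
- The centered log-total offset assumes library size is effect-free: when
  strongly differential genes shift total counts between groups, null genes
  acquire a small compensating bias (visible in total-unbalanced synthetic
  designs; the bundled generator's expression scales are chosen so this is
  minor).
- Expression counts are conditionally Poisson; the quasi-Poisson dispersion
  floor at 1 means under-dispersion is never modeled.
- The generator draws doublets as donor pairs within the pool only, with no
  intra-sample doublets' distinct expression signature, and models no
  ambient RNA contamination in expression.
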