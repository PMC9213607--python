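# Methods

`te-storm` analyzes transposable-element (TE) expression at the resolution
of individual genomic insertions rather than family consensus sequences.
The pipeline models a longitudinal blood-transcriptome study design: the
same subjects sampled while still cognitively normal ("Converter_pre") and
again after phenoconversion to amnestic MCI / late-onset Alzheimer's
disease ("Converter_post"), alongside an independent group of
never-converting controls ("NC").  Every stage operates on synthetic data
with planted ground truth, generated by the package itself.

## Transcript-to-locus assignment

Assembled transcripts aligned against a TE insertion reference (BLAST
tabular records with an extra `qlen` column) are reduced to unambiguous
transcript→locus assignments in two steps:

1. **Identity/coverage filter.** A record survives iff
   `pident >= 95%` and `aln_len / qlen >= 0.90`.  Both thresholds are
   inclusive ("at least"), and the coverage denominator is the transcript
   length, not the reference TE length.
2. **Strict multi-map removal.** A transcript whose surviving records hit
   two or more distinct loci is discarded (`multimap`).  Multiple records
   against the *same* locus (split alignments) count as one locus.
   No best-hit rescue is applied by default; discarding is the
   conservative reading of "unique primary genomic location".

Discard reasons are logged per transcript (identity checked before
coverage).  Locus counts are the sum of assigned transcripts' counts.
A small semi-global dynamic-programming aligner (free end gaps on the
target) is included so toy fixtures can be recomputed from FASTA alone; it
is a test-scale tool, not a replacement for a seeded aligner.

## Abundance scaling and normalization

Two per-sample scalings exist because the field's "TPM" is ambiguous when
counts are already transcript-level:

- `tpm_as_stated` — counts / sample total x 1e6.  This is formally a CPM
  (no length term) and is the pipeline default.
- `tpm_length_normalized` — the conventional length-normalized TPM,
  behind a flag.

The expression filter retains loci with CPM >= 1 in >= 2 samples,
computed on raw library sizes.  Cross-sample normalization is TMM: per
sample against a reference (the sample whose upper-quartile CPM is closest
to the mean of those quartiles), per-gene log ratios `M`, abundances `A`,
and delta-method variances `w` are computed over loci positive in both
samples; after two-sided trimming (30% by M, 5% by A — the established
defaults; the method's description names no fractions) the factor is the
1/w-weighted mean of the surviving M, and factors are rescaled to
geometric mean one.

Numerical notes: pairs with a zero count on either side are dropped from
that pair's M/A computation (the log is undefined); if nothing survives
trimming the factor falls back to 1 with a warning.  Because the weights
depend on absolute counts, TMM factors are *exactly* invariant to a global
rescale of the matrix and to a pure depth difference (one column a
multiple of another), but only approximately (order 1e-2) invariant to
rescaling a single sample's depth — the same behavior as the reference
R implementation of the method.

## Differential expression

Counts are modeled per locus as negative binomial with a log link and
offsets `log(N_k f_k)` (library size x TMM factor).  The paired contrast
(pre vs post) uses a subject blocking factor plus a condition indicator,
no interaction; unpaired contrasts use a two-group model.  The condition
indicator marks the contrast's *second* condition, so the reported log2FC
is second-over-first (for `pre_vs_post`, post over pre; a locus elevated
in the presymptomatic state has negative logFC).  Optional covariates
(sex, age) can be added to the design; the default is none.

**Fitting.** All loci share the design matrix, so IRLS is vectorized
across loci (batched weighted least squares with a 1e-10 ridge), iterating
until the per-locus score norm is below 1e-8 or 100 sweeps.  All-zero loci
are flagged degenerate with zero coefficients.

**Dispersion.** The common dispersion maximizes the Cox-Reid adjusted
profile likelihood (log-likelihood minus half the log-determinant of the
weighted information) on a 61-point log-grid spanning 1e-4 to 4, with
means fitted under the full design; two rounds are used (Poisson means,
then means refit at the first-round optimum).  Tagwise values maximize the
per-locus adjusted likelihood plus `prior_df` (default 10) times the
locus-averaged curve, so they shrink toward the common value and collapse
onto it as `prior_df` grows.  The Cox-Reid term matters here: with a
subject-blocked design the full model spends half the degrees of freedom,
and the unadjusted profile likelihood underestimates dispersion enough to
inflate the type-I error visibly.

**Testing.** Likelihood ratios of full vs reduced fits are referred to
chi-square with the coefficient-count difference as df; BH FDR is computed
across retained loci.  Selection uses the nominal p (p < 0.01) together
with |log2FC| >= 1.5, two-sided by default — the up/down sets are reported
under the same thresholds, with a one-sided flag available.  Calibration
is verified in the test suite: on a 2000-locus null with dispersion 0.2
and 20 paired subjects the fraction of p < 0.05 lands in [0.03, 0.07] and
the p distribution is KS-compatible with uniform.

**QC.** A PCA of logCPM over any locus set reports component scores and a
silhouette group-separation score without making decisions; regressing the
leading components on age within the control group checks the
age-independence of a DE signature (the generator plants none).

## Enrichment and annotation

TE class (or family) enrichment of a DE set uses the two-sided Fisher
exact test with the point-probability ordering rule — the two-sided p sums
the probabilities of all fixed-margin tables no more likely than the
observed one (stated explicitly because two-sided Fisher definitions
differ between ecosystems; this is also scipy's rule).  The background is
all loci surviving the expression filter in that contrast, and the
comparison group is background minus the DE set.  Classes are flagged at
raw p <= 0.01 with no correction across classes; BH values are written
alongside for transparency.

The DE-set intersection test is the one-sided hypergeometric tail on the
observed overlap within the universe of loci tested in both contrasts,
with an up/down cross-tabulation of the shared loci.  Fold-change
concordance between contrasts is summarized by Pearson and Spearman
correlation over shared loci.

Cis gene assignment maps a locus to every gene whose interval intersects
the locus expanded by ±5000 bp (half-open).  This is gene-body
intersection, not a TSS-based regulatory-domain rule; the reported
relation (upstream/downstream/overlap) is oriented by the locus strand.

## Chromatin states

Loci are annotated against per-tissue segmentations over the 15 Roadmap
core states (TssA, TssAFlnk, TxFlnk, Tx, TxWk, EnhG, Enh, ZNF/Rpts, Het,
TssBiv, BivFlnk, EnhBiv, ReprPC, ReprPCWk, Quies; mnemonic and
numeric-prefix spellings both accepted).  Adjacent same-state runs are
merged before labeling, so the assignment is invariant to how a
segmentation splits a constant-state region.  A locus overlapping exactly
one state inherits it; two or more states give the sentinel `Mx` (mixed);
no coverage gives `NA`.  A `min_minor_fraction` option (default 0) can
ignore trace overlaps below a fraction of the locus's covered bp before
the single-vs-Mx decision.

The "active" state set is configurable and defaults to the
transcription/enhancer/promoter block (states 1-8); every report echoes
the set used.  Active fractions are reported in two readings — by label,
and by any-overlap — because the overlap rule behind published active
fractions of this kind is usually unstated.  Per-state enrichment of a DE
set reuses the Fisher machinery with Mx as its own category.  Cross-tissue
consistency reports per-locus label agreement, a tissue-by-tissue
agreement-distance matrix, and its average-linkage clustering.

## Classifier

Feature screening ranks loci by the Shannon entropy of their expression:
values are transformed to log2(x+1) and histogrammed into 10 equal-width
bins over the observed range; H = -sum p log2 p over occupied bins.  The
top 10,000 loci by entropy are retained (everything, at desk scale).  The
binning is a documented choice — the transform is monotone but not
affine, so entropy is exactly invariant to sample relabeling and to
scaling (x+1) by a constant, but not to adding an arbitrary constant to
raw values.

Boruta then compares each feature's random-forest importance against the
best of the shuffled shadow copies: per iteration every still-active
feature gets a freshly shuffled shadow, a forest is fit on real + shadow
columns, and a feature scores a hit when it beats the shadow maximum.
Hits are tested two-sided binomial (success 0.5) with Bonferroni over the
currently undecided features; confirmation/rejection removes the feature
from testing, and survivors at `max_runs` stay tentative.  Importance is
mean impurity decrease by default (the convention of the widely used
Python port, and an order of magnitude faster); the canonical Z-scored
out-of-bag permutation importance (mean/sd of the per-tree accuracy drop)
is available via `importance="oob_permutation"`.

A caveat worth stating: Boruta is an *all-relevant, in-sample* selector.
With few samples and many features, a pure-noise feature whose in-sample
correlation with the labels is large by chance (at 60 samples and 55
features the largest such |r| is typically 0.35-0.45) is genuinely
relevant to those labels in that sample, and Boruta will confirm it even
when the labels are a random permutation.  Label-permutation emptiness is
therefore not a property this selector can guarantee at small n, under
any of its importance variants; the test suite documents the observed
behavior rather than assuming it away.

Model evaluation uses a random forest on the selected features with a
70/30 split performed at the *subject* level (a converter's pre and post
samples never straddle the boundary; with no paired subjects this reduces
to a stratified sample split), optional down-sampling of the training
majority class, a 5-fold cross-validation accuracy on the training set as
a sanity check, and ROC/AUC on the held-out test set.  AUC is the midrank
(Mann-Whitney) statistic on predicted class probabilities, so it is
invariant to any strictly monotone transform of the scores and handles
ties by midranks.  "Five times cross-validation" is read as 5-fold.

## Synthetic data

The generator is the package's study-conditions definition, not a tuning
dial.  Defaults mirror the emulated cohort: 25 paired converter subjects,
64 independent controls, converter ages ~N(81.2, 4.1) and control ages
~N(81.6, 3.9) (truncated to [75, 95]), ~56%/67% female, and a TE class
mix of 35% LINE / 30% SINE / 20% LTR / 5% SVA / 10% DNA.

- **Counts.** NB with dispersion 0.1 around
  `mu = N_k * softmax-like weights`: per-locus log2-normal baseline
  (sd 1.8), a per-locus per-subject random intercept (sd 0.7 log2) shared
  by a subject's two samples (what makes the paired design strictly more
  powerful), and planted group offsets.  Planted effects are added on top
  of the *baseline* composition, so planted log2FCs are exact on the
  count scale and the realized library size drifts slightly with planted
  content — the composition bias TMM exists to absorb.  Library sizes are
  drawn uniformly from 0.8-1.2 million; locus-level counts at desk scale,
  standing in for the tens of millions of reads of a real library.
- **Planted DE.** `de_fraction` (default 5%) of loci per contrast, with a
  `frac_shared` portion (default 40%) forming a pre-specific signature
  shifted in the Converter_pre condition only — differential in both
  contrasts with concordant direction.  Signs follow `frac_up = 0.86`
  (probability the locus is elevated in the presymptomatic state), and
  selection is biased toward LINE/LTR (and away from SINE) so the class
  enrichment stage has a planted positive.  Age is generated independent
  of expression: a null covariate for the QC stage.
- **Transcripts.** One per locus, built by substituting/truncating the
  reference sequence so the recorded identity and coverage are exact by
  construction; `frac_lowid`, `frac_lowcov`, and `frac_multimap` (with a
  second passing alignment) plant the filter classes in exact counts.
  Planted DE loci are kept out of the discard classes so the downstream
  stages can observe them.
- **Chromatin tracks.** Per-tissue segmentations tile each toy chromosome
  exactly; segment boundaries are aligned to locus edges so each
  non-straddle locus sits in one segment whose state is drawn from the
  configured proportions (default Quies-heavy, ~33% active), giving exact
  control over planted state composition; straddle loci get an internal
  boundary with two distinct states.
- **Determinism.** Every generator derives its RNG stream from the master
  seed by a fixed label, so outputs are byte-identical across runs and
  stable when one generator's call count changes.

What the generator does **not** emulate: read-level sequencing error,
assembly artifacts, GC/length biases, batch effects, correlated TE
families, or any real age/sex association with expression.  Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the stated model, not performance on real cohort data.

## Problem sizes

The demo configuration (and the reproduction script) uses 300 loci, 12
paired converters, 20 controls, 500-tree forests, and at most 50 Boruta
iterations — sizes chosen so a complete run takes about a minute on one
CPU while every stage still has planted structure to recover (a shared
signature of 20 loci, ~30 DE loci per contrast).  Test-suite simulations
use 100-2000 loci depending on what the property needs.

## Known limitations

- The NB/log-normal count model is an assumption; the emulated study
  reports no locus-level distributional description.
- Strict multi-map discard may be more conservative than the original
  "primary location" rule, which is not operationally defined; a
  bitscore-margin best-hit rescue exists behind a flag, default off.
- Chi-square reference for the LRT is asymptotic; calibration is verified
  at the tested sample sizes, not guaranteed for very small n.
- GREAT-style regulatory domains, surrogate-variable correction,
  pseudotime trajectories, and coordinate liftover are out of scope;
  inputs must share one coordinate system.
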