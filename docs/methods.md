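# Methods

## Model and assumptions

`reosig` implements a qualitative, rank-based classifier of TMPRSS2-ERG
(T2E) fusion status. Its single biological assumption is that the fusion
elevates ERG transcription enough to change ERG's *within-sample* order
relative to suitably chosen reference genes. All decisions are therefore
binary order relations between two raw measurements inside one sample;
the method never compares values across samples, which is what makes it
invariant under any per-sample strictly increasing transform (platform
changes, library-size scaling, quantile normalisation, monotone
batch distortions). That invariance is exact, not approximate, and is
asserted end-to-end by property tests.

TFP (fusion-positive) is the positive class everywhere.

## Reference-gene screening

Candidate ERG partners are genes with extreme expression variability in
the training cohort, scored by five metrics:

| metric | definition | notes |
| --- | --- | --- |
| F-statistic | one-way ANOVA between TFP and TFN | zero within-group variance → 0 if the group means agree, else a finite sentinel (1e12) so the ranking stays total |
| Shannon entropy | histogram entropy, equal-width bins over [min, max], log2 | 10 bins by default (configurable); constant vectors score 0 |
| CV | σ/μ with population (n-denominator) SD | μ = 0 → 0 |
| outlier sum | Σ\|x − median\| over points outside Q1 − c·IQR or Q3 + c·IQR | c = 1 as defined for this method (not the conventional 1.5); c is configurable; quartiles are linear-interpolation (type-7) |
| MAD | median(\|x − median\|), no consistency constant | |

Smaller means more stable. The five metrics are fused by rank
aggregation — each metric becomes an ascending rank, the fused score is
the mean of the five ranks (a mean-of-ranks realisation of
stingscore-style aggregation; the interface takes any fused ranking if a
different weighting is wanted). Exactly ⌊q·n⌋ genes from each tail
(q = 0.25) are labelled stable / unstable; both tails together are the
reference set. The anchor gene is excluded first, and ties across a
quartile boundary break lexicographically by gene id so the cut is
deterministic across platforms and runs.

Note the F-statistic measures *between-group* difference while the other
four measure overall dispersion; it is included as defined. On null
genes its rank is essentially uniform noise in the fused score.

## Pair statistics

Within-sample ranks are ascending (1 = lowest), ties averaged, computed
over all genes of the matrix by default (`rank_universe="references"`
restricts the universe for sensitivity analysis).

The reverse degree of a pair is

    R̄ = sqrt( |Σ_i (R_ERG[N_i] − R_Ref[N_i])| / m × |Σ_j (R_ERG[P_j] − R_Ref[P_j])| / n )

with N/P the TFN/TFP samples. Two consequences of this exact form are
implemented as defined and documented rather than "fixed": per-sample
differences of opposite sign cancel *within* a group, and a pair whose
rank gap is large but equally directed in both groups scores high even
though it never reverses. A `signed=True` variant multiplies in the sign
condition (opposite group sums required) and is off by default; on
simulated data the planted reversal pairs top the signed ranking, while
the as-printed ranking is dominated by distant same-direction pairs.

Pair discrimination is F-1 = 2·Sen·Spe/(Sen + Spe), the harmonic mean of
sensitivity and specificity (not precision/recall F1). Each pair is
scored in both orientations (ERG above / below the reference voting TFP)
and keeps the better; an orientation tie keeps the elevated-ERG
orientation. Exact expression ties vote TFN: equality is no evidence of
ERG elevation, so the conservative call is the negative class.

The candidate pool is (top-10 by R̄) ∪ (top-10 by F-1) ∪ (top-20% by R̄ ∩
top-20% by F-1), the top-fraction count rounding up. All orderings use
one deterministic tie-break chain: F-1 desc, R̄ desc, partner id (the R̄
ordering swaps the first two keys).

## Signature selection and classification

A signature is an anchor plus directed pairs under the majority rule: a
sample is called TFP iff at least half of its pairs vote TFP — read
literally, so a tie on an even-sized signature votes TFP. Selection is
seeded greedy forward search: the 10 candidates with the highest
individual F-1 each seed a run; a run repeatedly adds the candidate that
maximises ensemble F-1 on the training cohort and stops when no addition
improves it strictly (improvements must exceed 1e-12 to discount float
noise; no backward steps; a safety cap of 20 pairs). The winner is the
run with the highest F-1, ties resolved toward fewer pairs, then seed
order. The recorded selection trace is asserted non-decreasing.

Classification produces, per sample, the per-pair votes, the vote count,
the vote fraction (votes/k — the only graded score the classifier has,
hence the ROC score), and the label. Evaluation reports the confusion
counts, Sen/Spe/accuracy/F-1 and the trapezoidal AUC of the vote
fraction (sklearn's ROC implementation, verified exactly against an
all-pairs concordance oracle). AUC confidence intervals, when wanted,
come from a percentile bootstrap (2000 resamples by default, resamples
missing a class redrawn); this is a documented convention, as no
reference method is stated for the published intervals.

## Single-cell pseudobulk voting

For a sample with N flagged tumor cells, pseudobulk n (n = 1..N) is the
per-gene mean of a uniform random subset of n cells drawn without
replacement. Each pseudobulk is classified by the signature; the sample
call comes from an exact two-sided binomial test of the TFP count
against p = 0.5 at α = 0.05, with an explicit *indeterminate* outcome
when the test is not significant (the published procedure states only
"significantly more"; two-sided at 0.05 with an explicit third outcome
is this package's convention). Consequences worth knowing: N ≤ 5 can
never reach significance (min p = 2·0.5⁵ ≈ 0.0625), and N = 6 requires
unanimity. Pseudobulks are means of raw counts by default ("mean
expression level" read literally); a CPM flag normalises per cell first.
Pseudobulk means are *not* invariant to per-cell monotone transforms —
only to per-cell scaling that is uniform across genes — so the
platform-invariance guarantee applies downstream of pseudobulk
construction, not to arbitrary per-cell distortions. Tumor-cell
identification is upstream and out of scope; the module consumes a
per-cell flag.

## The simulator

`reosig.simulate` generates the study conditions used throughout the
tests: a two-group log-normal cohort (defaults: 1000 genes, 100 TFN + 50
TFP samples, 5 planted partners, noise_sd 0.5, anchor shift 1.5 log
units = 3 noise SDs) with a planted REO-reversal structure.

Design of the planted structure, chosen once by power analysis:

* The anchor has tight within-group dispersion (noise_sd/5) and gains
  `erg_shift` in TFP samples.
* Planted partners sit near the anchor's midpoint, offset by fixed
  fractions (0, ±0.15, ±0.22) of the shift, with dispersion 0.8·noise_sd.
  At the default shift each pair is individually imperfect (per-pair vote
  error rates roughly 3–15%, mostly partner-specific, on both sides of
  the margin). This mirrors real cohorts, where no single pair is a
  perfect fusion reporter, and it is what gives the majority vote — and
  hence the greedy search — something to gain; error rates fall off
  rapidly as the shift grows.
* Background genes form a stable tier (noise_sd/5) and an unstable tier
  (3·noise_sd); their baselines are rejection-sampled outside the
  anchor's dynamic range (±1.5 noise SDs beyond the anchor's two group
  means) so no background pair reproduces the planted reversal. The
  default stable fraction (0.15) keeps the stable tier smaller than the
  bottom stability quartile, so the partners — the next most stable tier,
  sitting between the two background tiers — reliably qualify as
  reference genes despite the mean-level confounding of the raw-scale
  MAD and outlier-sum metrics.

What the simulator does *not* emulate: realistic microarray error
models, correlated gene modules, batch effects beyond monotone
distortion, mixed tumor purity, or background genes inside the anchor's
dynamic range. Passing the recovery tests therefore shows the pipeline
identifies planted rank reversals under calibrated noise — not that it
attains any particular accuracy on real cohorts.

`distort_monotone` applies an independent random increasing
piecewise-linear map to every sample column (8 knots, random positive
slopes, random affine envelope); it changes every value and preserves
every within-sample rank, which is the lever used to test the
cross-platform claim at the level where it is exactly true.

## Numerical and interface conventions

* Expression matrices are genes × samples DataFrames at the library
  level; the sklearn estimators take the transpose (samples × genes) and
  require named columns, since gene identity is part of the model.
* Readers reject NaN/Inf and duplicate identifiers with the offending
  coordinates named. Probe collapse averages the probes of a gene per
  sample, drops probes mapping zero or several genes, and excludes a
  missing probe measurement from its sample's average rather than
  discarding the probe (DASL-style panels have sporadic missing values;
  no reference behaviour is stated).
* All randomness flows through explicitly seeded PCG64 generators;
  simulation, pseudobulk subsampling and the bootstrap are bitwise
  reproducible for a fixed seed.
* Problem sizes in the test suite (cohorts of 150–300 samples, 1000
  genes, 10 seeded replicates for recovery; exhaustive subset oracles up
  to 8 candidates; binomial oracle up to n = 30) were chosen as the
  smallest scales at which each property is informative.

## Known limitations

* The shipped 5-ERG-mRPs partner list is reconstructed from the
  published description; the published pair directions are not stated
  and default to "ERG above partner votes TFP". Classification with a
  wrong direction on a pair would systematically flip that pair's votes.
* The as-printed reverse degree rewards non-reversing pairs (see above);
  the candidate pool therefore leans on the F-1 ranking for its
  discriminative half, matching the printed procedure.
* The greedy search is myopic; it matches a step-by-step greedy oracle
  exactly but is only bounded by, not equal to, the exhaustive-subset
  optimum.
* The binomial call treats pseudobulk classifications as independent
  Bernoulli trials, which overstates the information content of nested
  subsets; this is the procedure as defined.
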