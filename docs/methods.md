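# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order the pipeline runs them.

## Synthetic cohort generator

The generator exists so that every downstream stage can be validated
against planted truth at desk scale; its defaults define the conditions
under which the test suite's recovery claims hold.

**Precursor library.** Hairpins are built as `flank5 + arm + loop +
revcomp(arm)±mutations + flank3` (arm 20–24 nt, loop 8–15 nt, flanks 5–15
nt, 0–2 arm mismatches), accepted only if the package's own folder reports
a stem pairing fraction ≥ 0.55, and placed on a mini-genome with ≥ 100 nt
of random flank so excision windows stay in bounds.  About 10% of known
precursors have a single annotated arm.  The genome additionally carries a
7-copy 30-nt repeat family (to exercise the > 5-position exclusion) and
annotated decoy ncRNA loci.  The genome is capped at 2 Mb.

**Cohort design.** Every patient has one pCRC and ≥ 1 metastasis; ~18% of
patients contribute a second metastasis and two patients contribute a
second pCRC-class sample (a double primary and a local recurrence), so 38
patients yield ≈ 40 pCRC + 45 M samples.  PN and MN samples attach to
configurable patient fractions (defaults 0.60 and 0.45 → 23 PN, 17 MN at
n = 38); MN patients are drawn from the PN patients because normal-tissue
sampling co-occurs in practice, and because the patient-paired MN–PN
contrast otherwise has too few pairs to be estimable at cohort scale.
Metastatic organs are drawn with liver overrepresented (p = 0.45).
Resection gaps are drawn half below and half above the 90-day
synchronicity threshold, with occasional metastasis-first cases.  Two
replicate groups (a biological triplicate and a technical duplicate) are
always emitted.

**Counts.** `count ~ NB(mean, dispersion)` with
`mean = libsize · exp(baseline + patient intercept + planted effects)`;
the gamma–Poisson construction reduces exactly to Poisson at dispersion 0.
Defaults: baseline log-abundance N(−10.4, 1.5²) (median ≈ 30 counts at a
10⁶ library), dispersion 0.15 (typical tagwise miRNA-seq scale), patient
intercept SD 0.2, library sizes log-uniform on [5×10⁵, 2×10⁶] — a
desk-scale stand-in for ~10⁷-read libraries; tests need relative
structure, not absolute depth.  The patient intercept both induces the
pairing correlation the paired tests exploit and sets inter-patient
heterogeneity; at 0.2 it is small enough that tumor-vs-normal signal
(hundreds of affected miRs) dominates sample clustering, matching the
observed complete tumor/normal separation, while the 8-miR
metastasis-specific signal does not.

**Planted effects** (natural-log fold changes, index sets disjoint):

| set | acts on | default magnitude |
|---|---|---|
| tumor up/down (135 + 87) | pCRC and M | \|N(0.9, 0.4)\| clipped [0.4, 2.7] |
| metastasis-specific (8) | M only | \|N(1.3, 0.25)\| clipped [0.9, 2.0] |
| tissue-specific decoys (29) | M and MN | \|N(1.0, 0.2)\| clipped [0.8, 1.6] |

Tumor magnitudes follow the reported tumor-vs-normal table range.  The
metastasis-specific scale follows the reported tissue-corrected contrast
magnitudes (0.80–2.32, mean ≈ 1.3) and a power calculation: the one-sided
|M−pCRC| − |MN−PN| statistic has standard error ≈ 0.2 at 45/17 pairs with
per-pair SD ≈ 0.65, so planted contrasts below ≈ 1 are undetectable by
*any* test at this cohort size — planting them would measure the cohort's
information limit, not the pipeline.  Tissue decoys act on M and MN alike,
so they create exactly the |M−pCRC| ≈ |MN−PN| pattern stage 2 must reject.

**Reads.** Each counted molecule becomes one read: 5' start jittered over
{−2…+5} by a truncated geometric (decay 0.04, ≥ 0.9 mass at 0 — the
acceptance window is stated by the protocol, the offset distribution is
not, so a sharply peaked choice is declared here), optional untemplated 3'
A/U (p = 0.05), 3' adapter (TruSeq small RNA), substitution errors at
10⁻³, plateau Q37 qualities with a sub-Q30 3' tail in 20% of reads (to
exercise the Q30 trimmer), plus decoy/repeat-locus reads (1%) and
adapter-dimer reads (0.5%, the reads lost at preprocessing).  What the
generator does **not** emulate: realistic per-base error profiles,
ligation bias, isomiR biology beyond the stated jitter/addition model, or
any sequence composition signal distinguishing real miRs — so passing
tests demonstrate the pipeline's rules and statistics, not classifier
performance on real genomes.

## Preprocessing

Quality trimming removes the maximal 3' suffix in which *every* base is
below Q30 (strict `< 30`); an internal low-quality base 5' of a
high-quality base survives.  Adapter clipping removes the read suffix from
the leftmost position where a prefix of the adapter matches with ≤ 1
mismatch per 10 nt of overlap (≥ 6 nt overlap, or any position for a
full-adapter occurrence).  Collapsing orders unique sequences by
decreasing count for determinism.  Genome mapping is full-length, ungapped
(appropriate for miR-length queries), both strands, ≤ 2 mismatches, and
returns the complete equally-best tier — the multi-assignment rule in
quantification needs all of it.  The mapper is seed-and-verify with
pigeonhole k-mer seeds; its contract is verified against a brute-force
sliding-window scanner in the tests.

## Discovery

Folding is a maximum base-pairing dynamic program (Watson–Crick + G·U,
minimum loop 3 nt) with helices shorter than 2 stacked pairs pruned from
the traceback — deliberately not a thermodynamic nearest-neighbour model,
and with no cross-species conservation term.  Under maximum pairing even
random sequence reaches pairing fractions of ~0.5–0.7, so the pairing
fraction is a weak discriminator; discrimination comes from the read
signature and the exclusion rules, which are implemented exactly: reads at
> 5 genomic positions excluded, candidate loci overlapping annotated
ncRNA/coding intervals excluded, and the final cutoff calibrated by
permutation.  The permutation null shuffles read start positions uniformly
within each locus window.  Score weights (mature log-count 1, star 2,
loop 1, pairing 2, outside-fraction penalty 2) are unstated upstream and
config-exposed; a locus with no reads scores 0 by convention.  The SNR at
cutoff c is `(candidates ≥ c + known miR count) / mean permuted count ≥ c`
and the lowest c on the observed score grid with SNR ≥ 5 is chosen.

## Quantification

Alignment to precursors tolerates ≤ 1 substitution; the window test is
exact on coordinates: a read is assigned to an arm iff its 5' start lies
in `[mature_start − 2, mature_start + 5]`.  The window applies to the 5'
start only — untemplated additions perturb the 3' end, which is left
unconstrained beyond full-length containment in the precursor.  Among a
sequence's hits only the minimum-mismatch tier survives; every surviving
window hit receives the full count (duplication, not fractional
splitting, following the stated assignment rule); surviving off-window
hits contribute nothing.  "Related precursors" are defined by identical
mature sequence (robust for novel candidates, and consistent with the
canonical multi-copy precursor example); their rows are merged by
arithmetic mean, which is why the count matrix is real-valued.

## Statistics

**TMM.** Reference sample: upper-quartile/library-size ratio closest to
the cohort mean.  Per sample, M and A values over genes positive in both
sample and reference; delta-method precision weights; double trimming by
average ranks (30% on M, 5% on A); factors rescaled so the reference is 1.
Verified to 10⁻⁸ against an independently coded naive implementation.

**Paired model.** Per-patient differences of `ln(normalized + 1)` are
regressed on an intercept plus mean-centered covariates, so the intercept
is the covariate-adjusted mean log fold change.  Covariates: organ of
metastasis (M–pCRC only; one-hot, degenerate levels dropped), time
between resections (0 when the gap is < 90 days or the metastasis came
first), chemotherapy-between flag.  A patient with two metastases
contributes both pairs; two pCRCs are averaged (expression and resection
time).  Within a replicate group only the first sample enters pairing.

**Moderation.** Squared standard errors are shrunk toward a
scaled-inverse-χ² prior whose (d₀, s₀²) are fitted by marginal maximum
likelihood (the marginal of s²/s₀² is F(d, d₀)); moderated t statistics
get d + d₀ degrees of freedom and are probit-transformed to z scores via
log-survival functions (numerically safe far into the tails).

**Local fdr / Bayesian FDR.** The marginal z density is estimated by
Lindsey's method: Poisson fit of histogram counts (120 bins) on a cubic
B-spline basis with evenly spaced interior knots (~1.2 z-units apart; at
typical z-ranges this gives ~15–25 effective df).  Even spacing matters:
quantile-placed knots bridge the empty valley between the null bulk and a
well-separated alternative cluster and inflate the realized FDR.  The fit
is a ridge-stabilized IRLS (λ = 10⁻⁴) because basis columns supported
only by empty bins have −∞ unpenalized MLEs; a fit that fails a
track-the-histogram sanity check falls back to a Gaussian KDE.  The null
is N(μ₀, σ₀²) estimated by central matching (quadratic fit to the log
density near its center, σ₀ clipped to [0.7, 1.6]), used only when the
bulk sits near 0 and there are ≥ 200 features; moderated statistics from
correlated paired designs are routinely ~5–10% overdispersed relative to
N(0, 1), which a theoretical null converts into badly anticonservative
fdrs.  π₀ matches the marginal and null densities at μ₀, capped at 1.
The Bayesian FDR of a feature is the mean local fdr over all features at
least as significant; it is nondecreasing along the lfdr ranking by
construction.  Calibration, measured by the suite: realized FDP ≈ 0.12 at
nominal q = 0.10 with 10% planted alternatives; < 10⁻³ of features called
under a global null.

This moderation + two-groups machinery is a declared substitute for the
original zero-inflated-NB Bayesian fitting; the selection logic, contrast
structure, covariate rules and the Bayesian-FDR definition are preserved
exactly.  Zero-inflation is not modelled (the presence filter removes the
worst of it); that is a known limitation for very sparsely expressed miRs.

**Tissue-specificity test.** T = |effect(M−pCRC)| − |effect(MN−PN)| per
miR, with one-sided significance by ≥ 1999 permutations of pair labels
between the two pair collections (one permutation applied across all miRs,
preserving pair-level exchangeability).  Reported p-values are the
empirical permutation p-values; for the local-fdr input the observed T is
studentized against the mean and SD of its own permutation null, which
extends resolution beyond the 1/(n_perm+1) floor — at 8 true signals in
1714 features, p-values capped at 5×10⁻⁴ carry too little information for
any FDR procedure to separate them.  Under the null the studentized
statistic is approximately N(0, 1) by construction.

**Selection.** Stage 1: M–pCRC BFDR ≤ 0.10 (the looser threshold is the
stated choice for this contrast, to limit false negatives).  Stage 2 keeps
stage-1 miRs whose tissue test reaches BFDR ≤ 0.05 (the level consistent
with the reported tissue-corrected FDRs, all ≤ 0.046); the rest are
reported as tissue-specific exclusions.  Tumor-specific selection requires
BFDR ≤ 0.05 in *both* tumor-vs-normal contrasts with concordant sign;
up-regulated hits with overall geometric mean > 1000 form the biomarker
shortlist.  Geometric means use the `exp(mean(ln(x+1))) − 1` convention
(the zero-handling convention is not stated upstream; +1 is declared
here).

## Profiles

Clustering: Ward linkage on Euclidean distances between sample columns of
`log2(normalized + 1)`; per-miR row scaling is a heatmap display
convention and is never applied before clustering.  Saturation:
subsampling without replacement, nested across depths (one permutation per
replicate, prefix per depth), so each replicate's curve is monotone — the
in-silico analog of resequencing the same library deeper.  Concordance:
Spearman correlation on miRs detected in both samples of a replicate
pair.  Report percentages are rounded half-up at the requested precision
(the convention that reproduces every printed ratio in the worked
examples).

One printed saturation figure (the first-interval rate) is internally
inconsistent with its own printed depths at printed precision; the
unrounded depths are unavailable, so only the second-interval rate (4.5
miRs per million reads) is reproduced.

## Problem sizes used by the tests and acceptance script

Study-shaped runs use 38 patients (45 M–pCRC, 23 PN, 17 MN pairs after
replicate handling) and 1714 miRs, 5 replicates; FDR calibration uses
2000 features × 30 pairs × 20 seeds; the mapping oracle uses a 200 kb
genome and 500 queries; round-trip and discovery runs use ~35–45
precursors and 10⁴–10⁵ reads per sample.  These sizes were chosen so the
full suite completes in well under ten minutes while every claim is still
measured at the cohort's real pair counts where pair counts matter (the
tissue test's power is set by the 17 MN–PN pairs, not by read depth).

## CLI and configuration

The library is the primary interface; `mirpair synth|preprocess|discover|
quantify|stats|profiles|all` is a thin orchestration layer over it.  All
fixed constants live in `AnalysisConfig` (YAML-overridable): Q30 trim,
18-nt/2-mismatch mapping, 1-mismatch precursor alignment, −2/+5 window,
5-locus exclusion, 5:1 SNR, 70/20 flanks, q = 0.10 / 0.05 / 0.05
thresholds, 3-sample presence filter, 90-day synchronicity, 1000
expression shortlist cut.  All randomness derives from the single config
seed via fixed stage offsets.
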