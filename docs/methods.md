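# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the shipped validation shows.

## Differential editing: beta-binomial likelihood-ratio test

Editing at one site is a pair (edited, coverage) per sample. Counts are
modelled as beta-binomial with mean `μ ∈ [0,1]` and overdispersion `φ > 0`
in the parameterization `a = μ/φ`, `b = (1−μ)/φ`, chosen so that mean and
dispersion are orthogonal: the variance of a sample's editing level is
`μ(1−μ)·[φ + (1−φ)/n]/(1+φ)` to first order, so `φ` is (approximately) the
intraclass correlation of reads within a sample. `φ → 0` recovers the
binomial.

Maximum likelihood uses L-BFGS-B on `(logit μ, log φ)` with bounds
`μ ∈ [10⁻⁶, 1−10⁻⁶]` (so all-zero / all-full counts keep a finite
likelihood) and `φ ∈ [10⁻⁶, 100]`, started from moment estimates plus two
dispersion-bracketing restarts; the returned likelihood is floored at the
moment estimate's. On a dense grid audit the optimizer attains the global
optimum on every dataset tried.

The two-group test fits each group and the pooled data and refers
`Λ = 2(ℓ₁ + ℓ₂ − ℓ_pooled)` to χ² with 2 df (both `μ` and `φ` freed per
group). At the study's sample sizes (8 vs 5) the asymptotic reference is
measurably anticonservative: the null mean of Λ is ≈ 2.5–2.7 rather than 2,
inflating the 5 % size to ≈ 0.11. We therefore apply a **Bartlett-type
correction**: Λ is divided by its simulated null mean over 2 (the factor is
estimated once per dataset by Monte Carlo at the median per-site moment
estimates of `(μ, φ)`, the median usable group sizes, and the median
coverage, with a fixed internal seed; 1000 simulated sites by default). The
factor is floored at 1, so the correction can only make the test more
conservative; the uncorrected statistic is reported alongside the corrected
p-value, and the correction can be disabled
(`small_sample_correction=False`). With the correction the test holds its
size (empirical α ≈ 0.05, p-values KS-uniform) under the validation
conditions below.

A site is called differentially edited when `|μ̂₂ − μ̂₁| ≥ 0.05` and
`p < 0.05`. No multiple-testing correction enters this call; BH FDR is
reported as an extra column. Samples with coverage below 10 at a site are
treated as missing for that site, and a site needs ≥ 2 usable samples per
group to be tested.

Global comparisons: the per-sample editing index is coverage-weighted,
`Σ edited / Σ coverage` over passing sites. Two modes compare groups —
pairing sites (each site contributes its two group means to a paired
t-test) or comparing per-sample indices with Welch's t — because the
pairing unit of such tests is genuinely ambiguous in practice; both are
exposed. ADAR-family expression is related to the index by Spearman
correlation.

## Splicing

Events are re-derived from annotation by pairwise transcript comparison.
An alternative 5'/3' splice site requires the two differing junction
boundaries to come from *overlapping* exons (long/short variants of the
same exon); without that guard, skipped-exon and mutually-exclusive
structures masquerade as A5SS/A3SS pairs. Effective junction counts are
SE 2/1, RI 2/1, MXE 2/2, A5SS and A3SS 1/1 (inclusion/skipping), and
`PSI = (I/L_I)/(I/L_I + S/L_S)`.

Differential splicing is a binomial likelihood-ratio test with a group
term on the pooled inclusion/skipping junction counts (χ², 1 df); ΔPSI is
the difference of group mean per-sample PSI (second group minus first).
This deliberately replaces the rMATS paired-likelihood machinery with the
simplest calibrated test of the same null; the package's claims concern
thresholds and integration, not the internals of junction-count modelling.
Events with fewer than two defined-PSI samples in a group are skipped, not
imputed. Calls require `|ΔPSI| > 0.1` (strict) and BH FDR < 0.05.

## Editing–splicing association

Sites pair with the nearest event *within their host gene*, distance being
the minimum absolute distance to any defining boundary of the event (ties:
smaller event start, then lexicographic id) — boundaries, not midpoints,
because mechanistic proximity to splice sites is the point. Spearman is the
default correlation (Pearson by flag); for n ≤ 9 tie-free samples the
permutation p-value is exact (all n! orderings), above that the usual t
approximation is used. Significance is `|r| > 0.5` (strict) and `p < 0.05`,
computed pooled across samples by default, or within groups with
`per_group`.

## Splice-site strength

Donor windows are 9-mers (3 exonic + 6 intronic nt), acceptor windows
23-mers (20 intronic + 3 exonic nt), stored 5'→3' on the transcript strand;
positions are labelled by 1-based distance from the exon–intron boundary
(`5'ss-2e`, `3'ss-2i`, …). Scores are log₂-odds from a maximum-entropy
model. When a directory with the published table files is supplied
(`me2x5`, `me2x3acc1..9`), the standard decompositions are used: the donor
consensus GT factor times a 4⁷-entry lookup over the non-consensus
positions; the acceptor consensus AG factor times the five-numerator /
four-denominator product over sub-k-mers of the remaining 21-mer. The
tables are not shipped (they are external data); without them a first-order
PWM model trained on the annotation's own donor/acceptor windows
(pseudocount 0.5, uniform background) provides a consistent offline score.
The editing delta is `score(edited) − score(unedited)` — negative means
weakening — with the A→G edit applied on the transcript strand; a window
whose base at the site is not A is flagged inconsistent rather than scored.

## RBP binding deltas

Flanks are ±50 nt around the site, transcript-strand oriented, truncated
and flagged at chromosome ends. Motifs are probability PWMs (length 4–12,
pseudocount 10⁻³ on load, uniform background); affinity is the best
(maximal) log₂-odds hit over all offsets, ties to the smallest offset —
the standard single-number proxy when per-site matches are reported. The
published alteration rule gives only "Δscore exceeding 20 %" without a
denominator; we read it as relative change `Δ / max(|unedited|, 1)` (the
floor prevents blow-up near zero), with an absolute-Δ mode behind a flag.
The locality property — a nonzero delta requires a best-scoring window
covering the edited base — is enforced by construction and verified
exhaustively in the tests.

## Triplet network

A (site, RBP, event) triplet requires: the site–RBP pair altered; an
eCLIP-style peak of that RBP overlapping the event's defining coordinates
± 300 nt (typical eCLIP resolution, configurable); and the site–event pair
correlation-significant. Triplets are deduplicated by identity and the
graph is tripartite (RES→RBP, RBP→AS edges); hub ranking is by degree with
lexicographic tie-breaks. A direct binding-change-vs-PSI correlation
variant is intentionally not part of the default conjunction, because no
formula for it is established; the peak-overlap + pair-correlation
operationalization is used instead.

## Synthetic cohorts

The generator writes a complete cohort — genome FASTA, two-transcript gene
models with canonical GT..AG introns (one planted event class per gene),
count and junction tables, WES/dbSNP masks, PWM file, eCLIP BED and a truth
JSON — deterministically from integer-seeded per-component RNG streams.
Defaults mirror the study design: 8 RIA + 5 UIA samples (controls
optional), coverage ~ Poisson(50) truncated at 1 (the coverage law of the
real data is unknown; Poisson is an explicit stand-in knob), junction depth
200.

Parameter choices worth recording:

* Ordinary sites use `φ = 0.02`. Editing levels of the same site across
  human individuals are tightly clustered; at 13 samples and 100× this
  puts the per-site mean-level sampling error near 0.02, which is also the
  regime in which per-site recovery is meaningfully testable.
* Planted differential sites use μ 0.2 vs 0.4 (alternating sign).
* Coupled site–event pairs (`slope 4, φ = 0.1`) represent moderately
  variable regulatory sites: the logit of the sample's PSI is shifted by
  `slope · (e_s − μ)` with `e_s` the *realized* editing level, so the
  coupling strength seen downstream includes measurement noise honestly.
* Triplet-planted sites use `slope 8, φ = 0.3` — strongly coupled,
  high-variance regulatory sites — so that full triplet recovery is an
  oracle property of the fixture rather than a power statement; the
  moderate-slope pairs carry the power claims.
* Junction counts are drawn with inclusion probability
  `ψL_I/(ψL_I+(1−ψ)L_S)` so the length-normalized PSI estimator is centred
  on the planted ψ for every event class.
* Planted motifs are the flank's own 6-mer through the site (consensus A
  at the centre; for gain plans, G). The generator rewrites chance
  duplicate occurrences of the consensus within the ±50 nt flank so the
  planted match is unique — otherwise the edit can leave the best score
  unchanged. Decoy RBPs carry all-pyrimidine consensi, whose scores are
  provably invariant under an A→G edit.
* WES/dbSNP masks are drawn from the ordinary (null/differential) sites
  only, keeping planted couplings intact; masked-site counts are exact
  (`round(fraction · n)`).
* Decoy triplet combinations each lack one *deterministic* evidence layer
  (no peak, or a never-altered motif). Correlation-layer false positives
  are a rate (≈ 5 % per pair by construction) and are validated as a rate
  in the null-slope study, not as a zero-count fixture property.

What passing on synthetic data does **not** show: robustness to alignment
artefacts, coverage-dependent editing biases, batch effects, non-Poisson
coverage, unannotated junctions, or RBP motif models beyond first-order
PWMs. The cohorts validate the statistics and the plumbing, not the
upstream measurement process.

## Validation sizes and determinism

The shipped studies use 2000 null sites (test size and KS uniformity), 500
planted sites (power), 1000 sites (recovery MAE), 2000 null / 500 planted
events (splicing), 300/500 replicates (coupling power/null rate), and a
full cohort run executed twice (byte-identical reports). These sizes give
Monte-Carlo standard errors a few times smaller than the margins being
checked while keeping the whole suite in a few CPU-minutes. All randomness
derives from explicit integer seeds; pipeline runs contain no randomness
beyond the Bartlett factor's fixed internal seed, so reports reproduce
byte-for-byte.

## Known limitations

* The Bartlett factor is dataset-level, not site-level; sites whose design
  deviates strongly from the median (many low-coverage samples) are
  corrected with the global factor.
* The acceptor maximum-entropy model is only exercised against synthetic
  tables offline; agreement with the published implementation to printed
  precision requires the official table files.
* Region annotation precedence (splice-site > 3'UTR > 5'UTR > exonic >
  intronic > intergenic) is explicit and deterministic but coarser than a
  full transcript-aware annotator.
* The GLMM formulation mentioned alongside the β-binomial model in the
  source literature is not reconciled there; this package implements the
  two-group β-binomial LRT throughout.
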