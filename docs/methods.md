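# Methods

This note documents the models and estimators implemented in `ribocycle`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Study design and containers

All analyses assume a two-organ circadian design: 12 Zeitgeber timepoints in
2-h steps (ZT0–ZT22), two replicates per timepoint, and two assays per organ
(RPF-seq footprints and RNA-seq), i.e. 24 libraries per organ×assay and 96 in
the full design. Libraries are identified by `organ_assay_ZThh_repN` column
keys. Coordinates are 0-based, half-open and transcript-relative throughout;
genome coordinates are never needed because footprints arrive
transcript-mapped.

## Normalization, RPKM and TE

Upper-quartile normalization: for each library the factor is the 75th
percentile of counts over genes with a positive count, divided by the raw
library depth; factors are rescaled to geometric mean 1 so that effective
library sizes (raw depth × factor) stay on the raw-depth scale. RPKM is
count / (CDS length/1000) / (effective size/10⁶), with no mappable-length
("faux reads") correction. TE is the per-gene, per-sample ratio of RPF-RPKM
to RNA-RPKM, undefined (missing) where the RNA denominator is zero. The
published description of the RPKM denominator ("geometric mean of normalised
read counts per million") is ambiguous; the implementation uses effective
sizes with geometric-mean-1 factors, which makes RPKM invariant under global
depth rescaling of any library — the property the tests assert. The
alternative reading (a per-sample geometric-mean denominator) differs only
by a constant global factor.

Measurement error: genes are binned into 10 deciles of the fourth root of
the product of the four class means (liver RNA × liver RPF × kidney RNA ×
kidney RPF). Within a bin, for each timepoint, ME_t = mean over genes of
(log x₁ − log x₂)²/2 on log(normalized count + 0.5); the mean and SD of ME_t
over the 12 timepoints are reported per organ×assay. The 0.5 pseudo-count
handles zeros and is exposed (`pseudocount=`); tests that verify the
closed-form behaviour of the estimator use `pseudocount=0`. An optional
filter excludes genes whose mean expression ratio (between organs at fixed
assay, or between assays at fixed organ) exceeds 2 at every timepoint.

## Rhythm detection

Model space: flat y = m versus a single 24-h harmonic
y = m + a·cos(ωt) + b·sin(ωt), ω = 2π/24, fit by least squares on
log2(RPKM + 0.05) with replicates entering as independent observations at
the same ZT. Model choice by AIC with k = 1 vs 3 parameters; a gene is
rhythmic when the harmonic wins AND the peak-to-trough fold 2^(2√(a²+b²))
reaches the amplitude cutoff (default 1.5). Restricting the harmonic family
to the fundamental keeps the fit identifiable from 12 distinct timepoints;
higher harmonics are deliberately omitted. Peak phase is
φ = (24/2π)·atan2(b, a) mod 24. Residual sums of squares are floored at
1e-12 before the AIC log so that noiseless fits stay finite; a constant
series then selects the flat model and is additionally excluded by the
fold-1 gate.

Phase differences Δ = φ_RPF − φ_RNA are wrapped into (−12, +12]; the +12
boundary maps to +12 by convention. Negative Δ means the footprint peak
precedes the mRNA peak.

Permutation test between two Δ distributions: statistic = two-sample KS
distance; null built by pooling and re-splitting at the original sizes;
add-one estimator p = (1 + #{perm ≥ obs})/(n_perm + 1) with n_perm = 10⁴ by
default, so identical samples give exactly p = 1 and p-values are uniform on
the achievable grid under the null.

Watson–Wheeler homogeneity test: phases (hours × 2π/24) are replaced by
uniform scores via circular ranks (average ranks on ties, logged);
W = 2Σ_k(C_k² + S_k²)/n_k with df = 2(k−1) referred to χ². Groups below 10
phases are rejected, as the χ² approximation degrades.

Cross-correlation: r(k) = Σ_t(x_{t+k}−x̄)(y_t−ȳ)/(n·s_x·s_y) with overall
means and population SDs and truncation at the series ends (the convention
of R's `ccf`); profiles are replicate-averaged first and are NOT z-scored
beyond the formula's own standardisation. Lag k is in 2-h steps, reported in
hours; negative lags mean the RPF series leads. A circular variant is
available behind `circular=True`. Constant profiles yield NaN correlations
with a logged warning.

Translation-only screen (rhythmic translation on flat mRNAs): a gene passes
when its RPF series is called rhythmic, its RNA series is non-rhythmic with
fold below the amplitude cutoff, and its TE varies across the 12 ZTs by
Kruskal–Wallis at BH FDR < 0.05. The third condition replaces an external
regression framework with a distribution-free test of the same question —
whether TE is time-dependent.

## Differential TE and compensation

Per gene, the paired Wilcoxon signed-rank test is applied to log TE
differences over the 24 matched samples; zero differences are dropped. For
n ≤ 25 pairs the exact sign-flip null of the rank sum is enumerated by
dynamic programming over doubled (average) ranks, so fully tied differences
— e.g. a uniform 2-fold shift, p = 2/2²⁴ — still receive exact p-values;
larger n uses the normal approximation with continuity correction (the two
agree to machine precision on untied data, which the tests check against
scipy). BH adjustment across genes; differential ⇔ q < 0.01 AND
|log2 median ratio| ≥ log2(1.5).

Compensation: for each timepoint×replicate sample the cross-organ Spearman
correlation over genes is computed at the RNA and at the RPF level (kidneys
and livers of one replicate come from the same animals, hence the pairing);
Fisher-z coefficients are compared by a paired two-sided t-test. RPF
correlations exceeding RNA correlations indicate that TE differences
counteract mRNA-abundance differences.

## A-sites, frames, metagene

A-site = footprint 5′ end + length-dependent offset; the default table maps
26–30 nt → +14 and 31–35 nt → +15 and is config-exposed and logged, since
offsets are protocol-dependent. Reads with lengths outside the table are
dropped and logged. Frame fractions are counted relative to a unit's start
codon. Metagene profiles average per-transcript densities around start and
stop codons after scaling each transcript's window to mean 1, so genes
contribute equally regardless of expression; qualifying transcripts need
CDS > 400 nt and (optionally) mean RPF RPKM > 5.

## uORFs

Candidates: every AUG whose codon lies fully within the 5′UTR, extended to
the first in-frame stop codon (which may lie downstream of the UTR);
candidates with coding span (AUG through the last codon before the stop)
< 18 nt are discarded — the boundary value 18 is included. Candidates
running into the CDS in the same frame are N-terminal extensions, not uORFs,
and are dropped; out-of-frame overlaps are kept with the countable span
clipped at the CDS start, so only 5′UTR-specific positions are counted.
Overlapping candidates merge into one composite counting unit whose frame is
taken from its 5′-most AUG. Translation call: one-sided exact binomial test
of the A-site count in the uORF's frame against the uniform rate ⅓
(α = 0.05) plus coverage > 10 % of countable positions; coverage is counted
at single-nucleotide resolution by default with a codon-resolution variant
behind a flag. uORF TE uses the same normalization machinery as the CDS
quantification, on span counts, with the span length cancelling in the
ratio.

## Isoform divergence, Kozak, features

Hellinger distance with the 1/√2 prefactor on per-organ isoform proportion
vectors over a shared isoform universe (absent isoforms carry zeros);
vectors must sum to 1 within 1e-6. Feature attribution compares the
expressed isoforms' per-feature identities: exactly one varying feature
gives `5utr-only`/`cds-only`/`3utr-only`; several varying features with a
shared 5′UTR give `5utr-identical`; identical proportion vectors give
`identical-set`; anything else is `mixed`. Kozak scoring: +3 for G at −6,
A/G at −3 and G at +4; +1 for C at −5, −4, −2, −1; maximum 13. When the
5′UTR is shorter than 6 nt the missing upstream positions are padded with N
and score 0.

## Clustering

Per gene, the 4×4 Euclidean distance matrix between its replicate-averaged
12-point log2 profiles; fusion = weighted elementwise mean with equal
weights by default (the weighting scheme is genuinely open; equal weights
make fusion linear and permutation-equivariant in genes, and alternative
weights are a parameter). Average-linkage agglomeration via scipy; leaf
labels are sorted lexicographically first so height ties break
deterministically. Profiles are not z-scored by default (a per-profile
standardisation flag would change which contrasts dominate; the default
keeps mean offsets — i.e. organ differences — in the distances, which is
what the compensated-vs-uncompensated topology contrast relies on).

## Synthetic data: what it emulates, and what it does not

Per gene g, organ o, assay a and time t the expected count is
L_j · 2^(m_g + organ/assay shifts + rhythm terms) · CDS-length/1000,
rescaled to the library size L_j, with negative-binomial noise
(var = μ + α·μ²) sharing one dispersion α across genes. Defaults (chosen
once as field-realistic):

- baseline log2 level ~ N(5, 2); cross-organ RNA log2 ratios ~ N(0, 2) vs TE
  log2 ratios ~ N(0, 0.5), mirroring the observation that mRNA abundance
  differs between organs over a far wider range than ribosome loading does;
- compensation: TE organ-ratios are drawn with correlation
  `compensation_rho` (default −0.4) to the RNA organ-ratios; −1 would be
  full buffering, 0 none;
- 10 % of genes carry RNA rhythms, 5 % TE-only rhythms, half-amplitudes
  uniform in (0.3, 1.0) log2, phases uniform over the day;
- planted RPF rhythms lag RNA rhythms by N(−2.0, 0.5) h in kidney and
  N(−0.5, 0.5) h in liver — deterministic shifts of the cosine argument,
  not a mechanistic decay model;
- NB dispersion 0.05; library sizes uniform in (8·10⁶, 12·10⁶) to exercise
  normalization; dispersion 0 is noise-free (counts = rounded means), which
  gives the tests an exact regime;
- footprints: 26–35 nt, placed so that after A-site offsetting a fraction
  `f_frame` (default 0.85) falls in frame 0 of the CDS and of each planted
  translated uORF; non-translated planted uORFs get frame-uniform coverage;
- 20 % of genes carry a planted 5′UTR uORF (coding span 18–33 nt); planted
  uORF interiors use an A/C-only alphabet and other accidental UTR AUGs are
  removed, so the planted coordinates are exactly recoverable;
- isoforms: 40 % of genes get 2–3 isoforms with Dirichlet proportions, 30 %
  of those diverge between organs.

Not emulated: raw reads/FASTQ, alignment artefacts, rRNA contamination,
positional biases along transcripts (footprint counts and CDS counts are
generated independently rather than from one read stream), mechanistic
deadenylation kinetics behind phase lags, and genome-coordinate annotation.
Passing tests therefore demonstrate estimator correctness and calibration
under the stated count model — not robustness to mapping artefacts or
protocol-specific biases in real libraries.

## Problem sizes and numerical choices

Tests and examples run simulations of 150–2000 genes, which is sufficient
for the planted effects to be estimable with the stated margins while
keeping the suite fast. Notable numerical decisions, collected: RSS floor
1e-12 in AIC; log2 pseudo-count 0.05 for rhythm fits and 0.5 (natural log)
for measurement error; Spearman ρ clipped to ±0.999999 before Fisher z;
exact signed-rank DP below n = 26; average ranks for all tie handling;
add-one permutation p-estimator; lexicographic tie-breaking in clustering.

## Known limitations

- The rhythm model fits a single 24-h harmonic; ultradian or strongly
  non-sinusoidal rhythms are attenuated and may fail the amplitude gate.
- The translation-only screen inherits the conservativeness of
  Kruskal–Wallis with two observations per timepoint; it trades power for
  distribution-freeness.
- uORF detection is restricted to AUG starts; near-cognate initiation is
  invisible to it.
- Fusion weights and profile standardisation in clustering are defaults,
  not estimates; conclusions about tree topology should be checked against
  the flags.
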