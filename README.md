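# ribocycle

Around-the-clock, dual-organ translatome analysis for paired ribosome
profiling (RPF-seq) and RNA-seq time courses.

Organs transcribe largely overlapping gene sets at very different levels, yet
protein synthesis rates are buffered: translation efficiency can counteract
mRNA-abundance differences between tissues, shift the timing of rhythmic
protein production relative to rhythmic mRNA accumulation, and respond to
regulatory elements such as upstream ORFs and alternative 5′UTRs. `ribocycle`
implements the statistical toolkit for dissecting these layers in a
two-organ (kidney/liver), 12-timepoint (ZT0–ZT22, 2-h steps), 2-replicate
circadian design — 96 libraries in total — together with a synthetic-data
generator that emulates the full design with known ground truth, so every
stage is testable without external downloads.

## What it computes

- **Quantification** (`ribocycle.quant`): upper-quartile library
  normalization (factors rescaled to geometric mean 1), RPKM, per-sample
  translation efficiency TE = RPF-RPKM / RNA-RPKM, and replicate-based
  measurement error per expression decile.
- **Rhythm detection** (`ribocycle.rhythm`): per-gene harmonic fits
  y = m + a·cos(2πt/24) + b·sin(2πt/24) vs a flat model, selected by AIC;
  peak phase φ = (24/2π)·atan2(b, a), peak-to-trough fold 2^(2√(a²+b²)),
  with a 1.5-fold amplitude gate. Phase-lag analysis: wrapped RPF−RNA peak
  differences on (−12, 12], a KS permutation test between lag distributions,
  the Watson–Wheeler test for homogeneity of circular phase distributions,
  lagged cross-correlation (negative lag ⇔ footprints lead mRNA), and a
  screen for rhythmic translation on constantly expressed mRNAs.
- **Differential TE & compensation** (`ribocycle.difftrans`): paired
  Wilcoxon signed-rank on log TE over the 24 matched samples (exact
  sign-flip null for n ≤ 25, ties included), BH-FDR < 0.01 plus a 1.5-fold
  gate; per-sample cross-organ Spearman correlations at RNA vs RPF level
  compared by paired t-test on Fisher-z coefficients.
- **A-site & frame statistics** (`ribocycle.ribopos`): footprint 5′ end +
  length-dependent offset → A-site profiles, reading-frame fractions,
  metagene averages around start/stop codons.
- **uORFs** (`ribocycle.uorf`): AUG-initiated ORFs ≥ 18 nt in 5′UTRs,
  composite merging of overlapping spans, translation calls from exact
  binomial frame bias (null rate ⅓) with > 10 % coverage, and uORF TE.
- **Isoform divergence** (`ribocycle.isodiv`): Hellinger distance
  H(P_L, P_K) = (1/√2)·√Σᵢ(√p_Lᵢ − √p_Kᵢ)² between per-organ isoform
  proportion vectors, feature attribution (5′UTR/CDS/3′UTR), Kozak context
  scoring (GccA/GccAUGG, +3/+1 scheme, max 13), and transcript feature tables.
- **Profile clustering** (`ribocycle.cluster`): per-gene Euclidean
  dissimilarities between the four organ×assay profiles, weighted fusion
  across genes, average-linkage trees with Newick export.
- **Synthetic data** (`ribocycle.synthdata`): negative-binomial counts with
  planted organ ratios, compensation correlation, cosine rhythms, phase
  lags, 3-periodic footprints and uORFs — all recorded as ground truth.
- **Pipeline** (`ribocycle.pipeline.run_pipeline`): a config-driven
  end-to-end run writing every stage's tables plus a run manifest with file
  hashes for byte-level reproducibility.

## Worked example

`examples/` holds one short script per capability. For instance, rhythm
detection with phase-lag analysis on a simulated kidney dataset
(`python examples/02_rhythm_detection_and_lags.py`):

```
kidney RNA: 86/600 genes rhythmic (>1.5-fold peak-to-trough)
kidney RPF: 119/600 genes rhythmic (>1.5-fold peak-to-trough)

85 genes rhythmic in both assays
mean RPF-minus-RNA phase difference: -2.01 h (planted lag mean: -2.0 h)
phase advances (RPF first): 84, delays: 1

per-gene cross-correlation argmax lags: median -2 h, 65/85 genes negative (negative = footprints lead mRNA)
```

The simulation planted a mean −2 h footprint lead in kidney; the harmonic
fits recover it both as the mean wrapped peak-phase difference and as the
median per-gene cross-correlation lag. Similarly,
`examples/03_differential_te_and_compensation.py` plants anti-correlated
RNA and TE organ-ratios (ρ = −0.6) and reports a higher cross-organ Spearman
correlation at the footprint level than at the mRNA level
(ρ̄ 0.687 vs 0.567, paired t p ≈ 4e-30) — the signature of translational
compensation.

An end-to-end run with all outputs and a manifest:

```python
from ribocycle.pipeline import run_pipeline
manifest = run_pipeline({"simulation": {"seed": 1, "n_genes": 500}}, "out/")
```

## Documentation

`docs/methods.md` describes the models, estimators, defaults and numerical
choices, what the synthetic data does and does not emulate, and known
limitations.
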