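"""Detect 24-h rhythms and measure RPF-vs-RNA phase lags.

Fits every gene's log2 expression series with a 24-h harmonic against a flat
model (AIC selection plus the 1.5-fold peak-to-trough gate), then compares
footprint and mRNA peak phases for genes rhythmic in both assays. Negative
phase differences and negative cross-correlation lags both mean translation
peaks BEFORE mRNA abundance does.
"""
import numpy as np

from ribocycle import SimulationConfig, simulate_dataset
from ribocycle.quant import rpkm, upper_quartile_factors
from ribocycle.rhythm import (call_rhythms, cross_correlate,
                              phase_differences, replicate_mean_profile)

cfg = SimulationConfig(seed=7, n_genes=600, frac_rhythmic_rna=0.15,
                       nb_dispersion=0.02)
ds = simulate_dataset(cfg)

fits = {}
for assay in ("RNA", "RPF"):
    cm = ds.counts[("kidney", assay)]
    norm = upper_quartile_factors(cm)
    table = rpkm(cm, cm.lengths["cds_len"], norm.effective_sizes)
    fits[assay] = call_rhythms(table)
    n = int(fits[assay]["rhythmic"].sum())
    print(f"kidney {assay}: {n}/{len(table)} genes rhythmic "
          f"(>1.5-fold peak-to-trough)")

deltas = phase_differences(fits["RPF"], fits["RNA"])
print(f"\n{len(deltas)} genes rhythmic in both assays")
print(f"mean RPF-minus-RNA phase difference: {deltas['delta_h'].mean():+.2f} h "
      f"(planted lag mean: {cfg.phase_lag_mean_h['kidney']:+.1f} h)")
print(f"phase advances (RPF first): {(deltas['delta_h'] < 0).sum()}, "
      f"delays: {(deltas['delta_h'] > 0).sum()}")

# per-gene lagged cross-correlation of replicate-averaged profiles
genes = deltas.index
prof = {}
for name in ("RPF", "RNA"):
    cm = ds.counts[("kidney", name)]
    norm = upper_quartile_factors(cm)
    table = rpkm(cm, cm.lengths["cds_len"], norm.effective_sizes)
    prof[name] = replicate_mean_profile(np.log2(table.loc[genes] + 0.05))
best = np.array([
    cross_correlate(prof["RPF"].loc[g].to_numpy(),
                    prof["RNA"].loc[g].to_numpy()).best_lag_h
    for g in genes])
print(f"\nper-gene cross-correlation argmax lags: median {np.median(best):+.0f} h, "
      f"{(best < 0).sum()}/{best.size} genes negative "
      "(negative = footprints lead mRNA)")
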