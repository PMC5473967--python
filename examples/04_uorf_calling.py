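"""Detect upstream ORFs and call their translation from footprint frame bias.

Scans every 5'UTR for AUG-initiated ORFs of >= 18 nt, merges overlapping
candidates into composite counting units, maps footprints to ribosome A-sites
(5' end + length-dependent offset) and calls a uORF translated when its
A-sites are significantly biased towards its own reading frame (exact
binomial vs the uniform 1/3) and cover > 10% of its positions.
"""
import numpy as np

from ribocycle import SimulationConfig, simulate_dataset, simulate_footprints
from ribocycle.ribopos import a_site_positions
from ribocycle.uorf import call_translated, detect_uorfs, merge_composites

cfg = SimulationConfig(seed=12, n_genes=300, frac_uorf_genes=0.3)
ds = simulate_dataset(cfg)
footprints = simulate_footprints(ds.annotation, ds.truth, cfg)
profiles = a_site_positions(
    footprints, {t: a.length for t, a in ds.annotation.items()})

n_candidates = n_translated = 0
correct = []
for tid, ann in sorted(ds.annotation.items()):
    candidates = merge_composites(detect_uorfs(ds.sequences[tid], ann))
    for rec in candidates:
        n_candidates += 1
        if tid in profiles:
            rec = call_translated(rec, profiles[tid])
        if rec.translated:
            n_translated += 1
    planted = ds.truth.uorfs[ds.truth.uorfs["transcript_id"] == tid]
    for row in planted.itertuples(index=False):
        match = [r for r in candidates if r.start == row.start]
        if match:
            called = call_translated(match[0], profiles[tid]).translated
            correct.append(called == row.translated)

print(f"{n_candidates} uORF candidates on {cfg.n_genes} transcripts, "
      f"{n_translated} called translated")
print(f"planted uORFs: {len(correct)}; translation status recovered for "
      f"{100 * np.mean(correct):.1f}%")
print("(translated uORFs show 3-nt periodic A-sites in their own frame; "
      "untranslated ones are frame-uniform and fail the binomial test)")
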