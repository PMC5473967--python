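"""Quantify cross-organ isoform-usage divergence with the Hellinger distance.

For each gene, the per-organ vector of isoform expression proportions is
compared between kidney and liver: H = 0 means identical isoform usage,
H = 1 means the organs express disjoint isoform sets. The Kozak context of
each transcript's start codon is scored against the GccA/GccAUGG consensus
(0-13; higher = stronger expected initiation).
"""
from ribocycle import SimulationConfig, simulate_dataset
from ribocycle.isodiv import feature_table, hellinger_table

cfg = SimulationConfig(seed=3, n_genes=400, frac_multi_isoform=0.5,
                       frac_isoform_divergent=0.4)
ds = simulate_dataset(cfg)

h = hellinger_table(ds.isoforms, "kidney", "liver")
print(f"Hellinger distance across {len(h)} genes:")
print(f"  identical usage (H=0): {(h == 0).sum()} genes")
print(f"  diverged (H>0.3):      {(h > 0.3).sum()} genes")
print(f"  median H among multi-isoform diverged genes: "
      f"{h[h > 0].median():.3f}")

feats = feature_table(ds.annotation, ds.sequences)
print(f"\ntranscript features ({len(feats)} transcripts):")
print(feats[["length", "utr5_len", "cds_len", "gc", "kozak_score"]]
      .describe().loc[["mean", "min", "max"]].round(2).to_string())
print("(random start-codon contexts average a Kozak score around 3; "
      "the consensus scores 13)")
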