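"""Config-driven end-to-end run: simulate -> quantify -> differential TE /
compensation -> rhythms -> phase lags -> uORFs -> isoform divergence ->
clustering, with a reproducible run manifest.

The configuration is a nested mapping (or a YAML file) with a ``simulation``
section (fields of :class:`ribocycle.synthdata.SimulationConfig`) and an
optional ``thresholds`` section; every deterministic stage re-run with the
same configuration reproduces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cluster as _cluster
from . import dataio, difftrans, isodiv, quant, rhythm, ribopos, uorf
from .synthdata import SimulationConfig, simulate_dataset, simulate_footprints

log = logging.getLogger("ribocycle")

DEFAULT_THRESHOLDS = {
    "fdr": 0.01,              # differential-TE FDR cutoff
    "fold": 1.5,              # differential-TE fold cutoff
    "amplitude_fold": 1.5,    # rhythm peak-to-trough gate
    "uorf_min_len": 18,       # nt
    "uorf_coverage": 0.10,
    "uorf_alpha": 0.05,
    "screen_alpha": 0.05,
    "rpkm_pseudocount": 0.05,
}


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int
    config: dict
    thresholds: dict
    file_hashes: dict[str, str]
    stage_counts: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    cfg.setdefault("simulation", {})
    cfg["thresholds"] = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    return cfg


def run_pipeline(config: str | Path | Mapping[str, Any],
                 outdir: str | Path) -> RunManifest:
    """Run every stage on a fresh simulation and write all outputs to ``outdir``."""
    cfg = load_config(config)
    thr = cfg["thresholds"]
    sim_cfg = SimulationConfig(**cfg["simulation"])
    out = Path(outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, dict] = {}

    # --- simulate ---------------------------------------------------------
    ds = simulate_dataset(sim_cfg)
    footprints = simulate_footprints(ds.annotation, ds.truth, sim_cfg)
    for (organ, assay), cm in ds.counts.items():
        dataio.write_counts(cm, out / "inputs" / f"counts_{organ}_{assay}.tsv")
    dataio.write_annotation(ds.annotation, out / "inputs" / "annotation.tsv")
    dataio.write_fasta(ds.sequences, out / "inputs" / "transcripts.fa")
    dataio.write_footprints(footprints, out / "inputs" / "footprints.tsv")
    dataio.write_isoform_proportions(ds.isoforms,
                                     out / "inputs" / "isoform_proportions.tsv")
    ds.truth.genes.to_csv(out / "inputs" / "truth_genes.tsv", sep="\t")
    ds.truth.uorfs.to_csv(out / "inputs" / "truth_uorfs.tsv", sep="\t", index=False)
    stage_counts["simulate"] = {"genes": sim_cfg.n_genes,
                                "footprints": int(len(footprints))}

    # --- quantify ---------------------------------------------------------
    organs = sim_cfg.organs
    rpkm_tables: dict[tuple[str, str], pd.DataFrame] = {}
    norm_by_class = {}
    for key, cm in ds.counts.items():
        norm = quant.upper_quartile_factors(cm)
        norm_by_class[key] = norm
        rpkm_tables[key] = quant.rpkm(cm, cm.lengths["cds_len"],
                                      norm.effective_sizes)
    te_tables = {o: quant.translation_efficiency(rpkm_tables[(o, "RPF")],
                                                 rpkm_tables[(o, "RNA")])
                 for o in organs}
    for (o, a), tab in rpkm_tables.items():
        tab.to_csv(out / f"rpkm_{o}_{a}.tsv", sep="\t")
    for o, tab in te_tables.items():
        tab.to_csv(out / f"te_{o}.tsv", sep="\t")
    normalized = {key: quant.normalized_counts(ds.counts[key].counts, norm)
                  for key, norm in norm_by_class.items()}
    me = quant.measurement_error(normalized)
    me.to_csv(out / "measurement_error.tsv", sep="\t", index=False)
    stage_counts["quantify"] = {"genes": int(len(next(iter(rpkm_tables.values()))))}

    # --- differential TE and compensation --------------------------------
    dte = difftrans.differential_te(te_tables[organs[0]], te_tables[organs[1]],
                                    fdr=thr["fdr"], fold=thr["fold"],
                                    organ_a=organs[0], organ_b=organs[1])
    dte.to_csv(out / "differential_te.tsv", sep="\t")
    comp = difftrans.compensation_test(
        rpkm_tables[(organs[0], "RNA")], rpkm_tables[(organs[1], "RNA")],
        rpkm_tables[(organs[0], "RPF")], rpkm_tables[(organs[1], "RPF")])
    (out / "compensation.json").write_text(json.dumps({
        "mean_rho_rna": comp.mean_rho_rna, "mean_rho_rpf": comp.mean_rho_rpf,
        "t": comp.t, "p": comp.p, "rpf_more_similar": comp.rpf_more_similar,
    }, indent=2) + "\n")
    stage_counts["dte"] = {"genes": int(len(dte)),
                           "differential": int(dte["differential"].sum())}

    # --- rhythms ----------------------------------------------------------
    fits: dict[tuple[str, str], pd.DataFrame] = {}
    for key, tab in rpkm_tables.items():
        f = rhythm.call_rhythms(tab, amplitude_cutoff=thr["amplitude_fold"],
                                pseudocount=thr["rpkm_pseudocount"])
        fits[key] = f
        f.to_csv(out / f"rhythms_{key[0]}_{key[1]}.tsv", sep="\t")
    sets = rhythm.rhythmic_gene_sets(
        {f"{o}_{a}": f for (o, a), f in fits.items()})
    stage_counts["rhythms"] = {name: len(s) for name, s in sets.items()}

    # --- phase lags -------------------------------------------------------
    lag_summary: dict[str, Any] = {}
    deltas = {}
    for o in organs:
        pd_table = rhythm.phase_differences(fits[(o, "RPF")], fits[(o, "RNA")])
        pd_table.to_csv(out / f"phase_differences_{o}.tsv", sep="\t")
        deltas[o] = pd_table["delta_h"].to_numpy()
        lag_summary[o] = {"n": int(len(pd_table)),
                          "mean_delta_h": (float(np.mean(deltas[o]))
                                           if len(pd_table) else None)}
    if all(len(deltas[o]) > 0 for o in organs):
        lag_summary["permutation_p"] = rhythm.permutation_test_distributions(
            deltas[organs[0]], deltas[organs[1]],
            n_perm=1000, seed=sim_cfg.seed)
    phases = [fits[(o, "RPF")].loc[fits[(o, "RPF")]["rhythmic"], "phase_h"]
              .to_numpy() for o in organs]
    if all(p.size >= 10 for p in phases):
        lag_summary["watson_wheeler"] = rhythm.watson_wheeler(phases)
    both = sorted(set.intersection(*[
        sets[f"{o}_RNA&{o}_RPF"] if f"{o}_RNA&{o}_RPF" in sets
        else sets[f"{o}_RPF&{o}_RNA"] for o in organs])) if organs else []
    ccf = {}
    for o in organs:
        if not both:
            break
        x = rhythm.replicate_mean_profile(
            np.log2(rpkm_tables[(o, "RPF")].loc[both] + thr["rpkm_pseudocount"]))
        y = rhythm.replicate_mean_profile(
            np.log2(rpkm_tables[(o, "RNA")].loc[both] + thr["rpkm_pseudocount"]))
        lc = rhythm.cross_correlate(x.mean(axis=0).to_numpy(),
                                    y.mean(axis=0).to_numpy())
        ccf[o] = {"lags_h": lc.lags_h.tolist(), "r": lc.r.tolist(),
                  "best_lag_h": lc.best_lag_h}
    lag_summary["cross_correlation"] = ccf
    (out / "lags.json").write_text(json.dumps(lag_summary, indent=2) + "\n")
    stage_counts["lags"] = {o: lag_summary[o]["n"] for o in organs}

    # --- translation-only screen -----------------------------------------
    screens = {}
    for o in organs:
        scr = rhythm.translation_only_screen(
            fits[(o, "RNA")], fits[(o, "RPF")], te_tables[o],
            alpha=thr["screen_alpha"], amplitude_cutoff=thr["amplitude_fold"])
        scr.to_csv(out / f"translation_only_{o}.tsv", sep="\t")
        screens[o] = int(scr["translation_only"].sum())
    stage_counts["translation_only"] = screens

    # --- uORFs ------------------------------------------------------------
    tlen = {t: a.length for t, a in ds.annotation.items()}
    asites = ribopos.a_site_positions(footprints, tlen)
    records = []
    for tid, ann in sorted(ds.annotation.items()):
        cands = uorf.detect_uorfs(ds.sequences[tid], ann,
                                  min_len=thr["uorf_min_len"])
        for rec in uorf.merge_composites(cands):
            if tid in asites:
                rec = uorf.call_translated(rec, asites[tid],
                                           alpha=thr["uorf_alpha"],
                                           min_coverage=thr["uorf_coverage"])
            records.append(rec)
    if records:
        uorf.records_to_frame(records).to_csv(out / "uorfs.tsv", sep="\t",
                                              index=False)
        dataio.write_bed6(uorf.records_to_bed6(records), out / "uorfs.bed")
    stage_counts["uorfs"] = {
        "candidates": len(records),
        "translated": sum(1 for r in records if r.translated),
    }

    # --- isoform divergence ----------------------------------------------
    hell = isodiv.hellinger_table(ds.isoforms, organs[0], organs[1])
    hell.to_csv(out / "hellinger.tsv", sep="\t", header=True)
    feats = isodiv.feature_table(ds.annotation, ds.sequences)
    feats.to_csv(out / "features.tsv", sep="\t")
    stage_counts["isodiv"] = {"genes": int(len(hell))}

    # --- clustering -------------------------------------------------------
    cluster_genes = both or sorted(
        fits[(organs[0], "RNA")]["fold"].nlargest(20).index)
    mats = []
    for g in cluster_genes:
        profiles_df = pd.DataFrame({
            f"{o}_{a}": rhythm.replicate_mean_profile(
                np.log2(rpkm_tables[(o, a)].loc[[g]]
                        + thr["rpkm_pseudocount"])).iloc[0]
            for o in organs for a in ("RNA", "RPF")
        }).T
        mats.append(_cluster.profile_dissimilarity(profiles_df))
    newick = None
    if mats:
        fused = _cluster.fuse(mats)
        fused.to_csv(out / "fused_dissimilarity.tsv", sep="\t")
        Z, labels = _cluster.hcluster(fused)
        newick = _cluster.to_newick(Z, labels)
        (out / "profiles.nwk").write_text(newick + "\n")
    stage_counts["cluster"] = {"genes": len(mats)}

    # --- manifest ---------------------------------------------------------
    hashes = {str(p.relative_to(out)): _sha256(p)
              for p in sorted(out.rglob("*")) if p.is_file()}
    manifest = RunManifest(
        version=__version__, seed=sim_cfg.seed,
        config={"simulation": dataclasses.asdict(sim_cfg)},
        thresholds=dict(thr), file_hashes=hashes, stage_counts=stage_counts)
    manifest.to_json(out / "manifest.json")
    return manifest
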