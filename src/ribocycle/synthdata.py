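"""Synthetic around-the-clock dual-organ translatome datasets with ground truth.

The generator emulates the study design of a two-organ (kidney, liver)
ribosome-profiling time course: 12 Zeitgeber timepoints in 2-h steps, two
replicates, RPF-seq and RNA-seq per organ (96 libraries in the full design).
It plants, per gene, cross-organ mRNA-abundance and translation-efficiency
log-ratios (with a configurable negative correlation between them emulating
translational compensation), 24-h cosine rhythms in RNA abundance and/or TE
with known phases and amplitudes, organ-specific RPF-before-RNA phase lags,
negative-binomial count noise, 3-periodic footprint placement, and AUG-
initiated uORFs in 5'UTRs — all recorded in a ground-truth table so every
downstream stage can be validated against what was planted.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import (ConfigError, CountMatrix, SampleKey, TranscriptAnnotation)
from .ribopos import DEFAULT_OFFSETS

log = logging.getLogger("ribocycle")

# uORF interior codons use only A/C so the planted AUG and stop are the only
# start/stop signals in the planted span (no ATG or stop can form anywhere,
# including across codon boundaries)
_SAFE_CODONS = ("AAA", "AAC", "ACA", "ACC", "CAA", "CAC", "CCA", "CCC")


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the two-organ around-the-clock design: 12 timepoints in
    duplicate per organ and assay, wide cross-organ mRNA differences with a
    much narrower TE spread, a minority of rhythmic genes, and footprints
    with a dominant reading frame.
    """

    seed: int = 0
    n_genes: int = 1000
    timepoints: tuple[int, ...] = tuple(range(0, 24, 2))
    n_replicates: int = 2
    organs: tuple[str, str] = ("kidney", "liver")
    baseline_log_mean: float = 5.0    # log2 RPKM-scale gene baseline
    baseline_log_sd: float = 2.0
    rna_organ_lfc_sd: float = 2.0     # spread of cross-organ RNA log2 ratios
    te_organ_lfc_sd: float = 0.5      # spread of cross-organ TE log2 ratios
    te_baseline_sd: float = 0.3
    compensation_rho: float = -0.4    # corr(RNA organ-ratio, TE organ-ratio)
    frac_rhythmic_rna: float = 0.10
    frac_rhythmic_te: float = 0.05
    amplitude_range_log2: tuple[float, float] = (0.3, 1.0)
    phase_lag_mean_h: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"kidney": -2.0, "liver": -0.5})
    phase_lag_sd_h: float = 0.5
    nb_dispersion: float = 0.05
    frac_uorf_genes: float = 0.2
    frac_multi_isoform: float = 0.4
    frac_isoform_divergent: float = 0.3
    library_size_range: tuple[float, float] = (8e6, 12e6)
    # footprint simulation
    f_frame: float = 0.85             # fraction of A-sites in frame 0
    cds_reads_per_transcript: int = 200
    uorf_reads_translated: int = 300
    uorf_reads_untranslated: int = 30

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        tps = tuple(self.timepoints)
        if any(not 0 <= t < 24 for t in tps) or any(
                b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigError(
                "timepoints must be strictly increasing within [0, 24)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(self.organs) != 2 or len(set(self.organs)) != 2:
            raise ConfigError("organs must be 2 distinct labels")
        for field in ("frac_rhythmic_rna", "frac_rhythmic_te",
                      "frac_uorf_genes", "frac_multi_isoform",
                      "frac_isoform_divergent", "f_frame"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{field} must lie in [0, 1], got {v}")
        if not -1.0 <= self.compensation_rho <= 0.0:
            raise ConfigError("compensation_rho must lie in [-1, 0]")
        if self.frac_rhythmic_rna + self.frac_rhythmic_te > 1.0:
            raise ConfigError(
                "frac_rhythmic_rna + frac_rhythmic_te must not exceed 1")
        lo, hi = self.amplitude_range_log2
        if not 0 <= lo <= hi:
            raise ConfigError("amplitude_range_log2 must be an interval >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ConfigError("library_size_range must be a positive interval")
        for o in self.organs:
            if o not in self.phase_lag_mean_h:
                raise ConfigError(f"phase_lag_mean_h missing organ {o!r}")


@dataclasses.dataclass
class GroundTruth:
    """Planted per-gene parameters plus uORF and isoform truth tables."""

    genes: pd.DataFrame     # per-gene planted parameters (indexed by gene id)
    uorfs: pd.DataFrame     # transcript_id, start, end, translated
    isoforms: pd.DataFrame  # gene_id, isoform_id, one proportion col per organ


@dataclasses.dataclass
class SimulatedDataset:
    config: SimulationConfig
    counts: dict[tuple[str, str], CountMatrix]  # (organ, assay) -> matrix
    truth: GroundTruth
    annotation: dict[str, TranscriptAnnotation]
    sequences: dict[str, str]
    isoforms: pd.DataFrame


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2.

    dispersion == 0 is noise-free: counts are the rounded means.
    """
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _plant_sequences(rng: np.random.Generator, cfg: SimulationConfig,
                     gene_ids: list[str], transcript_ids: list[str],
                     ) -> tuple[dict[str, TranscriptAnnotation],
                                dict[str, str], pd.DataFrame]:
    annotation: dict[str, TranscriptAnnotation] = {}
    sequences: dict[str, str] = {}
    uorf_rows = []
    n_uorf = int(round(cfg.frac_uorf_genes * cfg.n_genes))
    uorf_genes = set(rng.choice(cfg.n_genes, size=n_uorf, replace=False).tolist())
    for gi, (gid, tid) in enumerate(zip(gene_ids, transcript_ids)):
        utr5 = int(rng.integers(60, 301))
        cds = int(rng.integers(100, 601)) * 3
        utr3 = int(rng.integers(90, 501))
        length = utr5 + cds + utr3
        seq = rng.choice(list("ACGT"), size=length)
        # remove accidental AUGs from the 5'UTR so planted uORFs are the only ones
        utr = seq[:utr5]
        for s in range(utr5 - 2):
            if utr[s] == "A" and utr[s + 1] == "T" and utr[s + 2] == "G":
                utr[s] = "C"
        seq[:utr5] = utr
        seq[utr5:utr5 + 3] = list("ATG")
        seq[utr5 + cds - 3:utr5 + cds] = list("TAA")
        if gi in uorf_genes:
            n_codons = int(rng.integers(5, 11))  # coding span 18..33 nt
            span = 3 * (n_codons + 1)
            start = int(rng.integers(16, utr5 - span - 3 + 1))
            body = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
            insert = "ATG" + "".join(_SAFE_CODONS[i] for i in body) + "TAA"
            seq[start:start + span + 3] = list(insert)
            uorf_rows.append({
                "transcript_id": tid, "start": start, "end": start + span,
                "translated": bool(rng.random() < 0.5),
            })
        sequences[tid] = "".join(seq)
        annotation[tid] = TranscriptAnnotation(
            transcript_id=tid, gene_id=gid,
            utr5=(0, utr5), cds=(utr5, utr5 + cds),
            utr3=(utr5 + cds, length), protein_coding=True,
        )
    uorfs = pd.DataFrame(uorf_rows,
                         columns=["transcript_id", "start", "end", "translated"])
    return annotation, sequences, uorfs


def _plant_isoforms(rng: np.random.Generator, cfg: SimulationConfig,
                    gene_ids: list[str]) -> pd.DataFrame:
    rows = []
    for gid in gene_ids:
        multi = rng.random() < cfg.frac_multi_isoform
        n_iso = int(rng.integers(2, 4)) if multi else 1
        if n_iso == 1:
            props = {o: np.array([1.0]) for o in cfg.organs}
        else:
            base = rng.dirichlet(np.ones(n_iso) * 2.0)
            if rng.random() < cfg.frac_isoform_divergent:
                other = rng.dirichlet(np.ones(n_iso) * 2.0)
            else:
                other = base.copy()
            props = {cfg.organs[0]: base, cfg.organs[1]: other}
        for i in range(n_iso):
            row = {"gene_id": gid, "isoform_id": f"{gid}.iso{i + 1}"}
            for o in cfg.organs:
                row[o] = float(props[o][i])
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate counts, annotation, sequences, isoforms and ground truth.

    Per gene g, organ o, assay a and time t the expected count is
    L_j * 2^(m_g + organ/assay shifts + A*cos(2*pi*(t - phi)/24)) * len_g,
    rescaled to the library size L_j; counts are negative-binomial. RPF means
    equal RNA means times TE, with TE organ-ratios correlated to RNA
    organ-ratios at ``compensation_rho``, and planted RPF rhythms lag RNA
    rhythms by an organ-specific number of hours.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    transcript_ids = [f"t{i:0{width}d}" for i in range(cfg.n_genes)]

    annotation, sequences, uorfs = _plant_sequences(
        rng, cfg, gene_ids, transcript_ids)
    cds_len = np.array([annotation[t].cds_len for t in transcript_ids])
    lengths = pd.DataFrame(
        {"utr5_len": [annotation[t].utr5[1] for t in transcript_ids],
         "cds_len": cds_len,
         "utr3_len": [annotation[t].utr3[1] - annotation[t].utr3[0]
                      for t in transcript_ids]},
        index=pd.Index(gene_ids, name="gene_id"))

    n = cfg.n_genes
    m = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n)
    d = rng.normal(0.0, cfg.rna_organ_lfc_sd, n)       # RNA organ log2 ratio
    z = rng.normal(0.0, 1.0, n)
    rho = cfg.compensation_rho
    if cfg.rna_organ_lfc_sd > 0:
        e = (rho * cfg.te_organ_lfc_sd / cfg.rna_organ_lfc_sd * d
             + np.sqrt(max(0.0, 1 - rho ** 2)) * cfg.te_organ_lfc_sd * z)
    else:
        e = cfg.te_organ_lfc_sd * z
    te0 = rng.normal(0.0, cfg.te_baseline_sd, n)

    n_rna = int(round(cfg.frac_rhythmic_rna * n))
    n_te = int(round(cfg.frac_rhythmic_te * n))
    order = rng.permutation(n)
    rna_rhythmic = np.zeros(n, dtype=bool)
    te_rhythmic = np.zeros(n, dtype=bool)
    rna_rhythmic[order[:n_rna]] = True
    te_rhythmic[order[n_rna:n_rna + n_te]] = True
    lo, hi = cfg.amplitude_range_log2
    amp = np.where(rna_rhythmic, rng.uniform(lo, hi, n), 0.0)
    phase = rng.uniform(0.0, 24.0, n)
    te_amp = np.where(te_rhythmic, rng.uniform(lo, hi, n), 0.0)
    te_phase = rng.uniform(0.0, 24.0, n)
    lags = {o: rng.normal(cfg.phase_lag_mean_h[o], cfg.phase_lag_sd_h, n)
            for o in cfg.organs}

    w = 2.0 * np.pi / 24.0
    counts: dict[tuple[str, str], CountMatrix] = {}
    organ_sign = {cfg.organs[0]: +0.5, cfg.organs[1]: -0.5}
    for organ in cfg.organs:
        s = organ_sign[organ]
        for assay in ("RNA", "RPF"):
            cols = {}
            for tp in cfg.timepoints:
                for rep in range(1, cfg.n_replicates + 1):
                    mu_log2 = m + s * d
                    mu_log2 = mu_log2 + np.where(
                        rna_rhythmic,
                        amp * np.cos(w * (tp - phase
                                          - (lags[organ] if assay == "RPF" else 0.0))),
                        0.0)
                    if assay == "RPF":
                        mu_log2 = mu_log2 + te0 + s * e
                        mu_log2 = mu_log2 + np.where(
                            te_rhythmic,
                            te_amp * np.cos(w * (tp - te_phase)), 0.0)
                    intensity = (2.0 ** mu_log2) * (cds_len / 1000.0)
                    lib_size = rng.uniform(*cfg.library_size_range)
                    mu = lib_size * intensity / intensity.sum()
                    key = SampleKey(organ, assay, tp, rep)
                    cols[key.column] = _nb_counts(rng, mu, cfg.nb_dispersion)
            counts[(organ, assay)] = CountMatrix(
                counts=pd.DataFrame(cols, index=lengths.index),
                lengths=lengths)

    isoforms = _plant_isoforms(rng, cfg, gene_ids)
    genes = pd.DataFrame({
        "transcript_id": transcript_ids,
        "baseline_log2": m,
        "rna_organ_lfc": d,
        "te_organ_lfc": e,
        "te_baseline": te0,
        "rhythmic_rna": rna_rhythmic,
        "rhythmic_te": te_rhythmic,
        "amp_log2": amp,
        "phase_h": phase,
        "te_amp_log2": te_amp,
        "te_phase_h": te_phase,
        **{f"lag_{o}_h": np.where(rna_rhythmic, lags[o], np.nan)
           for o in cfg.organs},
    }, index=pd.Index(gene_ids, name="gene_id"))

    truth = GroundTruth(genes=genes, uorfs=uorfs, isoforms=isoforms)
    log.info("simulate_dataset: %d genes, %d rhythmic RNA, %d rhythmic TE, "
             "%d uORF genes", n, n_rna, n_te, len(uorfs))
    return SimulatedDataset(config=cfg, counts=counts, truth=truth,
                            annotation=annotation, sequences=sequences,
                            isoforms=isoforms)


def simulate_footprints(annotation: Mapping[str, TranscriptAnnotation],
                        truth: GroundTruth,
                        config: SimulationConfig) -> pd.DataFrame:
    """Place ribosome footprints on transcripts with a planted reading frame.

    Footprints of 26-35 nt are positioned so that, after A-site offsetting
    with the default offset table, a fraction ``f_frame`` of CDS A-sites (and
    of A-sites on planted translated uORFs) fall in frame 0 of the unit's
    start codon; planted non-translated uORFs receive frame-uniform coverage.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    lengths = sorted(DEFAULT_OFFSETS)
    uorfs_by_tid: dict[str, list] = {}
    for row in truth.uorfs.itertuples(index=False):
        uorfs_by_tid.setdefault(row.transcript_id, []).append(row)

    rows_tid: list[str] = []
    rows_pos: list[np.ndarray] = []
    rows_len: list[np.ndarray] = []

    def emit(tid: str, a_sites: np.ndarray) -> None:
        read_len = rng.choice(lengths, size=a_sites.size)
        offset = np.array([DEFAULT_OFFSETS[l] for l in read_len])
        five_prime = a_sites - offset
        tlen = annotation[tid].length
        ok = (five_prime >= 0) & (five_prime + read_len <= tlen)
        rows_tid.extend([tid] * int(ok.sum()))
        rows_pos.append(five_prime[ok])
        rows_len.append(read_len[ok])

    def framed_positions(start: int, n_codons: int, n_reads: int,
                         f_frame: float) -> np.ndarray:
        codon = rng.integers(0, n_codons, size=n_reads)
        framed = rng.random(n_reads) < f_frame
        shift = np.where(framed, 0, rng.integers(1, 3, size=n_reads))
        return start + 3 * codon + shift

    for tid in sorted(annotation):
        ann = annotation[tid]
        cds_start, cds_end = ann.cds
        n_codons = (cds_end - cds_start) // 3
        if n_codons < 1:
            raise ConfigError(f"{tid}: CDS shorter than one codon")
        emit(tid, framed_positions(cds_start, n_codons,
                                   cfg.cds_reads_per_transcript, cfg.f_frame))
        for u in uorfs_by_tid.get(tid, []):
            span_codons = (u.end - u.start) // 3
            if u.translated:
                emit(tid, framed_positions(u.start, span_codons,
                                           cfg.uorf_reads_translated,
                                           cfg.f_frame))
            else:
                pos = rng.integers(u.start, u.end,
                                   size=cfg.uorf_reads_untranslated)
                emit(tid, pos)

    out = pd.DataFrame({
        "transcript_id": rows_tid,
        "five_prime_pos": np.concatenate(rows_pos) if rows_pos else [],
        "read_length": np.concatenate(rows_len) if rows_len else [],
    })
    log.info("simulate_footprints: %d reads on %d transcripts",
             len(out), out["transcript_id"].nunique())
    return out
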