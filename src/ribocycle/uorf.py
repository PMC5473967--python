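"""Upstream ORF detection, composite merging, translation calling and uORF TE.

Candidate uORFs start at any AUG whose codon lies fully within the 5'UTR and
run to the first in-frame stop codon; candidates shorter than 18 nt (AUG
through the last codon before the stop) are discarded. uORFs that run into
the CDS in the same frame are dropped entirely; out-of-frame CDS overlaps are
kept but only the 5'UTR-specific part of the span is counted. Overlapping
uORFs on one 5'UTR are merged into a single composite counting unit.

A (composite) uORF is called translated when its A-sites show a significant
bias towards the reading frame of its start codon (one-sided exact binomial
against the uniform rate 1/3) and more than 10% of countable positions are
covered.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import TranscriptAnnotation, ValidationError, normalize_sequence
from .ribopos import ASiteProfile

log = logging.getLogger("ribocycle")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
MIN_UORF_LEN = 18


@dataclasses.dataclass
class UORFRecord:
    """One (possibly composite) upstream ORF on a transcript.

    ``start``/``end`` delimit the coding span (AUG through the last nt before
    the stop codon, 0-based half-open); the countable span is the 5'UTR-
    specific part used for read counting.
    """

    transcript_id: str
    start: int
    end: int
    frame: int                    # start position mod 3, relative to transcript
    cds_overlap: str              # none | out-of-frame | in-frame
    countable_start: int
    countable_end: int
    composite: bool = False
    translated: bool | None = None
    frame_bias_p: float | None = None
    coverage: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_uorfs(sequence: str, annotation: TranscriptAnnotation,
                 min_len: int = MIN_UORF_LEN) -> list[UORFRecord]:
    """Scan a transcript's 5'UTR for AUG-initiated uORFs.

    Every AUG whose codon lies within the 5'UTR opens a candidate; the span
    runs to the first in-frame stop codon (which may sit inside the CDS or
    3'UTR). Candidates with a coding span < ``min_len`` nt are discarded;
    candidates overlapping the CDS in the same frame are dropped; out-of-frame
    overlaps are clipped to their 5'UTR-specific countable span.
    """
    seq = normalize_sequence(sequence)
    if len(seq) != annotation.length:
        raise ValidationError(
            f"{annotation.transcript_id}: sequence length {len(seq)} != "
            f"annotated length {annotation.length}"
        )
    cds_start = annotation.cds[0]
    records: list[UORFRecord] = []
    for s in range(cds_start - 2):
        if seq[s:s + 3] != "ATG":
            continue
        end = None
        p = s + 3
        while p + 3 <= len(seq):
            if seq[p:p + 3] in STOP_CODONS:
                end = p
                break
            p += 3
        if end is None:
            end = p  # ran off the transcript without an in-frame stop
        if end - s < min_len:
            continue
        if end <= cds_start:
            overlap = "none"
        elif (cds_start - s) % 3 == 0:
            continue  # in-frame extension of the CDS, not a uORF
        else:
            overlap = "out-of-frame"
        records.append(UORFRecord(
            transcript_id=annotation.transcript_id,
            start=s, end=end, frame=s % 3, cds_overlap=overlap,
            countable_start=s, countable_end=min(end, cds_start),
        ))
    return records


def merge_composites(candidates: Sequence[UORFRecord]) -> list[UORFRecord]:
    """Merge overlapping uORF spans on one transcript into composite units.

    The composite span is the union of the overlapping coding spans; its
    reading frame is that of the 5'-most start codon and its countable span
    is the union clipped at the CDS. Disjoint candidates pass through
    unchanged.
    """
    if not candidates:
        return []
    tids = {r.transcript_id for r in candidates}
    if len(tids) > 1:
        raise ValidationError(f"candidates span multiple transcripts: {sorted(tids)}")
    ordered = sorted(candidates, key=lambda r: (r.start, r.end))
    merged: list[list[UORFRecord]] = [[ordered[0]]]
    for rec in ordered[1:]:
        cluster_end = max(r.end for r in merged[-1])
        if rec.start < cluster_end:
            merged[-1].append(rec)
        else:
            merged.append([rec])
    out = []
    for cluster in merged:
        if len(cluster) == 1:
            out.append(dataclasses.replace(cluster[0], composite=False))
            continue
        first = cluster[0]
        end = max(r.end for r in cluster)
        overlap = ("out-of-frame"
                   if any(r.cds_overlap == "out-of-frame" for r in cluster)
                   else "none")
        countable_end = min(max(r.countable_end for r in cluster), end)
        out.append(UORFRecord(
            transcript_id=first.transcript_id, start=first.start, end=end,
            frame=first.frame, cds_overlap=overlap,
            countable_start=first.start, countable_end=countable_end,
            composite=True,
        ))
    return out


def call_translated(record: UORFRecord, profile: ASiteProfile,
                    alpha: float = 0.05, min_coverage: float = 0.10,
                    codon_resolution: bool = False) -> UORFRecord:
    """Decide whether a uORF is translated from A-site frame bias and coverage.

    Over the countable span, the one-sided exact binomial tail probability of
    observing the A-sites in the uORF's frame at the uniform null rate 1/3 is
    the frame-bias p; coverage is the fraction of countable positions (or
    codons with ``codon_resolution``) holding at least one A-site. Translated
    requires frame_bias_p < ``alpha`` and coverage > ``min_coverage``. With
    zero A-sites the record is flagged not translated with undefined p.
    """
    if profile.transcript_id != record.transcript_id:
        raise ValidationError("profile transcript does not match the record")
    cs, ce = record.countable_start, record.countable_end
    window = profile.counts[cs:ce]
    n = int(window.sum())
    pos = np.arange(cs, ce)
    in_frame = (pos - record.start) % 3 == 0
    if codon_resolution:
        codon_idx = (pos - record.start) // 3
        covered = {int(c) for c, v in zip(codon_idx, window) if v > 0}
        coverage = len(covered) / max(1, codon_idx.max() + 1)
    else:
        coverage = float((window > 0).mean()) if window.size else 0.0
    if n == 0:
        log.debug("call_translated: %s:%d-%d has no A-sites",
                  record.transcript_id, record.start, record.end)
        return dataclasses.replace(record, translated=False,
                                   frame_bias_p=None, coverage=coverage)
    k = int(window[in_frame].sum())
    p = float(stats.binom.sf(k - 1, n, 1.0 / 3.0))
    translated = (p < alpha) and (coverage > min_coverage)
    return dataclasses.replace(record, translated=translated,
                               frame_bias_p=p, coverage=coverage)


def uorf_te(rpf_counts: pd.Series, rna_counts: pd.Series,
            effective_sizes_rpf: pd.Series,
            effective_sizes_rna: pd.Series) -> pd.Series:
    """Per-sample uORF TE = depth-normalized RPF over RNA counts on the span.

    Counts are per-sample reads whose A-sites fall in the countable span; the
    span length cancels in the ratio. TE is missing where the RNA count is 0.
    Series are matched on (organ, timepoint, replicate) column keys.
    """
    from .dataio import parse_sample_columns  # local to avoid cycle confusion

    def keyed(series: pd.Series) -> dict[tuple, float]:
        return {(k.organ, k.timepoint, k.replicate): series[k.column]
                for k in parse_sample_columns(series.index)}

    rpf = keyed(rpf_counts)
    rna = keyed(rna_counts)
    eff_rpf = keyed(effective_sizes_rpf)
    eff_rna = keyed(effective_sizes_rna)
    shared = sorted(set(rpf) & set(rna))
    out = {}
    for s in shared:
        organ, tp, rep = s
        label = f"{organ}_TE_ZT{tp:02d}_rep{rep}"
        if rna[s] == 0:
            out[label] = np.nan
        else:
            out[label] = ((rpf[s] / eff_rpf[s] * 1e6)
                          / (rna[s] / eff_rna[s] * 1e6))
    return pd.Series(out)


def uorf_vs_cds_ratio_table(uorf_te_ratio: pd.Series,
                            cds_te_ratio: pd.Series) -> pd.DataFrame:
    """Join per-gene cross-organ TE ratios of uORFs and their main CDS.

    Input series are indexed by gene and hold the kidney/liver (organ A over
    organ B) TE ratio of the translated uORF and of the CDS. The returned
    table carries one row per gene present in both inputs; the Pearson
    correlation of the log ratios is attached as ``.attrs['pearson_r']``.
    """
    genes = uorf_te_ratio.index.intersection(cds_te_ratio.index)
    if len(genes) == 0:
        raise ValidationError("no genes with both uORF and CDS TE ratios")
    out = pd.DataFrame({"uorf_te_ratio": uorf_te_ratio[genes],
                        "cds_te_ratio": cds_te_ratio[genes]})
    if len(genes) >= 2:
        r = float(np.corrcoef(np.log(out["uorf_te_ratio"]),
                              np.log(out["cds_te_ratio"]))[0, 1])
    else:
        r = np.nan
    out.attrs["pearson_r"] = r
    return out


def records_to_frame(records: Iterable[UORFRecord]) -> pd.DataFrame:
    """Flatten uORF records into a table (one row per record)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def records_to_bed6(records: Iterable[UORFRecord]) -> pd.DataFrame:
    """BED6 rows: transcript, span, uORF id, score = -log10 frame-bias p."""
    rows = []
    for i, r in enumerate(records):
        score = (0.0 if r.frame_bias_p is None or r.frame_bias_p <= 0
                 else -np.log10(r.frame_bias_p))
        rows.append((r.transcript_id, r.start, r.end,
                     f"uORF_{r.transcript_id}_{i}", round(float(score), 3), "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "name", "score", "strand"])
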