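"""A-site offsetting, reading-frame statistics and metagene profiles.

The A-site of a ribosome-protected fragment is inferred from its 5' end plus a
read-length-dependent offset. Frame statistics count A-sites per reading frame
relative to a unit's start codon (frame 0 = the start codon's frame).
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataio import TranscriptAnnotation, ValidationError

log = logging.getLogger("ribocycle")

#: default 5'-end -> A-site offsets (nt) per read length
DEFAULT_OFFSETS: dict[int, int] = {
    **{n: 14 for n in range(26, 31)},
    **{n: 15 for n in range(31, 36)},
}


@dataclasses.dataclass
class ASiteProfile:
    """Per-position A-site counts on one transcript."""

    transcript_id: str
    counts: np.ndarray          # length = transcript length
    offsets: Mapping[int, int]  # offset table used

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class FrameStats:
    """A-site counts per reading frame relative to a unit's start codon."""

    unit_id: str
    counts: np.ndarray  # (f0, f1, f2)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray | None:
        """Frame fractions, or None when the unit holds no A-sites."""
        if self.total == 0:
            return None
        return self.counts / self.total


def a_site_positions(footprints: pd.DataFrame,
                     transcript_lengths: Mapping[str, int],
                     offsets: Mapping[int, int] = DEFAULT_OFFSETS,
                     ) -> dict[str, ASiteProfile]:
    """Map footprint 5' ends to A-site positional histograms per transcript.

    Reads whose length is absent from the offset table, or whose offset A-site
    falls outside the transcript, are dropped and logged.
    """
    profiles: dict[str, ASiteProfile] = {}
    n_dropped = 0
    off = footprints["read_length"].map(offsets)
    known = off.notna()
    n_dropped += int((~known).sum())
    fp = footprints.loc[known]
    a_pos = (fp["five_prime_pos"] + off[known]).astype(int)
    for tid, group in a_pos.groupby(fp["transcript_id"], sort=True):
        tlen = transcript_lengths[tid]
        pos = group.to_numpy()
        inside = (pos >= 0) & (pos < tlen)
        n_dropped += int((~inside).sum())
        counts = np.bincount(pos[inside], minlength=tlen).astype(np.int64)
        profiles[tid] = ASiteProfile(tid, counts, dict(offsets))
    if n_dropped:
        log.info("a_site_positions: dropped %d reads (unknown length or "
                 "out-of-transcript A-site)", n_dropped)
    return profiles


def frame_stats(profile: ASiteProfile,
                unit: tuple[int, int],
                unit_id: str | None = None) -> FrameStats:
    """Count A-sites per frame within ``unit`` = (start, end), frame origin at start."""
    start, end = unit
    if not 0 <= start < end <= len(profile.counts):
        raise ValidationError(
            f"unit {unit} outside transcript {profile.transcript_id}"
        )
    window = profile.counts[start:end]
    frames = (np.arange(start, end) - start) % 3
    counts = np.array([int(window[frames == f].sum()) for f in range(3)])
    stats = FrameStats(unit_id or profile.transcript_id, counts)
    if stats.total == 0:
        log.debug("frame_stats: unit %s has no A-sites", stats.unit_id)
    return stats


def metagene(profiles: Mapping[str, ASiteProfile],
             annotations: Mapping[str, TranscriptAnnotation],
             window_nt: int = 60,
             rpkm: Mapping[str, float] | None = None,
             min_rpkm: float = 5.0,
             min_cds_nt: int = 400) -> dict[str, np.ndarray]:
    """Mean A-site density around the start and stop codons.

    Transcripts qualify when their CDS exceeds ``min_cds_nt`` and (if ``rpkm``
    is given) their mean RPF RPKM exceeds ``min_rpkm``. Each transcript's
    window is scaled to mean 1 before averaging so genes contribute equally.
    Returns arrays over offsets -window_nt..+window_nt ("start" is anchored at
    the first CDS nucleotide, "stop" at the first nucleotide after the CDS).
    """
    rel = np.arange(-window_nt, window_nt + 1)
    sums = {"start": np.zeros(rel.size), "stop": np.zeros(rel.size)}
    nobs = {"start": np.zeros(rel.size), "stop": np.zeros(rel.size)}
    n_used = 0
    for tid, profile in profiles.items():
        ann = annotations.get(tid)
        if ann is None or ann.cds_len <= min_cds_nt:
            continue
        if rpkm is not None and rpkm.get(tid, 0.0) <= min_rpkm:
            continue
        n_used += 1
        for anchor_name, anchor in (("start", ann.cds[0]), ("stop", ann.cds[1])):
            pos = anchor + rel
            inside = (pos >= 0) & (pos < len(profile.counts))
            vals = np.full(rel.size, np.nan)
            vals[inside] = profile.counts[pos[inside]]
            mean = np.nanmean(vals)
            if not np.isfinite(mean) or mean == 0:
                continue
            vals = vals / mean
            ok = np.isfinite(vals)
            sums[anchor_name][ok] += vals[ok]
            nobs[anchor_name][ok] += 1
    if n_used == 0:
        raise ValidationError("metagene: no transcript passes the filters")
    log.info("metagene: averaged %d transcripts", n_used)
    out = {"offsets": rel.astype(float)}
    for name in ("start", "stop"):
        with np.errstate(invalid="ignore"):
            out[name] = np.where(nobs[name] > 0, sums[name] / nobs[name], np.nan)
    return out
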