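"""Validated containers and readers/writers for the pipeline's tabular formats.

All coordinates are 0-based, half-open and transcript-relative. Sample columns
follow the naming scheme ``<organ>_<assay>_ZT<hh>_rep<n>`` (e.g.
``kidney_RPF_ZT02_rep1``); the full around-the-clock design comprises
2 organs x 2 assays x 12 timepoints x 2 replicates = 96 libraries.
"""
from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("ribocycle")

#: assays accepted in sample keys; "TE" appears in derived ratio tables
ASSAYS = ("RPF", "RNA", "TE")

LENGTH_COLUMNS = ("utr5_len", "cds_len", "utr3_len")

_SAMPLE_RE = re.compile(
    r"^(?P<organ>[A-Za-z][A-Za-z0-9]*)_(?P<assay>RPF|RNA|TE)"
    r"_ZT(?P<tp>\d{2})_rep(?P<rep>\d+)$"
)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclasses.dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sequencing library: organ, assay, ZT hour, replicate."""

    organ: str
    assay: str
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if not 0 <= self.timepoint < 24:
            raise ValidationError(f"timepoint {self.timepoint} outside [0, 24)")
        if self.replicate < 1:
            raise ValidationError(f"replicate {self.replicate} must be >= 1")

    @property
    def column(self) -> str:
        return f"{self.organ}_{self.assay}_ZT{self.timepoint:02d}_rep{self.replicate}"

    @classmethod
    def from_column(cls, name: str) -> "SampleKey":
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValidationError(f"column {name!r} does not parse as a sample key")
        return cls(m["organ"], m["assay"], int(m["tp"]), int(m["rep"]))

    def with_assay(self, assay: str) -> "SampleKey":
        return dataclasses.replace(self, assay=assay)


def parse_sample_columns(columns: Iterable[str]) -> list[SampleKey]:
    return [SampleKey.from_column(c) for c in columns]


@dataclasses.dataclass
class CountMatrix:
    """Gene x sample integer count table with per-gene feature lengths.

    ``counts``: DataFrame indexed by gene id, columns parse as sample keys.
    ``lengths``: DataFrame indexed by gene id with utr5_len/cds_len/utr3_len (nt).
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        neg = self.counts.lt(0)
        if neg.any().any():
            gene = self.counts.index[neg.any(axis=1)][0]
            col = self.counts.columns[neg.loc[gene].values][0]
            raise ValidationError(f"negative count at gene {gene!r}, sample {col!r}")
        parse_sample_columns(self.counts.columns)  # raises on malformed header
        missing = [c for c in LENGTH_COLUMNS if c not in self.lengths.columns]
        if missing:
            raise ValidationError(f"lengths table missing columns {missing}")
        if not self.lengths.index.equals(self.counts.index):
            raise ValidationError("lengths index does not match counts index")
        if (self.lengths["cds_len"] <= 0).any():
            bad = self.lengths.index[self.lengths["cds_len"] <= 0][0]
            raise ValidationError(f"non-positive CDS length for gene {bad!r}")
        if (self.lengths[list(LENGTH_COLUMNS)] < 0).any().any():
            raise ValidationError("negative feature length")

    @property
    def samples(self) -> list[SampleKey]:
        return parse_sample_columns(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    length_cols = [c for c in LENGTH_COLUMNS if c in df.columns]
    if len(length_cols) != 3:
        raise ValidationError(
            f"{path}: expected length columns {LENGTH_COLUMNS}, found {length_cols}"
        )
    lengths = df[list(LENGTH_COLUMNS)].astype(int)
    counts = df.drop(columns=list(LENGTH_COLUMNS))
    if not counts.map(lambda v: float(v).is_integer()).all().all():
        raise ValidationError(f"{path}: non-integer count value")
    return CountMatrix(counts=counts.astype(np.int64), lengths=lengths)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = pd.concat([matrix.lengths, matrix.counts], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


@dataclasses.dataclass(frozen=True)
class TranscriptAnnotation:
    """Per-transcript feature layout in transcript coordinates.

    Intervals are 0-based half-open and must tile the transcript in the order
    5'UTR < CDS < 3'UTR; the CDS length must be a multiple of 3.
    """

    transcript_id: str
    gene_id: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    protein_coding: bool = True

    def __post_init__(self) -> None:
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (0 == u5[0] <= u5[1] == c[0] < c[1] == u3[0] <= u3[1]):
            raise ValidationError(
                f"{self.transcript_id}: intervals {u5}, {c}, {u3} are not "
                "contiguous and ordered 5'UTR < CDS < 3'UTR"
            )
        if (c[1] - c[0]) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {c[1] - c[0]} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.utr3[1]

    @property
    def cds_len(self) -> int:
        return self.cds[1] - self.cds[0]


_ANNOT_COLS = [
    "transcript_id", "gene_id", "utr5_start", "utr5_end",
    "cds_start", "cds_end", "utr3_start", "utr3_end", "protein_coding",
]


def read_annotation(path: str | Path) -> dict[str, TranscriptAnnotation]:
    """Read the transcript annotation table, skipping invalid transcripts.

    Transcripts whose CDS length is not a multiple of 3 (or whose intervals do
    not tile the transcript) are skipped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing annotation columns {missing}")
    out: dict[str, TranscriptAnnotation] = {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            ann = TranscriptAnnotation(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                utr5=(int(row.utr5_start), int(row.utr5_end)),
                cds=(int(row.cds_start), int(row.cds_end)),
                utr3=(int(row.utr3_start), int(row.utr3_end)),
                protein_coding=bool(row.protein_coding),
            )
        except ValidationError as exc:
            log.warning("skipping transcript: %s", exc)
            n_skipped += 1
            continue
        out[ann.transcript_id] = ann
    log.info("read %d transcripts from %s (%d skipped)", len(out), path, n_skipped)
    return out


def write_annotation(annotations: Mapping[str, TranscriptAnnotation],
                     path: str | Path) -> None:
    rows = [
        (a.transcript_id, a.gene_id, a.utr5[0], a.utr5[1], a.cds[0], a.cds[1],
         a.utr3[0], a.utr3[1], a.protein_coding)
        for a in annotations.values()
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


#: default ribosome-protected-fragment size window (nt)
RPF_LENGTH_WINDOW = (26, 35)

_FOOTPRINT_COLS = ["transcript_id", "five_prime_pos", "read_length"]


def validate_footprints(df: pd.DataFrame,
                        transcript_lengths: Mapping[str, int] | None = None,
                        length_window: tuple[int, int] = RPF_LENGTH_WINDOW,
                        ) -> pd.DataFrame:
    missing = [c for c in _FOOTPRINT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"footprint table missing columns {missing}")
    if (df["five_prime_pos"] < 0).any():
        raise ValidationError("negative footprint position")
    lo, hi = length_window
    bad = ~df["read_length"].between(lo, hi)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} footprints outside the {lo}-{hi} nt size window"
        )
    if transcript_lengths is not None:
        tlen = df["transcript_id"].map(transcript_lengths)
        if tlen.isna().any():
            unknown = df.loc[tlen.isna(), "transcript_id"].unique()[:5]
            raise ValidationError(f"footprints on unknown transcripts {list(unknown)}")
        if (df["five_prime_pos"] + df["read_length"] > tlen).any():
            raise ValidationError("footprint extends past transcript end")
    return df


def read_footprints(path: str | Path,
                    transcript_lengths: Mapping[str, int] | None = None,
                    length_window: tuple[int, int] = RPF_LENGTH_WINDOW,
                    ) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_footprints(df, transcript_lengths, length_window)


def write_footprints(df: pd.DataFrame, path: str | Path) -> None:
    df[_FOOTPRINT_COLS].to_csv(path, sep="\t", index=False)


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse RNA/DNA alphabets onto DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_isoform_proportions(path: str | Path) -> pd.DataFrame:
    """Read a per-gene isoform proportion table.

    Columns: gene_id, isoform_id, then one proportion column per organ. The
    proportions of each gene must sum to 1 per organ (tolerance 1e-6; absent
    isoforms carry explicit zeros).
    """
    df = pd.read_csv(path, sep="\t")
    organ_cols = [c for c in df.columns if c not in ("gene_id", "isoform_id")]
    if not organ_cols:
        raise ValidationError(f"{path}: no organ proportion columns")
    if (df[organ_cols] < 0).any().any():
        raise ValidationError(f"{path}: negative isoform proportion")
    sums = df.groupby("gene_id")[organ_cols].sum()
    off = (sums - 1.0).abs().gt(1e-6)
    if off.any().any():
        gene = sums.index[off.any(axis=1)][0]
        raise ValidationError(f"{path}: proportions of gene {gene!r} do not sum to 1")
    return df


def write_isoform_proportions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed6(records: pd.DataFrame, path: str | Path) -> None:
    """Write transcript-relative BED6 (chrom = transcript id, score = -log10 p)."""
    records.to_csv(path, sep="\t", index=False, header=False)
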