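"""Isoform-usage divergence between organs, Kozak scoring and transcript
feature tables.

For each gene, P(g) = (p1, ..., pn) holds the relative expression proportions
of its n protein-coding transcript isoforms in one organ (shared isoform
index across organs, zeros for absent isoforms). Divergence between organs L
and K is the Hellinger distance

    H(P_L, P_K) = (1/sqrt(2)) * sqrt( sum_i (sqrt(p_L_i) - sqrt(p_K_i))^2 )

which is 0 for identical isoform distributions and 1 for disjoint ones.

The Kozak start-codon context is scored against the consensus GccA/GccAUGG:
+3 for each highly conserved position match (G at -6, A or G at -3, G at +4),
+1 for each common position match (C at -5, -4, -2, -1), AUG not scored,
maximum 13.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import gc_fraction

from .dataio import TranscriptAnnotation, ValidationError, normalize_sequence

log = logging.getLogger("ribocycle")

DIVERGENCE_CATEGORIES = ("identical-set", "5utr-only", "5utr-identical",
                         "cds-only", "3utr-only", "mixed")

KOZAK_MAX_SCORE = 13


def _check_proportions(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError(f"{name}: negative proportion")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"{name}: proportions sum to {p.sum():.6g}, not 1")
    return p


def hellinger_distance(p_a: Sequence[float], p_b: Sequence[float]) -> float:
    """Hellinger distance between two isoform proportion vectors (0..1)."""
    a = _check_proportions(np.asarray(p_a), "first vector")
    b = _check_proportions(np.asarray(p_b), "second vector")
    if a.size != b.size:
        raise ValidationError("proportion vectors differ in length")
    h = np.sqrt(0.5 * np.sum((np.sqrt(a) - np.sqrt(b)) ** 2))
    return float(min(1.0, h))


def hellinger_table(isoforms: pd.DataFrame,
                    organ_a: str, organ_b: str) -> pd.Series:
    """Per-gene Hellinger distance from an isoform proportion table.

    ``isoforms`` carries columns gene_id, isoform_id and one proportion column
    per organ (see :func:`ribocycle.dataio.read_isoform_proportions`).
    """
    out = {}
    for gene, grp in isoforms.groupby("gene_id", sort=True):
        out[gene] = hellinger_distance(grp[organ_a].to_numpy(),
                                       grp[organ_b].to_numpy())
    return pd.Series(out, name="hellinger")


def classify_divergence(features: Mapping[str, tuple],
                        p_a: Mapping[str, float],
                        p_b: Mapping[str, float]) -> str:
    """Attribute a gene's cross-organ isoform divergence to transcript features.

    ``features`` maps isoform id to a (utr5, cds, utr3) identity key (any
    hashable per-feature representation, e.g. sequences or spans); ``p_a`` and
    ``p_b`` map isoform id to its expression proportion in each organ.

    Categories: ``identical-set`` when both organs use the same isoforms at
    the same proportions; ``5utr-only``/``cds-only``/``3utr-only`` when the
    expressed isoforms differ in exactly that feature; ``5utr-identical``
    when several features differ but all expressed isoforms share the 5'UTR;
    otherwise ``mixed``.
    """
    isoforms = sorted(set(p_a) | set(p_b))
    missing = [i for i in isoforms if i not in features]
    if missing:
        raise ValidationError(f"isoforms without feature annotation: {missing}")
    va = np.array([p_a.get(i, 0.0) for i in isoforms])
    vb = np.array([p_b.get(i, 0.0) for i in isoforms])
    _check_proportions(va, "organ A")
    _check_proportions(vb, "organ B")
    if np.allclose(va, vb, atol=1e-9):
        return "identical-set"
    expressed = [i for i, a, b in zip(isoforms, va, vb) if a > 0 or b > 0]
    varying = {
        name
        for idx, name in enumerate(("5utr", "cds", "3utr"))
        if len({features[i][idx] for i in expressed}) > 1
    }
    if not varying:
        # same molecular isoforms, only proportions shifted
        return "identical-set"
    if varying == {"5utr"}:
        return "5utr-only"
    if varying == {"cds"}:
        return "cds-only"
    if varying == {"3utr"}:
        return "3utr-only"
    if "5utr" not in varying:
        return "5utr-identical"
    return "mixed"


#: (context position, scoring rule) pairs: positions -6..-1 then +4
_KOZAK_RULES = (
    (0, ("G",), 3),   # -6 highly conserved
    (1, ("C",), 1),   # -5 common
    (2, ("C",), 1),   # -4 common
    (3, ("A", "G"), 3),  # -3 highly conserved
    (4, ("C",), 1),   # -2 common
    (5, ("C",), 1),   # -1 common
    (9, ("G",), 3),   # +4 highly conserved
)


def kozak_score(context: str) -> int:
    """Score a 10-nt start-codon context against the consensus GccA/GccAUGG.

    The context covers positions -6..-1, the AUG, and +4; missing upstream
    positions may be padded with ``N`` (scored 0). The AUG itself is not
    scored; the consensus context scores the maximum of 13.
    """
    ctx = normalize_sequence(context)
    if len(ctx) != 10:
        raise ValidationError(f"context {context!r} is not 10 nt")
    if ctx[6:9] != "ATG":
        raise ValidationError(f"context {context!r} lacks AUG at positions 7-9")
    return sum(pts for pos, hits, pts in _KOZAK_RULES if ctx[pos] in hits)


def kozak_context(sequence: str, cds_start: int) -> str:
    """Extract the 10-nt Kozak context around a start codon.

    Upstream positions missing because the 5'UTR is shorter than 6 nt are
    padded with ``N`` and score 0.
    """
    seq = normalize_sequence(sequence)
    upstream = seq[max(0, cds_start - 6):cds_start].rjust(6, "N")
    downstream = seq[cds_start:cds_start + 4]
    if len(downstream) < 4:
        raise ValidationError("transcript too short for a +4 context position")
    return upstream + downstream


def feature_table(annotations: Mapping[str, TranscriptAnnotation],
                  sequences: Mapping[str, str],
                  mfe_5utr: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-transcript lengths, GC contents and Kozak score.

    GC content is computed on the whole transcript and on each feature
    (missing for empty features). An externally computed 5'UTR minimum free
    energy column may be merged in via ``mfe_5utr``.
    """
    rows = []
    for tid, ann in sorted(annotations.items()):
        seq = normalize_sequence(sequences[tid])
        if len(seq) != ann.length:
            raise ValidationError(
                f"{tid}: sequence length {len(seq)} != annotated {ann.length}"
            )
        spans = {"utr5": ann.utr5, "cds": ann.cds, "utr3": ann.utr3}
        row: dict = {"transcript_id": tid, "gene_id": ann.gene_id,
                     "length": ann.length, "gc": gc_fraction(seq)}
        for name, (lo, hi) in spans.items():
            row[f"{name}_len"] = hi - lo
            row[f"{name}_gc"] = gc_fraction(seq[lo:hi]) if hi > lo else np.nan
        row["kozak_score"] = kozak_score(kozak_context(seq, ann.cds[0]))
        if mfe_5utr is not None:
            row["utr5_mfe"] = mfe_5utr.get(tid, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")
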