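"""Normalization, RPKM, translation efficiency and replicate measurement error.

Libraries are scaled with upper-quartile normalization: each library's factor
is the 75th percentile of its positive gene counts divided by its raw depth,
and factors are rescaled to geometric mean 1 so that effective library sizes
stay on the raw-depth scale. RPKM is reads per kb of feature per effective
million; translation efficiency (TE) is the per-gene, per-sample ratio of
RPF-RPKM to RNA-RPKM.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import CountMatrix, SampleKey, ValidationError, parse_sample_columns

log = logging.getLogger("ribocycle")


@dataclasses.dataclass
class NormFactors:
    """Per-library upper-quartile scaling: raw depth, factor, effective size."""

    raw_sizes: pd.Series
    factors: pd.Series

    @property
    def effective_sizes(self) -> pd.Series:
        return self.raw_sizes * self.factors


def upper_quartile_factors(matrix: CountMatrix | pd.DataFrame) -> NormFactors:
    """Upper-quartile normalization factors with geometric mean 1.

    For each library, the factor is the 75th percentile of counts over genes
    with a positive count in that library, divided by the raw library size;
    factors are then rescaled to geometric mean 1 across libraries.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    raw_sizes = counts.sum(axis=0).astype(float)
    if (raw_sizes == 0).any():
        bad = raw_sizes.index[raw_sizes == 0].tolist()
        raise ValidationError(f"all-zero libraries: {bad}")
    uq = pd.Series(
        {c: np.percentile(col[col > 0], 75.0)
         for c, col in ((c, counts[c].to_numpy()) for c in counts.columns)},
        dtype=float,
    )
    factors = uq / raw_sizes
    factors = factors / np.exp(np.log(factors).mean())
    return NormFactors(raw_sizes=raw_sizes, factors=factors)


def normalized_counts(counts: pd.DataFrame, norm: NormFactors) -> pd.DataFrame:
    """Counts divided by the per-library upper-quartile factor."""
    return counts / norm.factors


def rpkm(matrix: CountMatrix | pd.DataFrame,
         lengths: pd.Series,
         effective_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kb of feature per effective million mapped reads.

    RPKM_gj = count_gj / (length_g / 1000) / (effective_size_j / 1e6). No
    mappable-length ("faux reads") correction is applied.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = lengths.index[(lengths <= 0) | lengths.isna()][0]
        raise ValidationError(f"non-positive or missing length for gene {bad!r}")
    per_kb = counts.div(lengths / 1000.0, axis=0)
    return per_kb.div(effective_sizes.reindex(counts.columns) / 1e6, axis=1)


def _assay_free(key: SampleKey) -> tuple:
    return (key.organ, key.timepoint, key.replicate)


def translation_efficiency(rpf: pd.DataFrame, rna: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample TE = RPF-RPKM / RNA-RPKM.

    Columns are matched on (organ, timepoint, replicate); output columns carry
    assay "TE". TE is missing (NaN) wherever RNA-RPKM is zero.
    """
    rpf_keys = {_assay_free(k): k.column for k in parse_sample_columns(rpf.columns)}
    rna_keys = {_assay_free(k): k.column for k in parse_sample_columns(rna.columns)}
    unmatched = set(rpf_keys) ^ set(rna_keys)
    if unmatched:
        raise ValidationError(f"unmatched samples between RPF and RNA: {sorted(unmatched)}")
    genes = rpf.index
    if not genes.equals(rna.index):
        raise ValidationError("RPF and RNA tables carry different genes")
    out = {}
    for free, rpf_col in sorted(rpf_keys.items()):
        organ, tp, rep = free
        te_col = SampleKey(organ, "TE", tp, rep).column
        denom = rna[rna_keys[free]].replace(0.0, np.nan)
        out[te_col] = rpf[rpf_col] / denom
    return pd.DataFrame(out, index=genes)


@dataclasses.dataclass
class MeasurementErrorEstimate:
    """Replicate measurement error for one expression decile and library class."""

    bin_index: int
    bin_bounds: tuple[float, float]
    organ: str
    assay: str
    n_genes: int
    me_mean: float       # mean over timepoints of ME_t (log^2 units)
    me_sd: float         # spread of ME_t over the 12 timepoints


def measurement_error(normalized: Mapping[tuple[str, str], pd.DataFrame],
                      n_bins: int = 10,
                      pseudocount: float = 0.5,
                      exclude_extreme_ratio: bool = False,
                      ) -> pd.DataFrame:
    """Replicate-based measurement error per expression decile.

    ``normalized`` maps (organ, assay) to a gene x sample table of normalized
    counts covering all four organ/assay combinations. Genes are binned into
    ``n_bins`` deciles of the fourth root of the product of the four per-class
    mean expression levels. Within each bin and class, the per-timepoint error
    is ME_t = mean over genes of (log x1 - log x2)^2 / 2 on
    log(normalized + pseudocount); the mean and SD of ME_t over the 12
    timepoints are reported.

    With ``exclude_extreme_ratio``, genes whose mean expression ratio (between
    organs at fixed assay, or between assays at fixed organ) exceeds 2 at all
    timepoints are excluded before binning.
    """
    classes = sorted(normalized)
    if len(classes) != 4:
        raise ValidationError(f"expected 4 organ/assay classes, got {classes}")
    genes = normalized[classes[0]].index
    for key in classes[1:]:
        if not normalized[key].index.equals(genes):
            raise ValidationError(f"class {key} carries different genes")

    tp_means = {}  # (organ, assay) -> gene x timepoint replicate-mean table
    rep_pairs = {}
    for key, table in normalized.items():
        keys = parse_sample_columns(table.columns)
        by_tp: dict[int, list[str]] = {}
        for k in keys:
            by_tp.setdefault(k.timepoint, []).append(k.column)
        for tp, cols in by_tp.items():
            if len(cols) != 2:
                raise ValidationError(
                    f"{key}: timepoint ZT{tp:02d} has {len(cols)} replicates, need 2"
                )
        rep_pairs[key] = {tp: sorted(cols) for tp, cols in by_tp.items()}
        tp_means[key] = pd.DataFrame(
            {tp: table[cols].mean(axis=1) for tp, cols in sorted(by_tp.items())}
        )

    if exclude_extreme_ratio:
        keep = pd.Series(False, index=genes)
        organs = sorted({o for o, _ in classes})
        assays = sorted({a for _, a in classes})
        comparisons = []
        if len(organs) == 2:
            comparisons += [((organs[0], a), (organs[1], a)) for a in assays]
        comparisons += [((o, assays[0]), (o, assays[1])) for o in organs]
        extreme = pd.Series(False, index=genes)
        for ka, kb in comparisons:
            ratio = (tp_means[ka] + pseudocount) / (tp_means[kb] + pseudocount)
            ratio = np.maximum(ratio, 1.0 / ratio)
            extreme |= (ratio > 2.0).all(axis=1)
        keep = ~extreme
        log.info("measurement_error: excluded %d/%d extreme-ratio genes",
                 int(extreme.sum()), len(genes))
        genes = genes[keep]

    class_means = pd.DataFrame(
        {key: normalized[key].loc[genes].mean(axis=1) for key in classes}
    )
    avg_expr = np.power(class_means.prod(axis=1), 0.25)
    bin_idx = pd.qcut(avg_expr.rank(method="first"), n_bins, labels=False)

    rows = []
    for b in range(n_bins):
        members = genes[bin_idx == b]
        lo, hi = float(avg_expr[members].min()), float(avg_expr[members].max())
        for organ, assay in classes:
            table = normalized[(organ, assay)].loc[members]
            me_t = []
            for tp, (c1, c2) in sorted(rep_pairs[(organ, assay)].items()):
                d = (np.log(table[c1] + pseudocount)
                     - np.log(table[c2] + pseudocount))
                me_t.append(float((d ** 2).mean() / 2.0))
            me_t = np.asarray(me_t)
            rows.append(MeasurementErrorEstimate(
                bin_index=b, bin_bounds=(lo, hi), organ=organ, assay=assay,
                n_genes=len(members), me_mean=float(me_t.mean()),
                me_sd=float(me_t.std(ddof=1)),
            ))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
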