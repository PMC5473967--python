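"""Harmonic rhythm detection and phase-lag statistics for 24-h time courses.

Each gene's log2 expression series is fit with a single 24-h harmonic,
y = m + a*cos(2*pi*t/T) + b*sin(2*pi*t/T), and compared against the flat model
y = m by Akaike information criterion. A gene is called rhythmic when the
harmonic wins the AIC comparison AND its peak-to-trough fold change
2^(2*sqrt(a^2 + b^2)) reaches the amplitude cutoff (default 1.5-fold).

Phase-lag analyses compare RPF (footprint) and RNA rhythms: wrapped peak-phase
differences, a permutation test on difference distributions, the
Watson-Wheeler test for homogeneity of circular phase distributions, and
lagged cross-correlation of replicate-averaged profiles where negative lags
mean the RPF series leads the RNA series.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SampleKey, ValidationError, parse_sample_columns

log = logging.getLogger("ribocycle")

PERIOD_H = 24.0
#: residual-sum-of-squares floor, keeps AIC finite on noiseless fits
_RSS_FLOOR = 1e-12

FIT_COLUMNS = ["mesor", "a", "b", "amp_log2", "phase_h", "fold",
               "aic_rhythmic", "aic_flat", "rhythmic"]


@dataclasses.dataclass
class HarmonicFit:
    """Single-gene harmonic fit: mesor, amplitude, peak phase, AICs, call."""

    gene_id: str
    mesor: float
    a: float
    b: float
    phase_h: float
    fold: float
    aic_rhythmic: float
    aic_flat: float
    rhythmic: bool

    @property
    def amp_log2(self) -> float:
        return float(np.hypot(self.a, self.b))


def _aic(rss: np.ndarray, n: int, k: int) -> np.ndarray:
    rss = np.maximum(rss, _RSS_FLOOR)
    return n * np.log(rss / n) + 2 * k


def fit_harmonic_matrix(t: np.ndarray, Y: np.ndarray,
                        period: float = PERIOD_H,
                        amplitude_cutoff: float = 1.5) -> pd.DataFrame:
    """Vectorised flat-vs-harmonic AIC fits for a genes x samples value matrix.

    ``t`` holds the ZT hour of every column (replicates appear as repeated
    hours and enter the fit as independent observations).
    """
    t = np.asarray(t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.unique(t).size < 3:
        raise ValidationError("need >= 3 distinct timepoints for a harmonic fit")
    if not np.isfinite(Y).all():
        raise ValidationError("non-finite values in the series")
    n = t.size
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (3, n_genes)
    resid = Y.T - X @ beta
    rss1 = (resid ** 2).sum(axis=0)
    mean = Y.mean(axis=1)
    rss0 = ((Y.T - mean) ** 2).sum(axis=0)
    aic1 = _aic(rss1, n, 3)
    aic0 = _aic(rss0, n, 1)
    a, b = beta[1], beta[2]
    amp = np.hypot(a, b)
    phase = (period / (2.0 * np.pi)) * np.arctan2(b, a) % period
    fold = 2.0 ** (2.0 * amp)
    rhythmic = (aic1 < aic0) & (fold >= amplitude_cutoff)
    return pd.DataFrame({
        "mesor": beta[0], "a": a, "b": b, "amp_log2": amp, "phase_h": phase,
        "fold": fold, "aic_rhythmic": aic1, "aic_flat": aic0,
        "rhythmic": rhythmic,
    })


def fit_harmonic(t: Sequence[float], y: Sequence[float],
                 period: float = PERIOD_H,
                 amplitude_cutoff: float = 1.5,
                 gene_id: str = "") -> HarmonicFit:
    """Fit one series; see :func:`fit_harmonic_matrix` for the model."""
    row = fit_harmonic_matrix(np.asarray(t), np.asarray(y)[None, :],
                              period, amplitude_cutoff).iloc[0]
    return HarmonicFit(gene_id, float(row.mesor), float(row.a), float(row.b),
                       float(row.phase_h), float(row.fold),
                       float(row.aic_rhythmic), float(row.aic_flat),
                       bool(row.rhythmic))


def call_rhythms(table: pd.DataFrame,
                 amplitude_cutoff: float = 1.5,
                 pseudocount: float = 0.05,
                 log_transformed: bool = False) -> pd.DataFrame:
    """Per-gene harmonic fits for one organ/assay expression table.

    ``table`` is a gene x sample RPKM (or TE) table whose columns parse as
    sample keys for a single organ and assay; values are fit on
    log2(value + pseudocount) unless ``log_transformed``.
    """
    keys = parse_sample_columns(table.columns)
    organs = {k.organ for k in keys}
    assays = {k.assay for k in keys}
    if len(organs) != 1 or len(assays) != 1:
        raise ValidationError(
            f"call_rhythms expects one organ/assay table, got {organs} x {assays}"
        )
    t = np.array([k.timepoint for k in keys], dtype=float)
    Y = table.to_numpy(dtype=float)
    if not log_transformed:
        Y = np.log2(Y + pseudocount)
    fits = fit_harmonic_matrix(t, Y, amplitude_cutoff=amplitude_cutoff)
    fits.index = table.index
    fits.insert(0, "organ", organs.pop())
    fits.insert(1, "assay", assays.pop())
    n = int(fits["rhythmic"].sum())
    log.info("call_rhythms: %d/%d genes rhythmic (%s, %s)",
             n, len(fits), fits["organ"].iloc[0], fits["assay"].iloc[0])
    return fits


def rhythmic_gene_sets(fits_by_class: Mapping[str, pd.DataFrame]
                       ) -> dict[str, set[str]]:
    """Rhythmic gene sets per class plus all pairwise intersections."""
    sets = {name: set(f.index[f["rhythmic"]]) for name, f in fits_by_class.items()}
    names = sorted(sets)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            sets[f"{na}&{nb}"] = sets[na] & sets[nb]
    return sets


def wrap_phase_difference(delta_h: np.ndarray | float,
                          period: float = PERIOD_H) -> np.ndarray | float:
    """Wrap a phase difference (hours) into (-period/2, +period/2]."""
    d = np.asarray(delta_h, dtype=float) % period
    d = np.where(d > period / 2.0, d - period, d)
    return float(d) if np.isscalar(delta_h) else d


def phase_differences(fits_rpf: pd.DataFrame, fits_rna: pd.DataFrame,
                      genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Wrapped RPF-minus-RNA peak-phase differences for rhythmic-in-both genes.

    Negative differences mean the footprint peak precedes the mRNA peak.
    """
    if genes is None:
        genes = fits_rpf.index[fits_rpf["rhythmic"]].intersection(
            fits_rna.index[fits_rna["rhythmic"]])
    genes = [g for g in genes if g in fits_rpf.index and g in fits_rna.index]
    phi_rpf = fits_rpf.loc[genes, "phase_h"].to_numpy()
    phi_rna = fits_rna.loc[genes, "phase_h"].to_numpy()
    delta = wrap_phase_difference(phi_rpf - phi_rna)
    out = pd.DataFrame({"phase_rpf_h": phi_rpf, "phase_rna_h": phi_rna,
                        "delta_h": delta}, index=pd.Index(genes, name="gene_id"))
    log.info("phase_differences: %d genes, mean delta %.2f h, %d advances / %d delays",
             len(out), float(np.mean(delta)) if len(out) else float("nan"),
             int((delta < 0).sum()), int((delta > 0).sum()))
    return out


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def permutation_test_distributions(delta_a: Sequence[float],
                                   delta_b: Sequence[float],
                                   n_perm: int = 10_000,
                                   seed: int | None = None) -> float:
    """Permutation p-value for a difference between two phase-shift distributions.

    The statistic is the two-sample Kolmogorov-Smirnov distance; the null is
    built by pooling both samples and re-splitting at the original sizes.
    Uses the add-one estimator p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("permutation test needs two non-empty groups")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    obs = _ks_distance(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _ks_distance(perm[:a.size], perm[a.size:]) >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def watson_wheeler(groups: Sequence[Sequence[float]],
                   min_size: int = 10) -> dict[str, float]:
    """Watson-Wheeler (Mardia) test for homogeneity of phase distributions.

    Phases in hours are converted to angles (h * 2*pi/24) and replaced by
    uniform scores via circular ranks (ties get average ranks, logged); the
    statistic W = 2 * sum_k (C_k^2 + S_k^2) / n_k is referred to chi-square
    with df = 2(k-1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("watson_wheeler needs >= 2 groups")
    for i, g in enumerate(groups):
        if g.size < min_size:
            raise ValidationError(f"group {i} has {g.size} < {min_size} phases")
    angles = np.concatenate(groups) * (2.0 * np.pi / PERIOD_H)
    ranks = stats.rankdata(angles % (2.0 * np.pi), method="average")
    if np.unique(angles).size < angles.size:
        log.info("watson_wheeler: ties broken by average circular ranks")
    n_total = angles.size
    scores = 2.0 * np.pi * ranks / n_total
    w_stat = 0.0
    start = 0
    for g in groups:
        s = scores[start:start + g.size]
        start += g.size
        w_stat += (np.cos(s).sum() ** 2 + np.sin(s).sum() ** 2) / g.size
    w_stat *= 2.0
    df = 2 * (len(groups) - 1)
    return {"W": float(w_stat), "df": df,
            "p": float(stats.chi2.sf(w_stat, df))}


@dataclasses.dataclass
class LagCorrelation:
    """Lagged RPF-vs-RNA profile correlation; negative lag = RPF leads RNA."""

    lags_h: np.ndarray
    r: np.ndarray

    @property
    def best_lag_h(self) -> float:
        return float(self.lags_h[int(np.nanargmax(self.r))])


def cross_correlate(x_rpf: Sequence[float], y_rna: Sequence[float],
                    step_h: float = 2.0, max_lag_h: float = 8.0,
                    circular: bool = False) -> LagCorrelation:
    """Truncated cross-correlation of two equal-length time profiles.

    r(k) = sum_t (x_{t+k} - xbar)(y_t - ybar) / (n * s_x * s_y) with overall
    means and population SDs, summing over the overlap (or cyclically with
    ``circular``). Lag k is in sampling steps and reported in hours; negative
    lags correspond to the RPF series leading the RNA series. Constant
    profiles yield undefined (NaN) correlations, flagged in the log.
    """
    x = np.asarray(x_rpf, dtype=float)
    y = np.asarray(y_rna, dtype=float)
    if x.size != y.size:
        raise ValidationError("profiles must have equal length")
    n = x.size
    max_k = int(round(max_lag_h / step_h))
    lags = np.arange(-max_k, max_k + 1)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        log.warning("cross_correlate: constant profile, correlation undefined")
        return LagCorrelation(lags * step_h, np.full(lags.size, np.nan))
    xc = x - x.mean()
    yc = y - y.mean()
    r = np.empty(lags.size)
    for i, k in enumerate(lags):
        if circular:
            r[i] = float(np.dot(np.roll(xc, -k), yc))
        else:
            if k >= 0:
                r[i] = float(np.dot(xc[k:], yc[:n - k]))
            else:
                r[i] = float(np.dot(xc[:n + k], yc[-k:]))
        r[i] /= n * sx * sy
    return LagCorrelation(lags * step_h, r)


def replicate_mean_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicates: gene x sample table -> gene x ZT-hour table."""
    keys = parse_sample_columns(table.columns)
    by_tp: dict[int, list[str]] = {}
    for k in keys:
        by_tp.setdefault(k.timepoint, []).append(k.column)
    return pd.DataFrame(
        {tp: table[cols].mean(axis=1) for tp, cols in sorted(by_tp.items())}
    )


def translation_only_screen(fits_rna: pd.DataFrame, fits_rpf: pd.DataFrame,
                            te_table: pd.DataFrame,
                            alpha: float = 0.05,
                            amplitude_cutoff: float = 1.5) -> pd.DataFrame:
    """Screen for rhythmic translation on constantly expressed mRNAs.

    A gene passes when (i) its footprint series is called rhythmic, (ii) its
    RNA series is not rhythmic and shows a peak-to-trough fold below the
    amplitude cutoff, and (iii) its TE varies over the 12 timepoints by
    Kruskal-Wallis at Benjamini-Hochberg FDR < ``alpha``.
    """
    genes = fits_rna.index.intersection(fits_rpf.index).intersection(te_table.index)
    keys = parse_sample_columns(te_table.columns)
    by_tp: dict[int, list[str]] = {}
    for k in keys:
        by_tp.setdefault(k.timepoint, []).append(k.column)
    cols_by_tp = [cols for _, cols in sorted(by_tp.items())]

    rpf_ok = fits_rpf.loc[genes, "rhythmic"].to_numpy(dtype=bool)
    rna_flat = (~fits_rna.loc[genes, "rhythmic"].to_numpy(dtype=bool)
                & (fits_rna.loc[genes, "fold"].to_numpy() < amplitude_cutoff))
    candidates = pd.Index(genes)[rpf_ok & rna_flat]

    pvals = np.ones(len(candidates))
    for i, g in enumerate(candidates):
        samples = [te_table.loc[g, cols].dropna().to_numpy() for cols in cols_by_tp]
        samples = [s for s in samples if s.size > 0]
        if len(samples) < 3 or np.ptp(np.concatenate(samples)) == 0:
            continue
        try:
            pvals[i] = stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical
            pvals[i] = 1.0
    qvals = (stats.false_discovery_control(pvals, method="bh")
             if len(candidates) else np.array([]))
    out = pd.DataFrame({"kw_p": pvals, "kw_q": qvals,
                        "translation_only": qvals < alpha},
                       index=pd.Index(candidates, name="gene_id"))
    log.info("translation_only_screen: %d candidates, %d called",
             len(out), int(out["translation_only"].sum()))
    return out
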