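import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribocycle.dataio import ValidationError
from ribocycle.rhythm import (cross_correlate, fit_harmonic,
                              fit_harmonic_matrix, call_rhythms,
                              permutation_test_distributions,
                              phase_differences, translation_only_screen,
                              watson_wheeler, wrap_phase_difference)

ZT = np.repeat(np.arange(0, 24, 2), 2).astype(float)  # 12 ZTs in duplicate


def cosine(t, mesor, amp, phase):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / 24.0)


class TestFitHarmonic:
    def test_constant_series_is_flat(self):
        fit = fit_harmonic(ZT, np.full(ZT.size, 5.0))
        assert fit.fold == pytest.approx(1.0)
        assert not fit.rhythmic
        assert fit.aic_flat <= fit.aic_rhythmic

    def test_noiseless_cosine_recovers_phase_and_fold(self):
        fit = fit_harmonic(ZT, cosine(ZT, 5.0, 0.5, 8.0))
        assert fit.phase_h == pytest.approx(8.0, abs=1e-9)
        assert fit.fold == pytest.approx(2.0 ** (2 * 0.5))
        assert fit.rhythmic

    def test_amplitude_gate_blocks_small_folds(self):
        # half-amplitude 0.25 -> fold 2^0.5 ~ 1.414 < 1.5: AIC prefers the
        # cosine but the gate keeps the gene non-rhythmic.
        fit = fit_harmonic(ZT, cosine(ZT, 5.0, 0.25, 8.0))
        assert fit.aic_rhythmic < fit.aic_flat
        assert fit.fold == pytest.approx(2.0 ** 0.5)
        assert not fit.rhythmic

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValidationError, match="3 distinct"):
            fit_harmonic(np.array([0.0, 0.0, 12.0, 12.0]), np.arange(4.0))

    @given(phase=st.floats(0.0, 24.0, exclude_max=True),
           amp=st.floats(0.3, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_phase_and_fold_recovery_property(self, phase, amp):
        """Noiseless planted cosines: phase within 0.25 h, fold exact."""
        fit = fit_harmonic(ZT, cosine(ZT, 6.0, amp, phase))
        delta = abs(wrap_phase_difference(fit.phase_h - phase))
        assert delta <= 0.25
        assert fit.fold == pytest.approx(2.0 ** (2 * amp), rel=1e-9)


class TestCallRhythms:
    def test_planted_rhythms_recovered(self, small_dataset):
        """Sensitivity and specificity on a simulation with known truth."""
        from ribocycle import SimulationConfig, simulate_dataset
        from ribocycle.quant import rpkm, upper_quartile_factors
        cfg = SimulationConfig(seed=21, n_genes=600, nb_dispersion=0.02,
                               frac_rhythmic_rna=0.10, frac_rhythmic_te=0.0,
                               amplitude_range_log2=(0.6, 0.9))
        ds = simulate_dataset(cfg)
        cm = ds.counts[("kidney", "RNA")]
        norm = upper_quartile_factors(cm)
        table = rpkm(cm, cm.lengths["cds_len"], norm.effective_sizes)
        fits = call_rhythms(table)
        truth = ds.truth.genes["rhythmic_rna"]
        called = fits["rhythmic"]
        sensitivity = called[truth].mean()
        fpr = called[~truth].mean()
        assert sensitivity >= 0.9
        assert fpr <= 0.05

    def test_null_simulation_controls_type_one_error(self):
        from ribocycle import SimulationConfig, simulate_dataset
        from ribocycle.quant import rpkm, upper_quartile_factors
        cfg = SimulationConfig(seed=22, n_genes=500, frac_rhythmic_rna=0.0,
                               frac_rhythmic_te=0.0)
        ds = simulate_dataset(cfg)
        cm = ds.counts[("liver", "RNA")]
        norm = upper_quartile_factors(cm)
        fits = call_rhythms(rpkm(cm, cm.lengths["cds_len"],
                                 norm.effective_sizes))
        assert fits["rhythmic"].mean() <= 0.05

    def test_mixed_organ_table_rejected(self):
        table = pd.DataFrame({"kidney_RNA_ZT00_rep1": [1.0],
                              "liver_RNA_ZT00_rep1": [1.0]}, index=["g1"])
        with pytest.raises(ValidationError, match="one organ/assay"):
            call_rhythms(table)


class TestPhaseDifferences:
    @pytest.mark.parametrize("phi_rpf, phi_rna, expected", [
        (22.0, 2.0, -4.0),   # wraps across midnight
        (8.0, 8.0, 0.0),
        (14.0, 2.0, 12.0),   # boundary maps to +12, not -12
    ])
    def test_wrap_convention(self, phi_rpf, phi_rna, expected):
        assert wrap_phase_difference(phi_rpf - phi_rna) == pytest.approx(expected)

    def test_antisymmetry_off_boundary(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-11.9, 11.9, 200)
        forward = wrap_phase_difference(d)
        backward = wrap_phase_difference(-d)
        off_boundary = np.abs(np.abs(forward) - 12.0) > 1e-9
        assert np.allclose(forward[off_boundary], -backward[off_boundary])

    def test_rhythmic_in_both_selection(self):
        fits_rpf = pd.DataFrame({"phase_h": [22.0, 5.0], "rhythmic": [True, False]},
                                index=["gA", "gB"])
        fits_rna = pd.DataFrame({"phase_h": [2.0, 5.0], "rhythmic": [True, True]},
                                index=["gA", "gB"])
        out = phase_differences(fits_rpf, fits_rna)
        assert list(out.index) == ["gA"]
        assert out.loc["gA", "delta_h"] == pytest.approx(-4.0)


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        a = np.array([-3.0, -1.0, 0.0, 2.0, 4.0] * 4)
        assert permutation_test_distributions(a, a.copy(), 200, seed=0) == 1.0

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(3)
        a = wrap_phase_difference(rng.normal(0.0, 1.0, 150))
        b = wrap_phase_difference(rng.normal(6.0, 1.0, 150))
        p = permutation_test_distributions(a, b, 10_000, seed=3)
        assert p <= 0.001

    def test_seeded_runs_reproducible(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 2, 40), rng.normal(1, 2, 50)
        p1 = permutation_test_distributions(a, b, 500, seed=7)
        p2 = permutation_test_distributions(a, b, 500, seed=7)
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test_distributions([], [1.0], 200)


class TestWatsonWheeler:
    def test_identical_groups_score_zero(self):
        g = np.linspace(0.0, 23.0, 40)
        out = watson_wheeler([g, g.copy()])
        assert out["W"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0)
        assert out["df"] == 2

    def test_separated_phase_clusters_detected(self):
        rng = np.random.default_rng(11)
        a = (rng.vonmises(0.0, 5.0, 50) * 24 / (2 * np.pi)) % 24
        b = (rng.vonmises(np.pi, 5.0, 50) * 24 / (2 * np.pi)) % 24
        out = watson_wheeler([a, b])
        assert out["W"] >= 0.0
        assert out["p"] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match="phases"):
            watson_wheeler([np.arange(5.0), np.arange(20.0)])


class TestCrossCorrelate:
    def test_identical_profiles_peak_at_zero(self):
        t = np.arange(0, 24, 2.0)
        x = cosine(t, 0.0, 1.0, 4.0)
        lc = cross_correlate(x, x)
        assert lc.r[lc.lags_h == 0.0][0] == pytest.approx(1.0)
        assert lc.best_lag_h == 0.0

    def test_antiphase_profiles(self):
        t = np.arange(0, 24, 2.0)
        x = cosine(t, 0.0, 1.0, 4.0)
        lc = cross_correlate(x, -x)
        assert lc.r[lc.lags_h == 0.0][0] == pytest.approx(-1.0)

    def test_rpf_leading_gives_negative_best_lag(self):
        t = np.arange(0, 24, 2.0)
        x = cosine(t, 0.0, 1.0, 4.0)   # RPF peaks at ZT4
        y = cosine(t, 0.0, 1.0, 8.0)   # RNA peaks at ZT8
        lc = cross_correlate(x, y)
        assert lc.best_lag_h == -4.0

    @pytest.mark.parametrize("lag", [-2.0, -4.0, -6.0])
    def test_planted_lag_recovered(self, lag):
        t = np.arange(0, 24, 2.0)
        rna_phase = 10.0
        y = cosine(t, 2.0, 0.8, rna_phase)
        x = cosine(t, 2.0, 0.8, rna_phase + lag)
        assert cross_correlate(x, y).best_lag_h == lag

    def test_constant_profile_flagged(self):
        lc = cross_correlate(np.ones(12), np.arange(12.0))
        assert np.isnan(lc.r).all()


class TestTranslationOnlyScreen:
    def _tables(self, rng, n=40, planted=5):
        """Flat RNA for all genes; planted genes carry a rhythmic TE."""
        genes = [f"g{i:04d}" for i in range(n)]
        te_cols = {}
        rna = {}
        rpf = {}
        for i, g in enumerate(genes):
            amp = 0.6 if i < planted else 0.0
            te = 2.0 ** cosine(ZT, 0.0, amp, 6.0)
            te *= rng.lognormal(0.0, 0.05, ZT.size)
            rna_vals = 50.0 * rng.lognormal(0.0, 0.05, ZT.size)
            rna[g] = rna_vals
            rpf[g] = rna_vals * te
            te_cols[g] = te
        def table(d, assay):
            cols = [f"kidney_{assay}_ZT{tp:02d}_rep{r}"
                    for tp in range(0, 24, 2) for r in (1, 2)]
            return pd.DataFrame(np.vstack([d[g] for g in genes]),
                                index=genes, columns=cols)
        return table(rna, "RNA"), table(rpf, "RPF"), table(te_cols, "TE")

    def test_planted_te_rhythm_detected_and_flat_excluded(self):
        rng = np.random.default_rng(9)
        rna, rpf, te = self._tables(rng)
        fits_rna = call_rhythms(rna)
        fits_rpf = call_rhythms(rpf)
        out = translation_only_screen(fits_rna, fits_rpf, te)
        called = set(out.index[out["translation_only"]])
        planted = {f"g{i:04d}" for i in range(5)}
        assert planted <= called
        assert not (called - planted)

    def test_gene_rhythmic_in_both_with_flat_te_excluded(self):
        rng = np.random.default_rng(10)
        genes = ["gA"]
        vals = 2.0 ** cosine(ZT, 5.0, 0.8, 4.0)
        def table(assay, v):
            cols = [f"kidney_{assay}_ZT{tp:02d}_rep{r}"
                    for tp in range(0, 24, 2) for r in (1, 2)]
            return pd.DataFrame([v], index=genes, columns=cols)
        rna = table("RNA", vals)
        rpf = table("RPF", vals * 2.0)
        te = table("TE", np.full(ZT.size, 2.0))
        out = translation_only_screen(call_rhythms(rna), call_rhythms(rpf), te)
        assert "gA" not in set(out.index[out.get("translation_only", [])])
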