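import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribocycle.dataio import TranscriptAnnotation, ValidationError
from ribocycle.ribopos import ASiteProfile, DEFAULT_OFFSETS
from ribocycle.uorf import (UORFRecord, call_translated, detect_uorfs,
                            merge_composites, uorf_te,
                            uorf_vs_cds_ratio_table)


def make_transcript(utr5_seq: str, cds_codons: int = 40, utr3_len: int = 30):
    """Build a transcript whose 5'UTR is exactly ``utr5_seq``."""
    rng = np.random.default_rng(abs(hash(utr5_seq)) % 2 ** 31)
    cds = "ATG" + "".join(rng.choice(["GCC", "AAA", "CGT"], cds_codons - 2)) + "TAA"
    utr3 = "".join(rng.choice(list("ACGT"), utr3_len))
    seq = utr5_seq + cds + utr3
    ann = TranscriptAnnotation(
        "t1", "g1", (0, len(utr5_seq)),
        (len(utr5_seq), len(utr5_seq) + len(cds)),
        (len(utr5_seq) + len(cds), len(seq)))
    return seq, ann


def brute_force_uorfs(seq: str, cds_start: int, min_len: int = 18):
    """Independent enumerator: every AUG in the UTR, every in-frame stop."""
    stops = {"TAA", "TAG", "TGA"}
    found = []
    for s in range(cds_start - 2):
        if seq[s:s + 3] != "ATG":
            continue
        end = None
        for p in range(s + 3, len(seq) - 2, 3):
            if seq[p:p + 3] in stops:
                end = p
                break
        if end is None:
            end = s + 3 * ((len(seq) - s) // 3)
        if end - s < min_len:
            continue
        if end > cds_start and (cds_start - s) % 3 == 0:
            continue
        found.append((s, end))
    return found


class TestDetectUorfs:
    def test_boundary_length_candidate_accepted(self):
        # AUG at 2 + 5 more codons + stop: coding span exactly 18 nt
        utr5 = "GG" + "ATG" + "AAA" * 5 + "TAA" + "GG"
        seq, ann = make_transcript(utr5)
        records = detect_uorfs(seq, ann)
        assert len(records) == 1
        rec = records[0]
        assert (rec.start, rec.end) == (2, 20)
        assert rec.length == 18
        assert rec.cds_overlap == "none"

    def test_below_threshold_rejected(self):
        utr5 = "GG" + "ATG" + "AAA" * 4 + "TAA" + "GG"  # 15 nt coding span
        seq, ann = make_transcript(utr5)
        assert detect_uorfs(seq, ann) == []

    def test_no_aug_no_candidates(self):
        seq, ann = make_transcript("CCCCCCCCCCCCCCCCCCCCCCCCCC")
        assert detect_uorfs(seq, ann) == []

    def test_in_frame_cds_overlap_dropped(self):
        # AUG with no UTR stop, in frame with the CDS start -> excluded
        utr5 = "ATG" + "AAA" * 9  # 30 nt, frame 0 relative to CDS at 30
        seq, ann = make_transcript(utr5)
        recs = detect_uorfs(seq, ann)
        assert all(r.cds_overlap != "in-frame" for r in recs)
        assert not any(r.start == 0 for r in recs)

    def test_out_of_frame_overlap_clipped_to_utr(self):
        # AUG at 1 with no UTR stop; CDS starts at 32, (32-1) % 3 != 0
        utr5 = "C" + "ATG" + "AAA" * 9 + "C"
        seq, ann = make_transcript(utr5)
        recs = [r for r in detect_uorfs(seq, ann) if r.start == 1]
        assert len(recs) == 1
        rec = recs[0]
        assert rec.cds_overlap == "out-of-frame"
        assert rec.countable_end == 32  # clipped at the CDS start
        assert rec.end > 32

    def test_sequence_annotation_mismatch_rejected(self):
        seq, ann = make_transcript("GGATGAAAAAAAAAAAAAAATAAGG")
        with pytest.raises(ValidationError, match="length"):
            detect_uorfs(seq + "A", ann)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        utr5 = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 150))))
        seq, ann = make_transcript(utr5)
        got = [(r.start, r.end) for r in detect_uorfs(seq, ann)]
        assert got == brute_force_uorfs(seq, ann.cds[0])


def _rec(start, end, tid="t1", overlap="none", countable_end=None):
    return UORFRecord(transcript_id=tid, start=start, end=end,
                      frame=start % 3, cds_overlap=overlap,
                      countable_start=start,
                      countable_end=countable_end or end)


class TestMergeComposites:
    def test_overlapping_spans_unioned(self):
        out = merge_composites([_rec(2, 26), _rec(14, 44)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (2, 44)
        assert out[0].composite

    def test_disjoint_spans_kept(self):
        out = merge_composites([_rec(2, 26), _rec(40, 70)])
        assert [(r.start, r.end) for r in out] == [(2, 26), (40, 70)]
        assert not any(r.composite for r in out)

    def test_chain_merge_matches_interval_union(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            spans = sorted((int(s), int(s + rng.integers(18, 40)))
                           for s in rng.integers(0, 150, 6))
            recs = [_rec(s, e) for s, e in spans]
            got = sorted((r.start, r.end) for r in merge_composites(recs))
            # oracle: sort + sweep interval union
            expected = []
            for s, e in sorted(spans):
                if expected and s < expected[-1][1]:
                    expected[-1] = (expected[-1][0], max(expected[-1][1], e))
                else:
                    expected.append((s, e))
            assert got == expected


def _profile(length, counts_at):
    counts = np.zeros(length, dtype=int)
    for pos, c in counts_at.items():
        counts[pos] = c
    return ASiteProfile("t1", counts, DEFAULT_OFFSETS)


class TestCallTranslated:
    def test_zero_reads_not_translated(self):
        rec = _rec(10, 40)
        out = call_translated(rec, _profile(100, {}))
        assert out.translated is False and out.frame_bias_p is None

    def test_strong_frame_bias_called(self):
        # 30 reads all in frame 0 spread over half the positions
        rec = _rec(12, 42)
        counts = {12 + 3 * i: 6 for i in range(5)}
        out = call_translated(rec, _profile(100, counts))
        assert out.frame_bias_p == pytest.approx((1.0 / 3.0) ** 30, rel=1e-9)
        assert out.coverage == pytest.approx(5 / 30)
        assert out.translated

    def test_uniform_frames_not_called(self):
        rec = _rec(12, 42)
        # exactly 10/10/10 reads across the three frames
        counts = {12 + 3 * i: 2 for i in range(5)}
        counts.update({13 + 3 * i: 2 for i in range(5)})
        counts.update({14 + 3 * i: 2 for i in range(5)})
        out = call_translated(rec, _profile(100, counts))
        from scipy.stats import binom
        assert out.frame_bias_p == pytest.approx(binom.sf(9, 30, 1 / 3), rel=1e-9)
        assert not out.translated

    def test_low_coverage_blocks_call(self):
        rec = _rec(0, 300, countable_end=300)
        out = call_translated(rec, _profile(300, {0: 50}))
        assert out.frame_bias_p < 0.05
        assert out.coverage <= 0.10
        assert not out.translated

    def test_monotone_in_frame_reads_never_untranslate(self):
        rec = _rec(12, 42)
        base = {12 + 3 * i: 2 for i in range(5)}
        base.update({13 + 3 * i: 2 for i in range(5)})
        prev_translated = False
        for extra in range(0, 40, 5):
            counts = dict(base)
            counts[12] = 2 + extra
            out = call_translated(rec, _profile(100, counts))
            if prev_translated:
                assert out.translated
            prev_translated = prev_translated or out.translated
        assert prev_translated  # strong bias eventually called


class TestUorfTE:
    def test_simple_ratio(self):
        rpf = pd.Series({"kidney_RPF_ZT00_rep1": 20.0})
        rna = pd.Series({"kidney_RNA_ZT00_rep1": 10.0})
        eff = pd.Series({"kidney_RPF_ZT00_rep1": 1e6})
        eff_rna = pd.Series({"kidney_RNA_ZT00_rep1": 1e6})
        te = uorf_te(rpf, rna, eff, eff_rna)
        assert te["kidney_TE_ZT00_rep1"] == pytest.approx(2.0)

    def test_zero_rna_missing(self):
        rpf = pd.Series({"kidney_RPF_ZT00_rep1": 20.0})
        rna = pd.Series({"kidney_RNA_ZT00_rep1": 0.0})
        eff = pd.Series({"kidney_RPF_ZT00_rep1": 1e6})
        eff_rna = pd.Series({"kidney_RNA_ZT00_rep1": 1e6})
        assert np.isnan(uorf_te(rpf, rna, eff, eff_rna).iloc[0])

    def test_joint_depth_doubling_invariant(self):
        rpf = pd.Series({"kidney_RPF_ZT00_rep1": 20.0})
        rna = pd.Series({"kidney_RNA_ZT00_rep1": 10.0})
        eff_rpf = pd.Series({"kidney_RPF_ZT00_rep1": 2e6})
        eff_rna = pd.Series({"kidney_RNA_ZT00_rep1": 5e5})
        base = uorf_te(rpf, rna, eff_rpf, eff_rna)
        scaled = uorf_te(rpf * 2, rna * 2, eff_rpf * 2, eff_rna * 2)
        pd.testing.assert_series_equal(base, scaled)


class TestRatioTable:
    def test_single_gene_join(self):
        out = uorf_vs_cds_ratio_table(pd.Series({"gA": 0.5}),
                                      pd.Series({"gA": 2.0}))
        assert out.loc["gA"].tolist() == [0.5, 2.0]

    def test_identical_columns_correlate_perfectly(self):
        s = pd.Series({"gA": 0.5, "gB": 2.0, "gC": 1.3})
        out = uorf_vs_cds_ratio_table(s, s.copy())
        assert out.attrs["pearson_r"] == pytest.approx(1.0)

    def test_planted_anticorrelation_recovered(self):
        rng = np.random.default_rng(13)
        n = 300
        z = rng.normal(0, 1, n)
        u = -0.5 * z + np.sqrt(1 - 0.25) * rng.normal(0, 1, n)
        cds = pd.Series(np.exp(z), index=[f"g{i}" for i in range(n)])
        uo = pd.Series(np.exp(u), index=cds.index)
        out = uorf_vs_cds_ratio_table(uo, cds)
        assert out.attrs["pearson_r"] == pytest.approx(-0.5, abs=0.1)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            uorf_vs_cds_ratio_table(pd.Series({"gA": 1.0}),
                                    pd.Series({"gB": 1.0}))


class TestEndToEndOnSimulation:
    def test_planted_translated_uorfs_called(self, small_dataset):
        """Frame-biased planted uORFs are called translated; frame-uniform
        planted uORFs are not."""
        from ribocycle.ribopos import a_site_positions
        from ribocycle import simulate_footprints
        ds = small_dataset
        fp = simulate_footprints(ds.annotation, ds.truth, ds.config)
        tlen = {t: a.length for t, a in ds.annotation.items()}
        profiles = a_site_positions(fp, tlen)
        hits = {True: [], False: []}
        for row in ds.truth.uorfs.itertuples(index=False):
            ann = ds.annotation[row.transcript_id]
            recs = [r for r in detect_uorfs(ds.sequences[row.transcript_id], ann)
                    if r.start == row.start]
            assert len(recs) == 1, "planted uORF must be detected"
            out = call_translated(recs[0], profiles[row.transcript_id])
            hits[row.translated].append(out.translated)
        assert np.mean(hits[True]) >= 0.95
        assert np.mean(hits[False]) <= 0.05
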