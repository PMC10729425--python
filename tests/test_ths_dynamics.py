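"""Consensus THSs, Venn partitioning, annotation, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    annotate_oracle,
    consensus_oracle,
    count_in_interval_oracle,
    reproducible_peaks_oracle,
)
from thstools.atac_qc import InsertionTrack
from thstools.formats_io import GeneModel, Peak
from thstools.ths_dynamics import (
    THS,
    annotate_ths,
    build_consensus,
    categorize,
    count_matrix,
    fold_change_matrix,
    reproducible_peaks,
    stage_group_of,
    term_enrichment,
    venn_partition,
)


def _peak(start, end, chrom="chr1", score=5.0):
    return Peak(chrom, start, end, start, score, 0.01)


def _random_peak_lists(rng, n_lists, n_per, genome_len=100_000):
    out = []
    for _ in range(n_lists):
        peaks = []
        cursor = 0
        for _ in range(n_per):
            cursor += int(rng.integers(50, genome_len // (n_per + 1)))
            length = int(rng.integers(50, 600))
            if cursor + length >= genome_len:
                break
            peaks.append(_peak(cursor, cursor + length))
            cursor += length
        out.append(peaks)
    return out


class TestReproduciblePeaks:
    def test_exact_fifty_percent_boundary(self):
        reps = [[_peak(100, 200)], [_peak(150, 250)]]
        merged = reproducible_peaks(reps)
        assert [(m.start, m.end) for m in merged] == [(100, 250)]

    def test_singleton_dropped(self):
        reps = [[_peak(100, 200)], []]
        assert reproducible_peaks(reps) == []

    def test_asymmetric_rule(self):
        # overlap is 10% of the long peak (fails for it) but 100% of the
        # short one (retained); union restores the long interval
        reps = [[_peak(0, 1000)], [_peak(0, 100)]]
        merged = reproducible_peaks(reps)
        assert [(m.start, m.end) for m in merged] == [(0, 1000)]
        # the long peak itself was NOT retained: with the short peak gone
        # from rep2 nothing survives
        assert reproducible_peaks([[_peak(0, 1000)], []]) == []

    def test_reciprocal_mode_stricter(self):
        reps = [[_peak(0, 1000)], [_peak(0, 100)]]
        assert reproducible_peaks(reps, reciprocal=True) == []

    def test_min_reps_exceeds_replicates(self):
        with pytest.raises(ValueError):
            reproducible_peaks([[_peak(0, 10)]], min_reps=2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            reps = _random_peak_lists(rng, 3, 15)
            got = reproducible_peaks(reps)
            expected = reproducible_peaks_oracle(
                [[(p.start, p.end) for p in peaks] for peaks in reps]
            )
            assert [(m.start, m.end) for m in got] == expected


class TestBuildConsensus:
    def test_identical_peak_everywhere(self):
        cp = {c: [_peak(100, 300)] for c in ("C", "D1", "D2", "D3")}
        (ths,) = build_consensus(cp)
        assert ths.partition == frozenset({"C", "D1", "D2", "D3"})
        assert (ths.start, ths.end) == (100, 300)

    def test_disjoint_peaks_per_condition(self):
        cp = {
            c: [_peak(1000 * i, 1000 * i + 200)]
            for i, c in enumerate(("C", "D1", "D2", "D3"))
        }
        thss = build_consensus(cp)
        assert len(thss) == 4
        assert all(len(t.partition) == 1 for t in thss)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            lists = _random_peak_lists(rng, 4, 50)
            cp = dict(zip(("C", "D1", "D2", "D3"), lists))
            got = build_consensus(cp)
            expected = consensus_oracle(
                {c: [(p.start, p.end) for p in ps] for c, ps in cp.items()}
            )
            assert len(got) == len(expected)
            for t, (s, e, presence) in zip(got, expected):
                assert (t.start, t.end) == (s, e)
                assert {c: t.presence[c] for c in presence} == presence


class TestVennPartition:
    def test_conservation_and_exact_counts(self):
        thss = (
            [_ths({"C"})] * 3 + [_ths({"C", "D1"})] * 2
            + [_ths({"D2", "D3"})] + [_ths({"C", "D1", "D2", "D3"})] * 4
        )
        venn = venn_partition(thss)
        assert sum(venn.values()) == len(thss)
        assert venn[("C",)] == 3
        assert venn[("C", "D1")] == 2
        assert venn[("D2", "D3")] == 1
        assert venn[("C", "D1", "D2", "D3")] == 4
        assert len(venn) == 15

    def test_stage_group_mapping(self):
        assert stage_group_of(frozenset({"C"})) == "watered_unique"
        assert stage_group_of(frozenset({"C", "D1"})) == "watered_to_moderate"
        assert stage_group_of(frozenset({"C", "D1", "D2"})) == "watered_to_severe"
        assert stage_group_of(frozenset({"D2", "D3"})) == "severe_to_dry"
        assert stage_group_of(frozenset({"C", "D1", "D2", "D3"})) == "constitutive"
        assert stage_group_of(frozenset({"D1", "D3"})) == "other"


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 50_000),
            st.integers(1, 500),
            st.sets(st.sampled_from(["C", "D1", "D2", "D3"]), min_size=1),
        ),
        min_size=1,
        max_size=60,
    )
)
def test_venn_conservation_property(items):
    """Partition counts always sum to the THS count, for any presence sets."""
    thss = [
        THS("chr1", s, s + ln, {c: c in conds for c in ("C", "D1", "D2", "D3")})
        for s, ln, conds in items
    ]
    venn = venn_partition(thss)
    assert sum(venn.values()) == len(thss)
    assert all(v >= 0 for v in venn.values())


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 5_000), st.integers(1, 400)),
        min_size=1,
        max_size=40,
    )
)
def test_merge_peaks_union_property(items):
    """Union-merge covers exactly the per-base union, sorted and disjoint."""
    from oracles import union_runs
    from thstools.ths_dynamics import merge_peaks

    peaks = [_peak(s, s + ln) for s, ln in items]
    merged = merge_peaks(peaks)
    assert [(m.start, m.end) for m in merged] == union_runs(
        [(s, s + ln) for s, ln in items]
    )


def _ths(conds, start=100, end=400, chrom="chr1"):
    return THS(chrom, start, end,
               {c: c in conds for c in ("C", "D1", "D2", "D3")})


class TestCountAndFoldChange:
    def test_counts_simple(self):
        ths = _ths({"C"}, 100, 200)
        tr = InsertionTrack("s1", "C", 1,
                            {"chr1": np.array([99, 100, 150, 199, 200])})
        cm = count_matrix([ths], [tr])
        assert cm.iloc[0, 0] == 3  # 100, 150, 199 inside [100, 200)

    def test_counts_match_oracle(self, rng):
        thss = [
            _ths({"C"}, s, s + 200) for s in range(0, 20_000, 1000)
        ]
        tracks = [
            InsertionTrack(f"s{i}", "C", i + 1,
                           {"chr1": np.sort(rng.integers(0, 20_000, 500))})
            for i in range(3)
        ]
        cm = count_matrix(thss, tracks)
        for i, t in enumerate(thss):
            for j, tr in enumerate(tracks):
                assert cm.iloc[i, j] == count_in_interval_oracle(
                    tr.positions["chr1"], t.start, t.end
                )

    def test_identical_condition_means_zero_fc(self):
        counts = pd.DataFrame(
            {"C_rep1": [10, 5], "C_rep2": [10, 5],
             "D1_rep1": [10, 5], "D1_rep2": [10, 5]},
            index=["t1", "t2"],
        )
        conds = {"C_rep1": "C", "C_rep2": "C",
                 "D1_rep1": "D1", "D1_rep2": "D1"}
        fc = fold_change_matrix(counts, conds)
        np.testing.assert_allclose(fc["D1"], 0.0)

    def test_cpm_normalization_cancels_depth(self):
        # doubling one sample's depth must not change its condition FC
        counts = pd.DataFrame(
            {"C_rep1": [10, 90], "D1_rep1": [20, 180]}, index=["t1", "t2"]
        )
        fc = fold_change_matrix(
            counts, {"C_rep1": "C", "D1_rep1": "D1"}
        )
        np.testing.assert_allclose(fc["D1"], 0.0, atol=1e-12)


def _gene(gene_id, strand, start, chrom="chr1"):
    end = start + 2000
    if strand == "+":
        return GeneModel(gene_id, chrom, strand, start, end, start, start + 100,
                         [(start, start + 800), (start + 1000, end)])
    return GeneModel(gene_id, chrom, strand, start, end, end - 1, end - 101,
                     [(start, start + 1000), (start + 1200, end)])


class TestAnnotation:
    def test_promoter_bin(self):
        g = _gene("g1", "+", 5000)
        ths = _ths({"C"}, 4400, 4600)  # midpoint 4500, tss 5000
        (a,) = annotate_ths([ths], [g])
        assert a.tss_distance == -500
        assert a.category == "Promoter<=1kb"

    def test_exon_priority_over_distance_bins(self):
        g = _gene("g1", "+", 5000)
        ths = _ths({"C"}, 5500, 5700)  # midpoint 5600 inside exon1, past codon
        (a,) = annotate_ths([ths], [g])
        assert a.category == "Exon"

    def test_five_prime_utr_proxy(self):
        g = _gene("g1", "+", 5000)
        # midpoint 5050: inside first exon, upstream of the start codon 5100
        (a,) = annotate_ths([_ths({"C"}, 5000, 5100)], [g])
        assert a.category == "5UTR"

    def test_intron_and_downstream(self):
        g = _gene("g1", "+", 5000)
        (a,) = annotate_ths([_ths({"C"}, 5800, 6000)], [g])  # mid 5900
        assert a.category == "Intron"
        (a,) = annotate_ths([_ths({"C"}, 7100, 7300)], [g])  # mid 7200
        assert a.category == "Downstream<=1kb"

    def test_minus_strand_upstream_is_negative(self):
        g = _gene("g1", "-", 5000)  # tss 6999
        (a,) = annotate_ths([_ths({"C"}, 7300, 7500)], [g])  # mid 7400
        assert a.tss_distance == -401
        assert a.category == "Promoter<=1kb"

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        ga = _gene("gA", "+", 10_000)
        gb = _gene("gB", "-", 1001)  # tss 3000
        # midpoint 6500: 3500 from both TSSs
        (a,) = annotate_ths([_ths({"C"}, 6400, 6600)], [gb, ga])
        assert a.gene_id == "gA"

    def test_matches_brute_force_oracle(self, rng):
        genes = [
            _gene(f"g{i}", "+" if i % 2 else "-",
                  int(rng.integers(3000, 90_000)))
            for i in range(8)
        ]
        thss = []
        for _ in range(200):
            s = int(rng.integers(0, 99_000))
            thss.append(_ths({"C"}, s, s + int(rng.integers(50, 800))))
        for a in annotate_ths(thss, genes):
            gid, d, cat = annotate_oracle(a.ths.midpoint, genes)
            assert (a.gene_id, a.tss_distance, a.category) == (gid, d, cat)


class TestTermEnrichment:
    def test_foreground_equals_background(self):
        bg = {f"g{i}" for i in range(20)}
        tm = {"T1": {f"g{i}" for i in range(10)}}
        (res,) = term_enrichment(bg, bg, tm)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_extreme_case(self):
        bg = {f"g{i}" for i in range(20)}
        fg = {f"g{i}" for i in range(10)}
        tm = {"T1": set(fg)}
        (res,) = term_enrichment(fg, bg, tm)
        assert res.p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-12)
        assert res.q >= res.p

    def test_absent_term_skipped_with_warning(self):
        bg = {"g1", "g2"}
        with pytest.warns(UserWarning, match="skipped"):
            res = term_enrichment({"g1"}, bg, {"T1": {"zz"}})
        assert res == []

    def test_bh_q_never_below_p(self, rng):
        bg = {f"g{i}" for i in range(50)}
        fg = {f"g{i}" for i in range(0, 50, 3)}
        tm = {
            f"T{j}": {f"g{int(k)}" for k in rng.integers(0, 50, 12)}
            for j in range(8)
        }
        for res in term_enrichment(fg, bg, tm):
            assert res.q >= res.p - 1e-15
            assert res.k <= min(res.K, res.n)
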