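"""Promoter extraction, dinucleotide shuffling, word enrichment, PWM matching."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from oracles import dinucleotide_counts
from thstools.formats_io import GeneModel, Genome, revcomp
from thstools.motif_enrich import (
    PromoterRecord,
    PromoterSet,
    dinucleotide_shuffle,
    dreme_enrich,
    expand_iupac,
    extract_promoters,
    load_builtin_pwms,
    match_known_motifs,
    shuffle_negatives,
    word_to_matrix,
)


def _random_genome(rng, n=20_000):
    return Genome({"chr1": "".join(rng.choice(list("ACGT"), size=n))})


def _gene(gene_id, strand, codon, chrom="chr1"):
    if strand == "+":
        start, end = codon - 100, codon + 1900
        tss = start
        exons = [(start, end)]
    else:
        start, end = codon - 1899, codon + 101
        tss = end - 1
        exons = [(start, end)]
    return GeneModel(gene_id, chrom, strand, start, end, tss, codon, exons)


class TestExtractPromoters:
    def test_plus_strand_window(self, rng):
        genome = _random_genome(rng)
        g = _gene("g1", "+", 10_000)
        (rec,) = extract_promoters(["g1"], [g], genome).records
        assert rec.sequence == genome.fetch("chr1", 7000, 10_000)
        assert len(rec.sequence) == 3000
        assert not rec.clipped

    def test_minus_strand_reverse_complement(self, rng):
        genome = _random_genome(rng)
        g = _gene("g1", "-", 5000)
        (rec,) = extract_promoters(["g1"], [g], genome).records
        expected = revcomp(genome.fetch("chr1", 5001, 8001))
        assert rec.sequence == expected

    def test_contig_edge_clipping(self, rng):
        genome = _random_genome(rng)
        g = _gene("g1", "+", 1000)
        (rec,) = extract_promoters(["g1"], [g], genome).records
        assert len(rec.sequence) == 1000
        assert rec.clipped

    def test_unknown_gene(self, rng):
        with pytest.raises(KeyError):
            extract_promoters(["nope"], [_gene("g1", "+", 5000)],
                              _random_genome(rng))


class TestDinucleotideShuffle:
    def test_dinucleotide_conservation(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=150))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
            assert dinucleotide_counts(shuf) == dinucleotide_counts(seq)

    def test_degenerate_homopolymer(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    def test_deterministic_under_seed(self):
        ps = PromoterSet([PromoterRecord("g", "ACGTACGGTTACCGTA" * 10)])
        a = shuffle_negatives(ps, seed=5).records[0].sequence
        b = shuffle_negatives(ps, seed=5).records[0].sequence
        assert a == b

    def test_planted_word_diluted_in_shuffles(self, rng):
        # after shuffling, a planted hexamer appears at roughly the
        # background rate expected from composition
        word = "TTGACC"
        seqs = []
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), size=150))
            seqs.append(s[:50] + word + s[56:])
        ps = PromoterSet([PromoterRecord(f"g{i}", s) for i, s in enumerate(seqs)])
        shuf = shuffle_negatives(ps, seed=1)
        hits = sum(word in r.sequence for r in shuf.records)
        # ~145 positions x (1/4)^6 chance each -> mean ~7, sd ~2.7
        assert hits < 7 + 3 * 2.7 + 1


class TestDremeEnrich:
    def _sets(self, rng, n=60, length=150, planted=40, neg_planted=4,
              word="TTGACC"):
        def clean(n_):
            while True:
                s = "".join(rng.choice(list("ACGT"), size=n_))
                if word not in s and revcomp(word) not in s:
                    return s

        pos = [clean(length) for _ in range(n)]
        neg = [clean(length) for _ in range(n)]
        for i in range(planted):
            pos[i] = pos[i][:70] + word + pos[i][76:]
        for i in range(neg_planted):
            neg[i] = neg[i][:30] + word + neg[i][36:]
        return (
            PromoterSet([PromoterRecord(f"p{i}", s) for i, s in enumerate(pos)]),
            PromoterSet([PromoterRecord(f"n{i}", s) for i, s in enumerate(neg)]),
        )

    def test_planted_word_recovered_with_fisher_oracle(self, rng):
        pos, neg = self._sets(rng)
        results = dreme_enrich(pos, neg)
        assert results
        top = results[0]
        assert top.word in ("TTGACC", "GGTCAA")  # either strand's spelling
        table = [[top.pos_hits, top.n_pos - top.pos_hits],
                 [top.neg_hits, top.n_neg - top.neg_hits]]
        _, oracle_p = fisher_exact(table, alternative="greater")
        assert top.p == pytest.approx(oracle_p, rel=1e-10)
        assert top.evalue == pytest.approx(top.p * top.n_candidates)

    def test_null_control_reports_nothing(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(40)]
        ps = PromoterSet([PromoterRecord(f"g{i}", s) for i, s in enumerate(seqs)])
        same = PromoterSet([PromoterRecord(f"h{i}", s) for i, s in enumerate(seqs)])
        assert dreme_enrich(ps, same) == []

    def test_masking_strictly_reduces_hits(self, rng):
        pos, neg = self._sets(rng)
        results = dreme_enrich(pos, neg, max_motifs=3)
        top = results[0]
        # re-running on masked positives cannot find the word as often
        from thstools.motif_enrich import _mask_word, _word_index, _hits

        masked = [_mask_word(r.sequence, top.word, True) for r in pos.records]
        idx = _word_index(masked, 3, 8, True)
        assert _hits(top.word, idx) < top.pos_hits

    def test_reverse_strand_hit_counts(self):
        # GGTCAA on the written strand is a reverse-strand W-box hit
        pos = PromoterSet([
            PromoterRecord("a", "ACAGACCGATTGACCGATCGAAGCT"),
            PromoterRecord("b", "ACAGACCGAGGTCAAGATCGAAGCT"),
        ])
        from thstools.motif_enrich import _word_index, _hits

        idx = _word_index(pos.sequences(), 3, 8, both_strands=True)
        assert _hits("TTGACC", idx) == 2

    def test_empty_sets_rejected(self):
        ps = PromoterSet([PromoterRecord("g", "ACGT" * 30)])
        with pytest.raises(ValueError):
            dreme_enrich(ps, PromoterSet([]))


class TestPlantedRecoveryOnFixture:
    def test_planted_word_ranks_first(self):
        """The simulator's planted promoter element ranks first against
        dinucleotide-shuffled negatives on the standard synthetic study
        (default size: ~38 positive promoters of 3 kb)."""
        from thstools.synthetic_data import (
            SimulationConfig, simulate_genome_and_genes,
        )

        genome, genes, truth = simulate_genome_and_genes(
            SimulationConfig(seed=5)
        )
        planted_word = truth.motif_positions[0][1]
        pos_genes = sorted({
            g for g, _, _ in truth.motif_positions
            if g in set(truth.coupled_genes)
        })
        promoters = extract_promoters(pos_genes, genes, genome)
        negatives = shuffle_negatives(promoters, seed=0)
        results = dreme_enrich(promoters, negatives, max_motifs=2)
        assert results
        top = results[0]
        hits = set(expand_iupac(top.word)) | {
            revcomp(w) for w in expand_iupac(top.word)
        }
        assert any(
            planted_word in w or w in planted_word for w in hits
        )


class TestIupac:
    def test_expansions(self):
        assert set(expand_iupac("TTGACY")) == {"TTGACC", "TTGACT"}

    def test_word_matrix_rows_sum_to_one(self):
        m = word_to_matrix("TTGACY")
        np.testing.assert_allclose(m.sum(axis=1), 1.0)


class TestMatchKnownMotifs:
    def test_consensus_self_match(self):
        library = load_builtin_pwms()
        wbox = next(p for p in library if p.name == "WBOX_WRKY")
        (m,) = match_known_motifs([wbox.consensus], library, seed=0)
        assert m.pwm.name == "WBOX_WRKY"
        assert m.p < 0.05

    def test_reverse_complement_same_best_match(self):
        library = load_builtin_pwms()
        gata = next(p for p in library if p.name == "GATA_BOX")
        (fwd,) = match_known_motifs([gata.consensus], library, seed=0)
        (rev,) = match_known_motifs([revcomp(gata.consensus)], library, seed=0)
        assert fwd.pwm.name == rev.pwm.name == "GATA_BOX"
        assert fwd.score == pytest.approx(rev.score)

    def test_null_calibration_roughly_uniform(self, rng):
        from scipy.stats import kstest

        library = load_builtin_pwms()
        words = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(100)]
        matches = match_known_motifs(words, library, n_shuffles=200, seed=3)
        pvals = [m.p for m in matches]
        assert kstest(pvals, "uniform").pvalue > 0.01
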