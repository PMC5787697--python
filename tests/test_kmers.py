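"""k-mer counting, shuffled-ORF backgrounds, log2-odds scores."""

import numpy as np
import pytest

from clipshift.kmers import (
    EnrichmentScore,
    KmerTable,
    all_kmers,
    background_frequencies,
    count_kmers_in_windows,
    enrichment_scores,
    gc_fraction,
    gc_summary,
    _dinucleotide_shuffle,
)
from clipshift.peaks import Peak
from clipshift.synthetic import GeneModel, GenomeModel, TranscriptModel


def make_peak(chrom, anchor, strand="+", span=20, pid="p0"):
    return Peak(
        chromosome=chrom, start=anchor - span // 2, end=anchor + span // 2,
        strand=strand, n_reads=10, n_converted_reads=8, conversion_frequency=0.8,
        conversion_sites=[(anchor, 8)], anchor=anchor, peak_id=pid,
    )


def seq_genome(seq, name="chr1"):
    return GenomeModel(
        chromosomes=[(name, len(seq))], genes=[],
        sequence={name: np.array(list(seq))}, seed=0,
    )


class TestCounting:
    def test_no_peaks_zero_counts(self, toy_genome):
        tables = count_kmers_in_windows([], toy_genome, k=4)
        assert all(t.total == 0 for t in tables.values())

    def test_window_arithmetic_17_positions(self):
        g = seq_genome("A" * 200)
        t = count_kmers_in_windows(
            [make_peak("chr1", 100)], g, k=4, window=20, flank=20,
            mask_anchor=False, center="anchor",
        )
        assert t["site"].total == 17  # 20 - 4 + 1
        assert t["upstream"].total == 17 and t["downstream"].total == 17

    def test_gcgc_repeat_count_nine(self):
        # "GCGC"*5 fills the window; GCGC occurs at every even offset: 9 times
        g = seq_genome("A" * 90 + "GCGC" * 5 + "A" * 90)
        t = count_kmers_in_windows(
            [make_peak("chr1", 100)], g, k=4, mask_anchor=False, center="anchor",
        )
        assert t["site"].counts["GCGC"] == 9

    def test_minus_strand_counts_sense_kmers(self):
        g = seq_genome("A" * 90 + "GGGGGGGGGGGGGGGGGGGG" + "A" * 90)
        t = count_kmers_in_windows(
            [make_peak("chr1", 100, strand="-")], g, k=4,
            mask_anchor=False, center="anchor",
        )
        assert t["site"].counts.get("CCCC", 0) == 17

    def test_peaks_near_ends_skipped(self):
        g = seq_genome("A" * 100)
        t = count_kmers_in_windows([make_peak("chr1", 10)], g, k=4)
        assert all(tab.total == 0 for tab in t.values())

    def test_k_larger_than_window_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="window"):
            count_kmers_in_windows([], toy_genome, k=8, window=6)

    def test_percentile_mode_five_bins(self, clip_data, called_peaks):
        genome, _m, _r, _s = clip_data
        t = count_kmers_in_windows(called_peaks, genome, k=4, mode="percentile")
        assert set(t) == {"q1", "q2", "q3", "q4", "q5"}


class TestBackground:
    @staticmethod
    def orf_genome(seq):
        n = len(seq)
        tx = TranscriptModel("t1", ((0, n),), (0, n))
        gene = GeneModel("g1", "chr1", "+", "mRNA", (tx,))
        return GenomeModel([("chr1", n)], [gene], {"chr1": np.array(list(seq))}, 0)

    def test_mononucleotide_frequencies_shuffle_invariant(self):
        g = self.orf_genome("ACGT" * 25)
        bg = background_frequencies(g, k=1, n_shuffles=3, seed=0)
        for base in "ACGT":
            assert bg[base] == pytest.approx(0.25, abs=0.01)

    def test_shuffled_4mer_frequencies_match_composition_product(self):
        # composition-preserving shuffles make k-mer frequencies converge to
        # the product of the ORF's mononucleotide frequencies
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        mono = {b: seq.count(b) / len(seq) for b in "ACGT"}
        bg = background_frequencies(self.orf_genome(seq), k=4, n_shuffles=30, seed=1)
        vals = np.array([bg[k] for k in all_kmers(4)])
        expected = np.array(
            [np.prod([mono[c] for c in km]) for km in all_kmers(4)]
        )
        assert np.allclose(vals, expected, atol=3e-4)
        assert np.allclose(vals, 1 / 256, atol=8e-4)  # near-uniform composition
        assert vals.sum() == pytest.approx(1.0)

    def test_no_coding_genes_rejected(self):
        g = seq_genome("ACGT" * 10)
        with pytest.raises(ValueError, match="protein-coding"):
            background_frequencies(g, k=4)

    def test_deterministic_per_seed(self):
        g = self.orf_genome("ACGTTGCA" * 50)
        a = background_frequencies(g, k=4, n_shuffles=5, seed=7)
        b = background_frequencies(g, k=4, n_shuffles=5, seed=7)
        assert a == b

    def test_dinucleotide_shuffle_preserves_dinucleotides(self):
        rng = np.random.default_rng(3)
        seq = np.array(list("ACGTTGCAACGTGGCTAACG" * 5))

        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out

        shuffled = _dinucleotide_shuffle(seq, rng)
        assert dinucs("".join(shuffled)) == dinucs("".join(seq))
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestScores:
    def test_equal_frequencies_score_zero(self):
        t = KmerTable(k=1, region="site", counts={"A": 10, "C": 10, "G": 10, "T": 10})
        bg = t.frequencies()
        for s in enrichment_scores(t, bg):
            assert s.score == 0.0

    def test_sixteen_fold_enrichment_scores_four(self):
        # foreground frequency 1/16 vs background 1/256 -> log2(16) = 4
        t = KmerTable(k=4, region="site")
        t.counts = {km: 1_000_000 for km in all_kmers(4)[:16]}
        bg = {km: 1 / 256 for km in all_kmers(4)}
        scores = enrichment_scores(t, bg)
        assert scores[0].score == pytest.approx(4.0, abs=0.01)

    def test_scores_invariant_to_window_duplication(self, clip_data, called_peaks):
        # duplicating every foreground window rescales counts, not
        # frequencies, so scores move only by pseudocount dilution
        genome, _m, _r, _s = clip_data
        t1 = count_kmers_in_windows(called_peaks, genome, k=4)["site"]
        t2 = KmerTable(
            k=4, region="site",
            counts={km: 2 * c for km, c in t1.counts.items()},
            n_windows=2 * t1.n_windows,
        )
        bg = {km: 1 / 256 for km in all_kmers(4)}
        s1 = {s.kmer: s.score for s in enrichment_scores(t1, bg)}
        s2 = {s.kmer: s.score for s in enrichment_scores(t2, bg)}
        for km in all_kmers(4):
            if t1.counts.get(km, 0) >= 5:  # scores of unobserved k-mers are
                # pseudocount-dominated and legitimately shift under doubling
                assert s1[km] == pytest.approx(s2[km], abs=0.05)

    def test_odds_consistency(self, clip_data, called_peaks):
        genome, _m, _r, _s = clip_data
        tables = count_kmers_in_windows(called_peaks, genome, k=4)
        bg = background_frequencies(genome, k=4, n_shuffles=5, seed=2)
        scores = enrichment_scores(tables["site"], bg)
        total = sum(2**s.score * s.background_frequency for s in scores)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_gc_bias_ranks_gc_kmers_top(self, clip_data, called_peaks):
        genome, _m, _r, _s = clip_data
        tables = count_kmers_in_windows(called_peaks, genome, k=4)
        bg = background_frequencies(genome, k=4, n_shuffles=10, seed=3)
        scores = enrichment_scores(tables["site"], bg)
        assert all(gc_fraction(s.kmer) >= 0.75 for s in scores[:10])


class TestGcSummary:
    def test_all_zero_scores_zero_means(self):
        scores = [
            EnrichmentScore(km, "site", 0.0, 1 / 256, 1 / 256) for km in all_kmers(4)
        ]
        out = gc_summary(scores)
        assert out["site"]["gc_rich"]["mean_score"] == 0.0
        assert out["site"]["at_rich"]["mean_score"] == 0.0

    def test_two_kmer_arithmetic(self):
        scores = [
            EnrichmentScore("GGCC", "site", 2.0, 0, 0),
            EnrichmentScore("AATT", "site", -2.0, 0, 0),
        ]
        out = gc_summary(scores)
        assert out["site"]["gc_rich"] == {"mean_score": 2.0, "n_kmers": 1}
        assert out["site"]["at_rich"] == {"mean_score": -2.0, "n_kmers": 1}

    def test_empty_class_reported_missing(self):
        scores = [EnrichmentScore("GGCC", "site", 1.0, 0, 0)]
        out = gc_summary(scores)
        assert out["site"]["at_rich"] is None

    def test_planted_bias_separates_classes(self, clip_data, called_peaks):
        genome, _m, _r, _s = clip_data
        tables = count_kmers_in_windows(called_peaks, genome, k=4)
        bg = background_frequencies(genome, k=4, n_shuffles=5, seed=4)
        out = gc_summary(enrichment_scores(tables["site"], bg))
        assert out["site"]["gc_rich"]["mean_score"] > 0
        assert out["site"]["at_rich"]["mean_score"] < 0
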