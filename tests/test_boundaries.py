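"""Exon-boundary metaprofiles: uniqueness rules, offsets, backgrounds."""

import numpy as np
import pytest
from scipy import stats

import clipshift as cs
from clipshift.boundaries import (
    background_profiles,
    boundaries_from_exons,
    profile_coverage,
    unique_boundaries,
)
from clipshift.peaks import AlignedRead
from clipshift.synthetic import GeneModel, GenomeModel, TranscriptModel


def genome_with(genes, length=50_000):
    return GenomeModel(
        chromosomes=[("chr1", length)], genes=list(genes),
        sequence={"chr1": np.array(list("A" * length))}, seed=0,
    )


def mrna(gene_id, strand, exons):
    tx = TranscriptModel(f"{gene_id}.t1", tuple(exons), (exons[0][0], exons[-1][1]))
    return GeneModel(gene_id, "chr1", strand, "mRNA", (tx,))


def read(start, end, strand="+", copies=1):
    return AlignedRead("chr1", start, end, strand, copy_count=copies)


class TestUniqueBoundaries:
    def test_empty_annotation(self):
        ei, ie = unique_boundaries(genome_with([]))
        assert len(ei) == 0 and len(ie) == 0

    def test_three_exon_transcript_internal_junctions(self):
        g = genome_with([mrna("g1", "+", [(1000, 1200), (2000, 2200), (3000, 3200)])])
        ei, ie = unique_boundaries(g)
        assert len(ei) == 2 and len(ie) == 2
        # + strand: EI at exon ends (first intronic base), IE one base
        # before exon starts
        assert [b for _c, b, _s in ei.positions] == [1200, 2200]
        assert [b for _c, b, _s in ie.positions] == [1999, 2999]

    def test_shared_exon_end_deduplicated(self):
        shared = [(1000, 1200), (2000, 2200)]
        g = genome_with(
            [
                GeneModel(
                    "g1", "chr1", "+", "mRNA",
                    (
                        TranscriptModel("t1", tuple(shared), (1000, 2200)),
                        TranscriptModel(
                            "t2", ((1000, 1200), (2000, 2300)), (1000, 2300)
                        ),
                    ),
                )
            ]
        )
        ei, _ie = unique_boundaries(g)
        assert len(ei) == 1  # both transcripts end exon 1 at 1200

    def test_non_coding_genes_excluded(self):
        linc = GeneModel(
            "l1", "chr1", "+", "lincRNA",
            (TranscriptModel("lt", ((100, 200), (300, 400)), None),),
        )
        ei, ie = unique_boundaries(genome_with([linc]))
        assert len(ei) == 0 and len(ie) == 0

    def test_minus_strand_boundary_positions(self):
        g = genome_with([mrna("g1", "-", [(1000, 1200), (2000, 2200)])])
        ei, ie = unique_boundaries(g)
        # transcript runs right-to-left: exon at (2000,2200) is exon 1; its
        # 3' end is genomic start 2000, first intronic base 1999
        assert [b for _c, b, _s in ei.positions] == [1999]
        assert [b for _c, b, _s in ie.positions] == [1200]


class TestProfileCoverage:
    def test_no_reads_zero_profile(self):
        g = genome_with([mrna("g1", "+", [(1000, 1200), (2000, 2200)])])
        ei, _ = unique_boundaries(g)
        prof = profile_coverage([], ei)
        assert prof.counts.sum() == 0
        assert len(prof.counts) == 400

    def test_single_read_covers_exact_offsets(self):
        g = genome_with([mrna("g1", "+", [(1000, 1200), (2000, 2200)])])
        ei, _ = unique_boundaries(g)  # boundary base 1200
        # read spanning genomic [1195, 1211) = offsets -5..+10
        prof = profile_coverage([read(1195, 1211)], ei)
        covered = prof.offsets[prof.counts == 1]
        assert covered.tolist() == list(range(-5, 11))
        assert prof.counts.sum() == 16

    def test_copy_count_weighting(self):
        g = genome_with([mrna("g1", "+", [(1000, 1200), (2000, 2200)])])
        ei, _ = unique_boundaries(g)
        prof = profile_coverage([read(1195, 1211, copies=3)], ei)
        assert prof.counts.max() == 3

    def test_opposite_strand_reads_ignored(self):
        g = genome_with([mrna("g1", "+", [(1000, 1200), (2000, 2200)])])
        ei, _ = unique_boundaries(g)
        prof = profile_coverage([read(1195, 1211, strand="-")], ei)
        assert prof.counts.sum() == 0

    def test_default_depths_100_exonic_300_intronic(self):
        g = genome_with([mrna("g1", "+", [(1000, 1200), (2000, 2200)])])
        ei, _ = unique_boundaries(g)
        prof = profile_coverage([], ei)
        assert prof.offsets[0] == -100 and prof.offsets[-1] == 299

    def test_strand_mirror_invariance(self):
        """Flipping annotation and reads to the opposite strand (mirrored
        coordinates) leaves the transcript-oriented profile unchanged."""
        L = 50_000
        exons = [(1000, 1200), (2000, 2200), (3000, 3300)]
        reads_fwd = [read(1150, 1170), read(2195, 2215), read(2990, 3010)]
        g_fwd = genome_with([mrna("g1", "+", exons)], L)

        mirror = lambda s, e: (L - e, L - s)
        exons_rev = sorted(mirror(s, e) for s, e in exons)
        reads_rev = [
            read(*mirror(r.start, r.end), strand="-") for r in reads_fwd
        ]
        g_rev = genome_with([mrna("g1", "-", exons_rev)], L)

        for which in (0, 1):
            p_fwd = profile_coverage(reads_fwd, unique_boundaries(g_fwd)[which])
            p_rev = profile_coverage(reads_rev, unique_boundaries(g_rev)[which])
            assert np.array_equal(p_fwd.counts, p_rev.counts)

    def test_total_matches_per_boundary_brute_force(self, clip_data):
        genome, _m, reads, _s = clip_data
        sample = reads[:2000]
        ei, _ = unique_boundaries(genome)
        prof = profile_coverage(sample, ei)
        # brute force: for each boundary and offset, count overlapping reads
        total = 0
        for chrom, b, strand in ei.positions:
            step = 1 if strand == "+" else -1
            for off in range(-100, 300):
                pos = b + step * off
                total += sum(
                    r.copy_count
                    for r in sample
                    if r.chromosome == chrom
                    and r.strand == strand
                    and r.start <= pos < r.end
                )
        assert prof.counts.sum() == total


class TestBackgrounds:
    def test_zero_reads_zero_background(self, toy_genome):
        for method in ("shuffle-exons", "random-regions"):
            ei, ie = background_profiles(
                [], toy_genome, method, n_regions=200, region_length=1000, seed=0
            )
            assert ei.counts.sum() == 0 and ie.counts.sum() == 0

    def test_shuffle_preserves_exon_count(self, toy_genome):
        n_exons = sum(
            len(tx.exons)
            for g in toy_genome.genes
            if g.biotype == "mRNA"
            for tx in g.transcripts
        )
        ei, ie = background_profiles(
            [read(100, 120)], toy_genome, "shuffle-exons", seed=1
        )
        # every shuffled exon contributes one EI and one IE boundary
        # (minus rare placement collisions)
        assert ei.n_boundaries <= n_exons
        assert ei.n_boundaries >= 0.95 * n_exons

    def test_random_regions_split_half(self, toy_genome):
        ei, ie = background_profiles(
            [], toy_genome, "random-regions", n_regions=1000,
            region_length=2000, seed=2,
        )
        assert abs(ei.n_boundaries - ie.n_boundaries) <= 0.05 * 1000

    def test_region_longer_than_chromosome_warns(self):
        g = genome_with([], length=900)
        with pytest.raises(ValueError, match="long enough"):
            background_profiles([], g, "random-regions",
                                n_regions=10, region_length=1000, seed=0)

    def test_uniform_reads_give_flat_profiles(self):
        genome = cs.make_genome(
            cs.GenomeConfig(n_chromosomes=2, chromosome_length=400_000, n_genes=60),
            seed=31,
        )
        model = cs.BindingModel(background_rate=1.0, n_sites=10)
        reads, _ = cs.simulate_clip_reads(genome, model, n_reads=40_000, seed=32)
        ei, _ = unique_boundaries(genome)
        prof = profile_coverage(reads, ei)
        res = stats.linregress(prof.offsets, prof.counts)
        # total drift across the 400-bp window stays well below the mean level
        drift = abs(res.slope) * len(prof.offsets)
        assert drift < 0.3 * prof.counts.mean()

    def test_planted_flank_reads_exceed_backgrounds(self, clip_data):
        genome, _m, reads, _s = clip_data
        ei, _ = unique_boundaries(genome)
        prof = profile_coverage(reads, ei)
        sh_ei, _ = background_profiles(reads, genome, "shuffle-exons", seed=3)
        rr_ei, _ = background_profiles(
            reads, genome, "random-regions", n_regions=2000,
            region_length=5000, seed=3,
        )
        flank = slice(80, 100)  # exonic offsets -20..-1
        obs = prof.counts[flank].mean() / prof.n_boundaries
        for bg in (sh_ei, rr_ei):
            exp = max(bg.counts[flank].mean() / bg.n_boundaries, 1e-9)
            assert obs / exp > 2
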