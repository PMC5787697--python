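"""Synthetic-data generators: determinism, invariants, distributions."""

import numpy as np
import pytest
from scipy import stats

import clipshift as cs
from clipshift import io
from clipshift.synthetic import (
    DEFAULT_PROTEIN_GRID_M,
    TABLE_READ_LENGTHS,
    BindingModel,
    GenomeConfig,
    make_genome,
    simulate_clip_reads,
    simulate_competition,
    simulate_splice_events,
    simulate_titration,
)


class TestMakeGenome:
    def test_zero_genes(self):
        g = make_genome(GenomeConfig(n_genes=0), seed=0)
        assert g.genes == []

    def test_deterministic_per_seed(self):
        a, b = make_genome(seed=5), make_genome(seed=5)
        assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]
        assert all(
            np.array_equal(a.sequence[c], b.sequence[c]) for c, _ in a.chromosomes
        )
        c = make_genome(seed=6)
        assert any(
            not np.array_equal(a.sequence[n], c.sequence[n]) for n, _ in a.chromosomes
        )

    def test_exon_count_via_independent_gtf_parse(self, tmp_path):
        cfg = GenomeConfig(
            n_genes=10, exons_per_gene=(3, 3),
            biotype_mix={"mRNA": 1.0, "lincRNA": 0, "miRNA": 0, "snRNA": 0},
        )
        g = make_genome(cfg, seed=1)
        path = tmp_path / "ann.gtf"
        io.write_gtf(g, path)
        n_exons = sum(
            1 for line in open(path) if line.split("\t")[2] == "exon"
        )
        assert n_exons == 30

    def test_default_mix_includes_all_biotypes(self):
        g = make_genome(GenomeConfig(n_genes=80), seed=2)
        assert {x.biotype for x in g.genes} == {"mRNA", "lincRNA", "miRNA", "snRNA"}

    def test_annotation_invariants(self, toy_genome):
        lengths = dict(toy_genome.chromosomes)
        for gene in toy_genome.genes:
            assert 0 <= gene.start < gene.end <= lengths[gene.chromosome]
            for tx in gene.transcripts:
                for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
                    assert e1 <= s2  # ordered, non-overlapping
                if gene.biotype == "mRNA":
                    # UTR5 + CDS + UTR3 partition the exonic span
                    exonic = sum(e - s for s, e in tx.exons)
                    cs_, ce = tx.cds
                    cds_exonic = sum(
                        max(0, min(e, ce) - max(s, cs_)) for s, e in tx.exons
                    )
                    utr = sum(e - s for s, e in tx.utr5) + sum(
                        e - s for s, e in tx.utr3
                    )
                    assert cds_exonic + utr == exonic
                if gene.strand == "+":
                    assert gene.tss == tx.start
                else:
                    assert gene.tss == tx.end - 1

    def test_sequence_matches_declared_lengths(self, toy_genome):
        for name, length in toy_genome.chromosomes:
            assert len(toy_genome.sequence[name]) == length

    def test_oversized_gene_config_rejected(self):
        cfg = GenomeConfig(chromosome_length=2_000)
        with pytest.raises(ValueError, match="longer than the chromosome"):
            make_genome(cfg, seed=0)


class TestSimulateReads:
    def test_zero_reads(self, toy_genome):
        reads, _ = simulate_clip_reads(toy_genome, n_reads=0, seed=0)
        assert reads == []

    def test_reads_within_chromosome_bounds(self, clip_data):
        genome, _m, reads, _s = clip_data
        lengths = dict(genome.chromosomes)
        for r in reads:
            assert 0 <= r.start < r.end <= lengths[r.chromosome]
            assert len(r.mismatches) <= 1

    def test_deterministic_per_seed(self, toy_genome):
        r1, _ = simulate_clip_reads(toy_genome, n_reads=500, seed=9)
        r2, _ = simulate_clip_reads(toy_genome, n_reads=500, seed=9)
        assert [(a.chromosome, a.start, a.end, a.strand, a.mismatches) for a in r1] == [
            (a.chromosome, a.start, a.end, a.strand, a.mismatches) for a in r2
        ]

    def test_certain_conversion_when_read_has_T(self, toy_genome):
        model = BindingModel(conversion_probability=1.0, background_rate=0.0)
        reads, _ = simulate_clip_reads(toy_genome, model, n_reads=2000, seed=3)
        for r in reads:
            if "T" in r.sequence or r.mismatches:
                # sequence carries the conversion (T replaced by C), so any
                # site read that had a sense T must carry the record
                assert r.mismatches or "T" not in r.sequence

    def test_conversion_records_are_sense_ttc(self, clip_data):
        genome, _m, reads, _s = clip_data
        for r in reads:
            for off, ref, alt in r.mismatches:
                assert (ref, alt) == ("T", "C")
                gpos = r.start + off if r.strand == "+" else r.end - 1 - off
                base = genome.sequence[r.chromosome][gpos]
                expected = "T" if r.strand == "+" else "A"
                assert base == expected

    def test_length_distribution_matches_configured(self, toy_genome):
        reads, _ = simulate_clip_reads(toy_genome, n_reads=100_000, seed=4)
        lengths = np.array([r.length for r in reads])
        assert set(np.unique(lengths)) <= set(range(16, 24))
        support = sorted(TABLE_READ_LENGTHS)
        observed = np.array([(lengths == l).sum() for l in support])
        w = np.array([TABLE_READ_LENGTHS[l] for l in support], dtype=float)
        expected = w / w.sum() * len(lengths)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(support) - 1) > 0.01
        # modal length per the configured distribution
        assert support[np.argmax(observed)] in (20, 21)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError, match="conversion_probability"):
            BindingModel(conversion_probability=1.5)
        with pytest.raises(ValueError, match="16..23"):
            BindingModel(read_lengths={30: 1.0})


class TestSimulateSpliceEvents:
    def test_zero_events(self, toy_genome):
        assert simulate_splice_events(toy_genome, 0, seed=0) == []

    def test_negative_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            simulate_splice_events(toy_genome, -1, seed=0)

    def test_all_background_mix(self, toy_genome):
        evs = simulate_splice_events(toy_genome, 50, class_mix=(0, 0, 1), seed=1)
        assert all(ev.fdr > 0.5 for ev in evs)

    def test_class_structure(self, toy_genome):
        evs = simulate_splice_events(toy_genome, 300, seed=2)
        for ev in evs:
            if ev.true_class == "enhanced":
                assert ev.delta_psi >= 0.1 and ev.fdr <= 0.05
            elif ev.true_class == "silenced":
                assert ev.delta_psi <= -0.1 and ev.fdr <= 0.05
            else:
                assert ev.fdr > 0.5

    def test_classifier_recovers_planted_labels(self, toy_genome):
        evs = simulate_splice_events(
            toy_genome, 300, class_mix=(1 / 3, 1 / 3, 1 / 3), seed=3
        )
        cs.classify_events(evs)
        assert all(ev.event_class == ev.true_class for ev in evs)


class TestTitrationForwardModel:
    def test_zero_protein_zero_bound(self):
        s = simulate_titration(1.0, 1e6, concentrations=[0.0, 1e-6], noise_sd=0, seed=0)
        assert s.fraction_bound[0] == 0.0

    def test_midpoint_identity_any_n(self):
        for n in (0.5, 1.0, 1.75, 3.31):
            s = simulate_titration(n, 1e6, concentrations=[1e-6], noise_sd=0, seed=0)
            assert s.fraction_bound[0] == pytest.approx(0.5)

    def test_log_linearity_slope_two(self):
        # ln(bound/free) = n ln P + ln Kn must hold exactly for the forward model
        p = np.linspace(0.1e-6, 2.5e-6, 12)
        s = simulate_titration(2.0, 1e6, concentrations=p, noise_sd=0, seed=0)
        y = np.log(s.fraction_bound / (1 - s.fraction_bound))
        slopes = np.diff(y) / np.diff(np.log(p))
        assert np.allclose(slopes, 2.0)

    def test_closed_form_at_every_grid_point(self):
        p = DEFAULT_PROTEIN_GRID_M
        n, K = 1.75, 1.95e6
        s = simulate_titration(n, K, noise_sd=0, seed=0)
        expected = (K * p) ** n / (1 + (K * p) ** n)
        assert np.allclose(s.fraction_bound, expected, rtol=1e-12)

    def test_noise_clipped_and_deterministic(self):
        a = simulate_titration(1.0, 1e6, noise_sd=0.2, seed=7)
        b = simulate_titration(1.0, 1e6, noise_sd=0.2, seed=7)
        assert np.array_equal(a.fraction_bound, b.fraction_bound)
        assert np.all((a.fraction_bound >= 0) & (a.fraction_bound <= 1))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(1.0, 1e6, concentrations=[-1e-6], seed=0)


class TestCompetitionForwardModel:
    def test_symmetry_equal_affinities(self):
        s = simulate_competition(1, 1, 1e6, 1e6, noise_sd=0, seed=0)
        assert np.allclose(s.dna_free_fraction, s.rna_free_fraction)

    def test_default_grid_and_ligand_totals(self):
        s = simulate_competition(1, 1, 1e6, 1e6, noise_sd=0, seed=0)
        assert s.protein_M.max() == pytest.approx(2.5e-6)
        assert s.protein_M.min() == pytest.approx(0.05e-6)
        assert s.dna_total_M == pytest.approx(0.05e-6)
        assert s.rna_total_M == pytest.approx(0.05e-6)
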