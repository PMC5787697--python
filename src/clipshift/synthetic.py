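"""Synthetic genomes, PAR-CLIP reads, splice-event tables and gel-shift data.

Every generator is deterministic for a fixed seed and produces data with the
statistical structure the downstream analyses assume:

* toy genomes with mRNA / lincRNA / miRNA / snRNA genes, exon-intron
  structure, UTRs and promoters, over i.i.d. uniform background sequence;
* crosslink reads of 16-23 nt (default length frequencies follow the
  empirical read-length table of the source PAR-CLIP library, mode 20 nt)
  carrying sense-strand T-to-C conversions at planted binding sites;
* planted sites optionally GC-biased in sequence and enriched at
  exon-boundary flanks, intron bodies, or intergenic space;
* cassette-exon event tables with enhanced / silenced / background classes
  (|dPSI| >= 0.1 at FDR <= 0.05 for regulated classes, FDR > 0.5 for
  background) carrying their hidden truth labels;
* noisy single-step binding isotherms and equimolar DNA/RNA competition
  series on the 0.05-2.5 uM protein grid with 0.05 uM ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emsa import CompetitionSeries, TitrationSeries, fraction_bound
from .peaks import AlignedRead
from .splicemap import SpliceEvent

__all__ = [
    "GenomeConfig",
    "GenomeModel",
    "GeneModel",
    "TranscriptModel",
    "BindingModel",
    "BindingSite",
    "TABLE_READ_LENGTHS",
    "DEFAULT_PROTEIN_GRID_M",
    "make_genome",
    "plant_sites",
    "simulate_clip_reads",
    "simulate_splice_events",
    "simulate_titration",
    "simulate_competition",
]

# Empirical read-length counts of the sequenced crosslink library
# (16-23 nt); normalised as the default simulator length distribution.
TABLE_READ_LENGTHS = {
    16: 2142,
    17: 3897,
    18: 5271,
    19: 6894,
    20: 8935,
    21: 5883,
    22: 3535,
    23: 1888,
}

#: 12-point linear protein grid, 0.05-2.5 uM, in molar.
DEFAULT_PROTEIN_GRID_M = np.linspace(0.05e-6, 2.5e-6, 12)

#: ligand (probe) total concentration, molar
DEFAULT_LIGAND_TOTAL_M = 0.05e-6

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome + annotation


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    exons: tuple            # ((start, end), ...) genomic order, non-overlapping
    cds: tuple | None       # (start, end) genomic, mRNA only
    utr5: tuple = ()        # ((start, end), ...)
    utr3: tuple = ()

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    biotype: str            # mRNA | lincRNA | miRNA | snRNA
    transcripts: tuple

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """Transcription start: transcript start on +, last base on -."""
        t = self.transcripts[0]
        return t.start if self.strand == "+" else t.end - 1


@dataclass
class GenomeModel:
    chromosomes: list       # [(name, length)]
    genes: list
    sequence: dict          # name -> numpy char array over {A,C,G,T}
    seed: int

    def chrom_length(self, name: str) -> int:
        return dict(self.chromosomes)[name]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return "".join(self.sequence[chrom][start:end])


@dataclass(frozen=True)
class GenomeConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    n_genes: int = 30
    exons_per_gene: tuple = (3, 6)        # inclusive range, mRNA/lincRNA
    exon_length: tuple = (120, 300)
    intron_length: tuple = (300, 1500)
    utr5_length: int = 60
    utr3_length: int = 100
    intergenic_gap: tuple = (2_000, 12_000)
    biotype_mix: dict = field(
        default_factory=lambda: {
            "mRNA": 0.70,
            "lincRNA": 0.15,
            "miRNA": 0.075,
            "snRNA": 0.075,
        }
    )

    def validate(self):
        max_exons = self.exons_per_gene[1]
        max_span = (
            max_exons * self.exon_length[1]
            + (max_exons - 1) * self.intron_length[1]
        )
        if max_span > self.chromosome_length:
            raise ValueError(
                f"config allows genes up to {max_span} bp, longer than the "
                f"chromosome ({self.chromosome_length} bp)"
            )
        if abs(sum(self.biotype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_mix proportions must sum to 1")
        if self.exon_length[0] <= max(self.utr5_length, self.utr3_length):
            raise ValueError("exons must be longer than the UTRs they host")


def _make_gene(rng, gene_id, chrom, pos, cfg: GenomeConfig, biotype):
    strand = "+" if rng.random() < 0.5 else "-"
    if biotype == "miRNA":
        exon_lens = [int(rng.integers(60, 120))]
        intron_lens = []
    elif biotype == "snRNA":
        exon_lens = [int(rng.integers(100, 220))]
        intron_lens = []
    else:
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(*cfg.exon_length)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(*cfg.intron_length)) for _ in range(n_exons - 1)]
    exons = []
    p = pos
    for i, el in enumerate(exon_lens):
        exons.append((p, p + el))
        p += el
        if i < len(intron_lens):
            p += intron_lens[i]
    exons = tuple(exons)
    cds = utr5 = utr3 = None
    if biotype == "mRNA":
        # UTRs occupy the outermost exonic bases in transcript orientation;
        # CDS is the remaining exonic span, so UTR5+CDS+UTR3 partition exons
        first, last = exons[0], exons[-1]
        if strand == "+":
            utr5 = ((first[0], first[0] + cfg.utr5_length),)
            utr3 = ((last[1] - cfg.utr3_length, last[1]),)
            cds = (first[0] + cfg.utr5_length, last[1] - cfg.utr3_length)
        else:
            utr5 = ((last[1] - cfg.utr5_length, last[1]),)
            utr3 = ((first[0], first[0] + cfg.utr3_length),)
            cds = (first[0] + cfg.utr3_length, last[1] - cfg.utr5_length)
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        exons=exons,
        cds=cds,
        utr5=utr5 or (),
        utr3=utr3 or (),
    )
    return GeneModel(gene_id, chrom, strand, biotype, (tx,)), p


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Deterministic toy genome with internally consistent annotation."""
    if config is None:
        config = GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", config.chromosome_length) for i in range(config.n_chromosomes)]
    sequence = {
        name: BASES[rng.integers(0, 4, size=length)] for name, length in chroms
    }
    biotypes = list(config.biotype_mix)
    probs = np.array([config.biotype_mix[b] for b in biotypes])
    genes = []
    gi = 0
    ci = 0
    pos = int(rng.integers(*config.intergenic_gap))
    while gi < config.n_genes and ci < len(chroms):
        chrom, clen = chroms[ci]
        biotype = biotypes[int(rng.choice(len(biotypes), p=probs))]
        gene, gene_end = _make_gene(rng, f"gene_{gi:04d}", chrom, pos, config, biotype)
        if gene_end >= clen:  # no room left on this chromosome
            ci += 1
            pos = int(rng.integers(*config.intergenic_gap))
            continue
        genes.append(gene)
        gi += 1
        pos = gene_end + int(rng.integers(*config.intergenic_gap))
        if pos >= clen:
            ci += 1
            pos = int(rng.integers(*config.intergenic_gap))
    return GenomeModel(chromosomes=chroms, genes=genes, sequence=sequence, seed=seed)


# ---------------------------------------------------------------------------
# binding sites + reads


@dataclass(frozen=True)
class BindingModel:
    """Generative model for crosslink sites and reads."""

    region_weights: dict = field(
        default_factory=lambda: {
            "exon_boundary": 1.0,
            "intron": 1.0,
            "intergenic": 1.0,
        }
    )
    gc_bias_exponent: float = 0.0   # 0 = no sequence bias within sites
    conversion_probability: float = 0.8
    background_rate: float = 0.1    # fraction of reads not drawn from sites
    n_sites: int = 200
    site_length: int = 20
    boundary_flank: int = 20        # exonic flank width at exon 3' ends
    read_lengths: dict = field(default_factory=lambda: dict(TABLE_READ_LENGTHS))

    def __post_init__(self):
        if not 0 <= self.conversion_probability <= 1:
            raise ValueError("conversion_probability must be in [0, 1]")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        if not set(self.read_lengths) <= set(range(16, 24)):
            raise ValueError("read-length support must be within 16..23 nt")

    def length_distribution(self):
        lengths = np.array(sorted(self.read_lengths))
        w = np.array([self.read_lengths[l] for l in lengths], dtype=float)
        return lengths, w / w.sum()


@dataclass(frozen=True)
class BindingSite:
    chromosome: str
    start: int
    end: int
    strand: str
    region_class: str

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _candidate_positions(genome: GenomeModel, model: BindingModel):
    """Per region class: list of (chrom, anchor position, strand)."""
    half = model.site_length // 2
    boundary, intron, genic_mask = [], [], {}
    for name, length in genome.chromosomes:
        genic_mask[name] = np.zeros(length, dtype=bool)
    for g in genome.genes:
        tx = g.transcripts[0]
        genic_mask[g.chromosome][g.start:g.end] = True
        exons = tx.exons
        for i, (es, ee) in enumerate(exons):
            # exon 3'-end flank (transcript orientation) of internal exons
            is_internal_3p = (g.strand == "+" and i < len(exons) - 1) or (
                g.strand == "-" and i > 0
            )
            if is_internal_3p:
                anchor = ee - model.boundary_flank // 2 if g.strand == "+" else es + model.boundary_flank // 2
                boundary.append((g.chromosome, anchor, g.strand))
        for i in range(len(exons) - 1):
            is_, ie_ = exons[i][1], exons[i + 1][0]
            if ie_ - is_ > model.site_length + 100:
                for p in range(is_ + 50, ie_ - 50, 100):
                    intron.append((g.chromosome, p, g.strand))
    intergenic = []
    for name, length in genome.chromosomes:
        free = np.flatnonzero(~genic_mask[name][half + 50 : length - half - 50])
        if len(free):
            step = max(1, len(free) // 3000)
            for p in free[::step]:
                intergenic.append((name, int(p) + half + 50, None))
    return {"exon_boundary": boundary, "intron": intron, "intergenic": intergenic}


def plant_sites(genome: GenomeModel, model: BindingModel, seed: int = 0):
    """Choose binding-site windows and (if GC-biased) rewrite their sequence.

    Site anchors are drawn from the three region classes with the configured
    weights.  With ``gc_bias_exponent`` b > 0 each site base is redrawn with
    per-base G/C probability e^b / (1 + e^b) (b = 0 recovers uniform), which
    plants the GC-rich site composition against the uniform background.
    Modifies ``genome.sequence`` in place for biased sites.
    """
    rng = np.random.default_rng(seed)
    cands = _candidate_positions(genome, model)
    classes = [c for c in ("exon_boundary", "intron", "intergenic") if cands[c]]
    w = np.array([model.region_weights.get(c, 0.0) for c in classes], dtype=float)
    if w.sum() <= 0:
        raise ValueError("region weights must include at least one positive class")
    w = w / w.sum()
    half = model.site_length // 2
    sites = []
    b = model.gc_bias_exponent
    p_gc = np.exp(b) / (1.0 + np.exp(b))
    base_probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    for _ in range(model.n_sites):
        cls = classes[int(rng.choice(len(classes), p=w))]
        chrom, anchor, strand = cands[cls][int(rng.integers(len(cands[cls])))]
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        start, end = anchor - half, anchor - half + model.site_length
        clen = genome.chrom_length(chrom)
        start = max(0, min(start, clen - model.site_length))
        end = start + model.site_length
        if b > 0:
            genome.sequence[chrom][start:end] = BASES[
                rng.choice(4, size=model.site_length, p=base_probs)
            ]
        sites.append(BindingSite(chrom, start, end, strand, cls))
    return sites


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _sense_sequence(genome, chrom, start, end, strand):
    seq = genome.fetch(chrom, start, end)
    if strand == "-":
        seq = "".join(_COMPLEMENT[c] for c in reversed(seq))
    return seq


def simulate_clip_reads(
    genome: GenomeModel,
    model: BindingModel | None = None,
    n_reads: int = 10_000,
    seed: int = 0,
    sites=None,
):
    """Simulate collapsed crosslink reads.

    Site-derived reads overlap a planted site anchor and, with the configured
    probability, carry one sense-strand T-to-C conversion at a uniformly
    chosen T of the read (at most one mismatch per read).  Background reads
    are uniform over the genome with random strand and no conversions.
    Returns ``(reads, sites)``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if model is None:
        model = BindingModel()
    rng = np.random.default_rng(seed)
    if sites is None:
        sites = plant_sites(genome, model, seed=seed + 1 if seed < 2**31 - 1 else 0)
    lengths, lprobs = model.length_distribution()
    reads = []
    for i in range(n_reads):
        rl = int(lengths[int(rng.choice(len(lengths), p=lprobs))])
        if sites and rng.random() >= model.background_rate:
            site = sites[int(rng.integers(len(sites)))]
            anchor = site.center
            # uniform among start positions whose read covers the anchor
            offset = int(rng.integers(rl))
            start = anchor - offset
            chrom, strand = site.chromosome, site.strand
            from_site = True
        else:
            chrom, clen_ = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
            start = int(rng.integers(0, clen_ - rl))
            strand = "+" if rng.random() < 0.5 else "-"
            from_site = False
        clen = genome.chrom_length(chrom)
        start = max(0, min(start, clen - rl))
        end = start + rl
        seq = _sense_sequence(genome, chrom, start, end, strand)
        mismatches = ()
        if from_site and rng.random() < model.conversion_probability:
            t_offsets = [j for j, c in enumerate(seq) if c == "T"]
            if t_offsets:
                off = t_offsets[int(rng.integers(len(t_offsets)))]
                seq = seq[:off] + "C" + seq[off + 1:]
                mismatches = ((off, "T", "C"),)
        reads.append(
            AlignedRead(
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand,
                sequence=seq,
                mismatches=mismatches,
                copy_count=1,
                read_id=f"read_{i}",
            )
        )
    return reads, sites


# ---------------------------------------------------------------------------
# splice events


def simulate_splice_events(
    genome: GenomeModel,
    n_events: int,
    class_mix=(1 / 3, 1 / 3, 1 / 3),
    effect=None,
    seed: int = 0,
):
    """Cassette-exon event table with planted regulatory classes.

    ``class_mix`` gives (enhanced, silenced, background) proportions;
    ``effect`` optionally overrides the per-class |dPSI| sampling ranges.
    Events are consistent exon trios on one strand; the planted class is
    recorded in ``true_class``.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    mix = np.asarray(class_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("class_mix must be nonnegative and sum to 1")
    if effect is None:
        effect = {"enhanced": (0.1, 0.5), "silenced": (0.1, 0.5)}
    rng = np.random.default_rng(seed)
    labels = ["enhanced", "silenced", "background"]
    events = []
    for i in range(n_events):
        cls = labels[int(rng.choice(3, p=mix))]
        chrom, clen = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        strand = "+" if rng.random() < 0.5 else "-"
        up_len = int(rng.integers(100, 250))
        cas_len = int(rng.integers(80, 200))
        down_len = int(rng.integers(100, 250))
        i1 = int(rng.integers(400, 1200))
        i2 = int(rng.integers(400, 1200))
        span = up_len + i1 + cas_len + i2 + down_len
        g0 = int(rng.integers(0, clen - span))
        # genomic left-to-right: first, intron, cassette, intron, last
        first = (g0, g0 + up_len)
        cas = (first[1] + i1, first[1] + i1 + cas_len)
        last = (cas[1] + i2, cas[1] + i2 + down_len)
        if strand == "+":
            up, down = first, last
        else:
            up, down = last, first
        if cls == "enhanced":
            dpsi = float(rng.uniform(*effect["enhanced"]))
            fdr = float(rng.uniform(1e-4, 0.05))
            p = fdr * float(rng.uniform(0.05, 1.0))
        elif cls == "silenced":
            dpsi = -float(rng.uniform(*effect["silenced"]))
            fdr = float(rng.uniform(1e-4, 0.05))
            p = fdr * float(rng.uniform(0.05, 1.0))
        else:
            dpsi = float(rng.uniform(-0.05, 0.05))
            fdr = float(rng.uniform(0.5 + 1e-6, 1.0))
            p = float(rng.uniform(0.1, 1.0))
        events.append(
            SpliceEvent(
                chromosome=chrom,
                strand=strand,
                cassette_start=cas[0],
                cassette_end=cas[1],
                upstream_start=up[0],
                upstream_end=up[1],
                downstream_start=down[0],
                downstream_end=down[1],
                delta_psi=dpsi,
                p_value=p,
                fdr=fdr,
                event_id=f"se_{i:05d}",
                true_class=cls,
            )
        )
    return events


# ---------------------------------------------------------------------------
# gel-shift forward models


def simulate_titration(
    n_true: float,
    K_true: float,
    concentrations=None,
    noise_sd: float = 0.03,
    seed: int = 0,
    ligand_total_M: float = DEFAULT_LIGAND_TOTAL_M,
    species: str = "RNA",
) -> TitrationSeries:
    """Noisy single-step isotherm: fb = Kn P^n / (1 + Kn P^n), Kn = K^n.

    Gaussian noise (sd ``noise_sd``) is added to the measured fractions and
    the result clipped to [0, 1], mirroring phosphor-image quantification.
    """
    if concentrations is None:
        concentrations = DEFAULT_PROTEIN_GRID_M
    p = np.asarray(concentrations, dtype=float)
    if np.any(p < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    fb = fraction_bound(p, n_true, K_true)
    if noise_sd > 0:
        fb = fb + rng.normal(0.0, noise_sd, size=fb.shape)
    return TitrationSeries(
        protein_M=p,
        fraction_bound=np.clip(fb, 0.0, 1.0),
        species=species,
        ligand_total_M=ligand_total_M,
    )


def simulate_competition(
    m: float,
    n: float,
    K_DNA: float,
    K_RNA: float,
    concentrations=None,
    noise_sd: float = 0.03,
    seed: int = 0,
    ligand_total_M: float = DEFAULT_LIGAND_TOTAL_M,
) -> CompetitionSeries:
    """Equimolar DNA/RNA competition in the trace-ligand regime.

    Each species independently follows the single-step model, so its free
    fraction is 1 / (1 + K_s^s P^s).  Noise as in :func:`simulate_titration`.
    The generating ratio K_DNA/K_RNA is recoverable by
    :func:`clipshift.emsa.competition_ratio`.
    """
    if concentrations is None:
        concentrations = DEFAULT_PROTEIN_GRID_M
    p = np.asarray(concentrations, dtype=float)
    if np.any(p < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    free_d = 1.0 - fraction_bound(p, m, K_DNA)
    free_r = 1.0 - fraction_bound(p, n, K_RNA)
    if noise_sd > 0:
        free_d = free_d + rng.normal(0.0, noise_sd, size=p.shape)
        free_r = free_r + rng.normal(0.0, noise_sd, size=p.shape)
    return CompetitionSeries(
        protein_M=p,
        dna_free_fraction=np.clip(free_d, 0.0, 1.0),
        rna_free_fraction=np.clip(free_r, 0.0, 1.0),
        m=m,
        n=n,
        dna_total_M=ligand_total_M,
        rna_total_M=ligand_total_M,
    )
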