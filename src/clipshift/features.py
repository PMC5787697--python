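"""Genomic feature assignment for binding-site peaks.

Each peak is assigned to exactly one of six categories by its anchor base
(the crosslink-supported position): 5'UTR, 3'UTR, exon (CDS exon), promoter,
intron, or intergenic.  Overlapping features resolve by that fixed
precedence; assignment is same-strand only, so a peak antisense to the only
overlapping gene is intergenic (sense-strand RNA evidence cannot come from
the antisense gene).  The promoter is a fixed-width window upstream of the
TSS (default 1000 bp).

Intergenic peaks are then "rescued" by proximity to annotated coding ends:
a peak within 10 kb downstream of a CDS stop codon, or within 10 kb
upstream of a CDS start codon (same strand), is flagged as a candidate
unannotated UTR extension.  Remaining peaks can be matched against a
user-supplied secondary annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "FeatureAssignment",
    "FeatureIndex",
    "CATEGORY_PRECEDENCE",
    "RESCUE_DISTANCE_BP",
    "build_feature_index",
    "assign_peak",
    "assign_peaks",
    "rescue_intergenic",
    "classify_rna_type",
    "category_proportions",
]

CATEGORY_PRECEDENCE = ("utr5", "utr3", "exon", "promoter", "intron")
RESCUE_DISTANCE_BP = 10_000


@dataclass
class FeatureAssignment:
    peak_id: str
    category: str                    # utr5 | utr3 | exon | promoter | intron | intergenic
    gene_id: str | None = None
    rescue_status: str | None = None  # intergenic only
    distance_bp: int | None = None    # intergenic only


class FeatureIndex:
    """Interval trees per (chromosome, strand) per category, plus the
    CDS start/stop codon tables used for intergenic rescue."""

    def __init__(self, chromosome_lengths):
        self.chromosome_lengths = dict(chromosome_lengths)
        self.trees: dict = {}           # (chrom, strand, category) -> IntervalTree
        self.stop_codons: list = []     # (chrom, strand, position, gene_id)
        self.start_codons: list = []
        self.biotypes: dict = {}        # gene_id -> biotype

    def _tree(self, chrom, strand, category) -> IntervalTree:
        return self.trees.setdefault((chrom, strand, category), IntervalTree())

    def add(self, chrom, strand, category, start, end, gene_id):
        if end <= start:
            raise ValueError(
                f"malformed {category} interval [{start}, {end}) for {gene_id}"
            )
        self._tree(chrom, strand, category).addi(start, end, gene_id)

    def lookup(self, chrom, strand, position):
        """(category, gene_id) at one base, same strand, by precedence."""
        for category in CATEGORY_PRECEDENCE:
            tree = self.trees.get((chrom, strand, category))
            if tree:
                hits = tree[position]
                if hits:
                    gid = sorted(iv.data for iv in hits)[0]
                    return category, gid
        return "intergenic", None


def build_feature_index(genome, promoter_width: int = 1000) -> FeatureIndex:
    """Index a GenomeModel's annotation for anchor-base lookup.

    For mRNA genes the "exon" category holds CDS-exon segments (exonic bases
    minus UTRs); non-coding gene exons are plain exons.  Introns are the
    transcript span minus exonic bases.  The promoter is ``promoter_width``
    bases immediately upstream of the TSS on the gene strand.
    """
    index = FeatureIndex(genome.chromosomes)
    for gene in genome.genes:
        index.biotypes[gene.gene_id] = gene.biotype
        chrom, strand, gid = gene.chromosome, gene.strand, gene.gene_id
        clen = index.chromosome_lengths[chrom]
        for tx in gene.transcripts:
            utr = list(tx.utr5) + list(tx.utr3)
            for s, e in tx.utr5:
                index.add(chrom, strand, "utr5", s, e, gid)
            for s, e in tx.utr3:
                index.add(chrom, strand, "utr3", s, e, gid)
            for es, ee in tx.exons:
                # subtract UTR intervals from the exon to leave CDS exon
                pieces = [(es, ee)]
                for us, ue in utr:
                    pieces = [
                        seg
                        for (ps, pe) in pieces
                        for seg in ((ps, min(pe, us)), (max(ps, ue), pe))
                        if seg[1] > seg[0]
                    ] if us < ee and ue > es else pieces
                for ps, pe in pieces:
                    index.add(chrom, strand, "exon", ps, pe, gid)
            for i in range(len(tx.exons) - 1):
                is_, ie_ = tx.exons[i][1], tx.exons[i + 1][0]
                if ie_ > is_:
                    index.add(chrom, strand, "intron", is_, ie_, gid)
            if tx.cds is not None:
                cs, ce = tx.cds
                if strand == "+":
                    index.start_codons.append((chrom, strand, cs, gid))
                    index.stop_codons.append((chrom, strand, ce - 1, gid))
                else:
                    index.start_codons.append((chrom, strand, ce - 1, gid))
                    index.stop_codons.append((chrom, strand, cs, gid))
        tss = gene.tss
        if strand == "+":
            ps, pe = max(0, tss - promoter_width), tss
        else:
            ps, pe = tss + 1, min(clen, tss + 1 + promoter_width)
        if pe > ps:
            index.add(chrom, strand, "promoter", ps, pe, gid)
    return index


def assign_peak(peak, index: FeatureIndex) -> FeatureAssignment:
    """Categorise one peak by its anchor base."""
    clen = index.chromosome_lengths.get(peak.chromosome)
    if clen is None or not 0 <= peak.anchor < clen:
        raise ValueError(
            f"peak {peak.peak_id}: anchor {peak.anchor} off chromosome "
            f"{peak.chromosome}"
        )
    category, gid = index.lookup(peak.chromosome, peak.strand, peak.anchor)
    return FeatureAssignment(peak_id=peak.peak_id, category=category, gene_id=gid)


def assign_peaks(peaks, index: FeatureIndex):
    return [assign_peak(pk, index) for pk in peaks]


def _codon_distance(codons, chrom, strand, pos, side):
    """Distance to the nearest codon with the anchor on the stated side of
    it in transcript orientation ('downstream' of stops, 'upstream' of
    starts).  Returns (distance, gene_id) or (None, None)."""
    best = (None, None)
    for c_chrom, c_strand, c_pos, gid in codons:
        if c_chrom != chrom or c_strand != strand:
            continue
        delta = pos - c_pos if strand == "+" else c_pos - pos
        ok = delta >= 0 if side == "downstream" else delta <= 0
        if ok:
            d = abs(delta)
            if best[0] is None or d < best[0]:
                best = (d, gid)
    return best


def rescue_intergenic(
    assignments,
    peaks,
    index: FeatureIndex,
    secondary=None,
    max_distance: int = RESCUE_DISTANCE_BP,
):
    """Annotate intergenic peaks by proximity to CDS stop/start codons.

    Updates assignments in place and returns ``(assignments, curve)`` where
    ``curve`` is the nondecreasing cumulative count of intergenic peaks
    within each observed distance of their nearest codon.

    ``secondary`` is an optional DataFrame of intervals (columns chromosome,
    start, end) from another annotation source; unrescued peaks overlapping
    it get status ``other-annotation``.

    Equidistant stop and start codons resolve to the stop (the 3'UTR
    extension reading).  Non-intergenic assignments are never modified.
    """
    peak_by_id = {pk.peak_id: pk for pk in peaks}
    sec_trees: dict = {}
    if secondary is not None:
        for row in secondary.itertuples(index=False):
            sec_trees.setdefault(row.chromosome, IntervalTree()).addi(
                int(row.start), int(row.end)
            )
    distances = []
    for a in assignments:
        if a.category != "intergenic":
            continue
        pk = peak_by_id[a.peak_id]
        d_stop, g_stop = _codon_distance(
            index.stop_codons, pk.chromosome, pk.strand, pk.anchor, "downstream"
        )
        d_start, g_start = _codon_distance(
            index.start_codons, pk.chromosome, pk.strand, pk.anchor, "upstream"
        )
        cand = []
        if d_stop is not None:
            cand.append((d_stop, 0, "within-10kb-of-stop", g_stop))
        if d_start is not None:
            cand.append((d_start, 1, "within-10kb-of-start", g_start))
        if cand:
            d, _prio, status, gid = min(cand)
            a.distance_bp = int(d)
            distances.append(int(d))
            if d <= max_distance:
                a.rescue_status = status
                a.gene_id = gid
                continue
        tree = sec_trees.get(pk.chromosome)
        if tree is not None and tree[pk.anchor]:
            a.rescue_status = "other-annotation"
        else:
            a.rescue_status = "unresolved"
    if distances:
        ds = sorted(distances)
        curve = pd.DataFrame(
            {"distance_bp": ds, "cumulative_count": range(1, len(ds) + 1)}
        )
    else:
        curve = pd.DataFrame({"distance_bp": [], "cumulative_count": []})
    return assignments, curve


def classify_rna_type(assignments, index: FeatureIndex) -> pd.DataFrame:
    """Peak counts and proportions per gene biotype (genic peaks only)."""
    counts: dict = {}
    for a in assignments:
        if a.gene_id is not None and a.category != "intergenic":
            bt = index.biotypes.get(a.gene_id, "unknown")
            counts[bt] = counts.get(bt, 0) + 1
    total = sum(counts.values())
    rows = [
        {"biotype": bt, "n_peaks": n, "proportion": n / total}
        for bt, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["biotype", "n_peaks", "proportion"])


def category_proportions(assignments) -> dict:
    """Proportion of peaks per category; values sum to 1 over all peaks."""
    counts: dict = {}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()} if total else {}
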