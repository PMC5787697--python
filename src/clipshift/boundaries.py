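"""Coverage metaprofiles at exon-intron (EI) and intron-exon (IE) boundaries.

For every unique boundary of protein-coding transcripts, read coverage is
accumulated at transcript-oriented offsets: 100 bases into the exon
(negative offsets) and 300 bases into the intron (offset 0 is the first
intronic base).  Coverage counts reads (or peaks) overlapping each base,
weighted by copy_count.

Uniqueness follows the strand-resolved rule: EI boundaries are deduplicated
exon 3'-end locations (exon ends on the forward strand, exon starts on the
reverse strand); IE boundaries are deduplicated exon 5'-start locations.
Terminal exon ends with no adjacent intron are excluded.

Two background randomizations are provided: re-placing exons per chromosome
while preserving their number and sizes (shuffle-exons), and uniform random
regions whose starts act as EI boundaries and ends as IE boundaries
(random-regions), mirroring the two standard null constructions for this
kind of metaprofile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoundarySet",
    "MetaProfile",
    "unique_boundaries",
    "profile_coverage",
    "background_profiles",
    "boundaries_from_exons",
]

EXON_DEPTH = 100
INTRON_DEPTH = 300


@dataclass
class BoundarySet:
    boundary_type: str          # "EI" or "IE"
    positions: list             # [(chromosome, boundary base, strand)]
    provenance: str = "annotation"
    chromosome_lengths: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.positions)


def _direction(boundary_type: str, strand: str) -> int:
    """Genomic step per +1 transcript-oriented offset (offset 0 = first
    intronic base; the intron lies after the exon for EI, before it for IE)."""
    if boundary_type == "EI":
        return 1 if strand == "+" else -1
    return -1 if strand == "+" else 1


def boundaries_from_exons(exons, chromosome_lengths, provenance="annotation",
                          internal_only=True):
    """Build deduplicated EI / IE boundary sets from exon records.

    ``exons`` is an iterable of (chromosome, start, end, strand,
    has_downstream_intron, has_upstream_intron); with ``internal_only``
    False every exon contributes both boundaries.
    """
    ei, ie = set(), set()
    for chrom, start, end, strand, has_down, has_up in exons:
        if not internal_only:
            has_down = has_up = True
        if has_down:  # exon 3' end -> intron
            b = end if strand == "+" else start - 1
            ei.add((chrom, b, strand))
        if has_up:    # intron -> exon 5' start
            b = start - 1 if strand == "+" else end
            ie.add((chrom, b, strand))
    mk = lambda typ, ps: BoundarySet(
        boundary_type=typ,
        positions=sorted(ps),
        provenance=provenance,
        chromosome_lengths=dict(chromosome_lengths),
    )
    return mk("EI", ei), mk("IE", ie)


def unique_boundaries(genome):
    """(EI, IE) boundary sets from the protein-coding transcripts of a
    GenomeModel."""
    records = []
    for gene in genome.genes:
        if gene.biotype != "mRNA":
            continue
        for tx in gene.transcripts:
            n = len(tx.exons)
            for i, (es, ee) in enumerate(tx.exons):
                if gene.strand == "+":
                    has_down = i < n - 1   # intron follows the exon 3' end
                    has_up = i > 0
                else:
                    has_down = i > 0       # transcript 3' end is the genomic start
                    has_up = i < n - 1
                records.append((gene.chromosome, es, ee, gene.strand, has_down, has_up))
    return boundaries_from_exons(records, dict(genome.chromosomes))


@dataclass
class MetaProfile:
    boundary_type: str
    offsets: np.ndarray            # -exon_depth .. intron_depth-1
    counts: np.ndarray             # copy-weighted coverage sums
    n_boundaries: int
    backgrounds: dict = field(default_factory=dict)   # method -> MetaProfile


def _coverage_arrays(intervals, chromosome_lengths):
    """(chrom, strand) -> per-base copy-weighted coverage."""
    cov = {}
    for iv in intervals:
        key = (iv.chromosome, iv.strand)
        if key not in cov:
            cov[key] = np.zeros(chromosome_lengths[iv.chromosome] + 1, dtype=np.int64)
        w = getattr(iv, "copy_count", 1)
        cov[key][iv.start] += w
        cov[key][iv.end] -= w
    return {k: np.cumsum(v)[:-1] for k, v in cov.items()}


def profile_coverage(
    intervals,
    boundaries: BoundarySet,
    exon_depth: int = EXON_DEPTH,
    intron_depth: int = INTRON_DEPTH,
) -> MetaProfile:
    """Aggregate same-strand coverage around every boundary.

    Boundaries near the next feature are counted in full (no truncation);
    offsets that run off the chromosome contribute nothing.
    """
    offsets = np.arange(-exon_depth, intron_depth)
    counts = np.zeros(len(offsets), dtype=np.int64)
    cov = _coverage_arrays(intervals, boundaries.chromosome_lengths)
    for chrom, b, strand in boundaries.positions:
        arr = cov.get((chrom, strand))
        if arr is None:
            continue
        step = _direction(boundaries.boundary_type, strand)
        pos = b + step * offsets
        ok = (pos >= 0) & (pos < len(arr))
        counts[ok] += arr[pos[ok]]
    return MetaProfile(
        boundary_type=boundaries.boundary_type,
        offsets=offsets,
        counts=counts,
        n_boundaries=len(boundaries),
    )


def _shuffled_exon_boundaries(genome, rng):
    """Random exon re-placement per chromosome, preserving count and sizes."""
    by_chrom: dict = {}
    for gene in genome.genes:
        if gene.biotype != "mRNA":
            continue
        for tx in gene.transcripts:
            for es, ee in tx.exons:
                by_chrom.setdefault(gene.chromosome, []).append((ee - es, gene.strand))
    records = []
    lengths = dict(genome.chromosomes)
    for chrom, exon_list in by_chrom.items():
        clen = lengths[chrom]
        for size, strand in exon_list:
            s = int(rng.integers(1, clen - size))
            records.append((chrom, s, s + size, strand, True, True))
    return boundaries_from_exons(
        records, lengths, provenance="shuffled", internal_only=False
    )


def _random_region_boundaries(genome, n_regions, region_length, rng):
    lengths = dict(genome.chromosomes)
    usable = {c: L for c, L in lengths.items() if L > region_length + 2}
    for c in lengths:
        if c not in usable:
            warnings.warn(
                f"chromosome {c} shorter than region length; skipped", stacklevel=2
            )
    if not usable:
        raise ValueError("no chromosome is long enough for the region length")
    names = list(usable)
    w = np.array([usable[c] for c in names], dtype=float)
    w /= w.sum()
    ei, ie = set(), set()
    for i in range(n_regions):
        chrom = names[int(rng.choice(len(names), p=w))]
        s = int(rng.integers(1, usable[chrom] - region_length - 1))
        e = s + region_length
        strand = "+" if rng.random() < 0.5 else "-"
        if i % 2 == 0:
            # region start as an exon->intron transition (intron = region)
            b = s if strand == "+" else e - 1
            ei.add((chrom, b, strand))
        else:
            # region end as an intron->exon transition
            b = e - 1 if strand == "+" else s
            ie.add((chrom, b, strand))
    mk = lambda typ, ps: BoundarySet(
        boundary_type=typ,
        positions=sorted(ps),
        provenance="random-regions",
        chromosome_lengths=lengths,
    )
    return mk("EI", ei), mk("IE", ie)


def background_profiles(
    intervals,
    genome,
    method: str,
    n_regions: int = 150_000,
    region_length: int = 5_000,
    seed: int = 0,
    exon_depth: int = EXON_DEPTH,
    intron_depth: int = INTRON_DEPTH,
):
    """Null metaprofiles (EI, IE) for the configured randomization.

    ``shuffle-exons`` re-places exon intervals (reads stay fixed) and
    recomputes boundaries; ``random-regions`` draws uniform regions whose
    starts stand in for EI boundaries and ends for IE boundaries, half each.
    """
    rng = np.random.default_rng(seed)
    if method == "shuffle-exons":
        ei, ie = _shuffled_exon_boundaries(genome, rng)
    elif method == "random-regions":
        ei, ie = _random_region_boundaries(genome, n_regions, region_length, rng)
    else:
        raise ValueError("method must be 'shuffle-exons' or 'random-regions'")
    return (
        profile_coverage(intervals, ei, exon_depth, intron_depth),
        profile_coverage(intervals, ie, exon_depth, intron_depth),
    )
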