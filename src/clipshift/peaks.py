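"""PAR-CLIP cluster calling.

Groups aligned reads by same-strand coordinate overlap and emits binding-site
peaks from groups that pass three T-to-C conversion filters:

1. conversion frequency (converted reads / all reads) >= 0.25,
2. more than five converted reads (i.e. >= 6),
3. at least two distinct genomic T-to-C conversion positions.

A read counts as *converted* iff it carries at least one sense-strand T-to-C
mismatch and at most one mismatch in total.  Mismatch offsets are stored in
sense (transcript) orientation; on the minus strand the genomic position of a
mismatch at offset ``o`` in a read spanning ``[start, end)`` is
``end - 1 - o``.

Collapsed reads carry a ``copy_count``: a read with copy_count ``c``
contributes ``c`` to every read-level tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AlignedRead",
    "Peak",
    "FilterConfig",
    "GroupStats",
    "group_reads",
    "score_group",
    "call_peaks",
]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned PAR-CLIP read with strand-aware mismatch records.

    Coordinates are 0-based half-open.  ``mismatches`` is a list of
    ``(offset, ref_base, alt_base)`` tuples with the offset measured in sense
    orientation (offset 0 is the 5' end of the transcript-strand read).
    """

    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str = ""
    mismatches: tuple = ()
    copy_count: int = 1
    read_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"malformed read {self.read_id or '(unnamed)'}: "
                f"end ({self.end}) <= start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be '+' or '-'")
        if self.copy_count < 1:
            raise ValueError(f"read {self.read_id}: copy_count must be >= 1")
        for off, _ref, _alt in self.mismatches:
            if not 0 <= off < (self.end - self.start):
                raise ValueError(
                    f"read {self.read_id}: mismatch offset {off} outside read"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_converted(self) -> bool:
        """True iff the read has >=1 sense T-to-C mismatch and <=1 mismatch total."""
        if len(self.mismatches) > 1:
            return False
        return any(r == "T" and a == "C" for _o, r, a in self.mismatches)

    def conversion_positions(self):
        """Genomic positions of sense T-to-C mismatches on this read."""
        out = []
        for off, ref, alt in self.mismatches:
            if ref == "T" and alt == "C":
                if self.strand == "+":
                    out.append(self.start + off)
                else:
                    out.append(self.end - 1 - off)
        return out


@dataclass
class GroupStats:
    n_reads: int
    n_converted_reads: int
    conversion_frequency: float
    conversion_sites: dict  # genomic position -> converted-read count (copy-weighted)


@dataclass
class Peak:
    """A read group that passed the binding-site filters."""

    chromosome: str
    start: int
    end: int
    strand: str
    n_reads: int
    n_converted_reads: int
    conversion_frequency: float
    conversion_sites: list  # [(position, converted-read count)] sorted by position
    anchor: int
    peak_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the three binding-site criteria.

    ``min_converted_reads`` is an inclusive minimum; the default 6 encodes
    "more than five reads with T-to-C conversion".
    """

    min_conversion_frequency: float = 0.25
    min_converted_reads: int = 6
    min_conversion_sites: int = 2


def group_reads(reads) -> list:
    """Partition reads into maximal chains of same-strand >=1-bp overlaps.

    Two reads belong to one group iff they are connected by a chain of
    overlapping (shared base, not merely abutting) reads on the same
    chromosome and strand.  Returns a list of lists of AlignedRead.
    """
    for r in reads:
        if r.end <= r.start:  # pragma: no cover - AlignedRead already validates
            raise ValueError(f"malformed read {r.read_id}")
    ordered = sorted(reads, key=lambda r: (r.chromosome, r.strand, r.start, r.end))
    groups = []
    current: list = []
    cur_key = None
    cur_end = None
    for r in ordered:
        key = (r.chromosome, r.strand)
        if current and key == cur_key and r.start < cur_end:
            current.append(r)
            cur_end = max(cur_end, r.end)
        else:
            if current:
                groups.append(current)
            current = [r]
            cur_key = key
            cur_end = r.end
    if current:
        groups.append(current)
    return groups


def score_group(group) -> GroupStats:
    """Copy-weighted conversion statistics of one read group."""
    if not group:
        raise ValueError("cannot score an empty group")
    n_reads = sum(r.copy_count for r in group)
    n_conv = 0
    sites: dict = {}
    for r in group:
        if r.is_converted:
            n_conv += r.copy_count
            for pos in r.conversion_positions():
                sites[pos] = sites.get(pos, 0) + r.copy_count
    return GroupStats(
        n_reads=n_reads,
        n_converted_reads=n_conv,
        conversion_frequency=n_conv / n_reads,
        conversion_sites=sites,
    )


def _make_peak(group, stats: GroupStats, peak_id: str = "") -> Peak:
    start = min(r.start for r in group)
    end = max(r.end for r in group)
    # anchor: conversion site with the largest converted-read support;
    # ties broken leftmost for determinism
    best = max(stats.conversion_sites.items(), key=lambda kv: (kv[1], -kv[0]))
    return Peak(
        chromosome=group[0].chromosome,
        start=start,
        end=end,
        strand=group[0].strand,
        n_reads=stats.n_reads,
        n_converted_reads=stats.n_converted_reads,
        conversion_frequency=stats.conversion_frequency,
        conversion_sites=sorted(stats.conversion_sites.items()),
        anchor=best[0],
        peak_id=peak_id,
    )


def call_peaks(reads, thresholds: FilterConfig | None = None) -> list:
    """Group reads and return the groups passing all three filters as Peaks."""
    if thresholds is None:
        thresholds = FilterConfig()
    peaks = []
    for group in group_reads(reads):
        stats = score_group(group)
        if (
            stats.conversion_frequency >= thresholds.min_conversion_frequency
            and stats.n_converted_reads >= thresholds.min_converted_reads
            and len(stats.conversion_sites) >= thresholds.min_conversion_sites
        ):
            peaks.append(_make_peak(group, stats, peak_id=f"peak_{len(peaks)}"))
    return peaks
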