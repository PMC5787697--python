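"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open everywhere; GTF is written and
read 1-based inclusive, and the conversion happens only here.  Mismatch
records travel in sense (transcript) orientation: a minus-strand T-to-C
appears as A-to-G in reference coordinates and the SAM reader performs the
flip.  All tabular outputs are single-header TSV.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .emsa import CompetitionSeries, TitrationSeries
from .peaks import AlignedRead, Peak
from .splicemap import SpliceEvent
from .synthetic import GeneModel, GenomeModel, TranscriptModel

__all__ = [
    "write_fasta", "read_fasta", "write_gtf", "read_annotation_gtf",
    "write_bed12", "read_genome", "write_reads_bed", "read_reads_bed",
    "read_reads_sam", "write_peaks", "read_peaks", "write_events_tsv",
    "read_events_tsv", "events_from_frame", "events_to_frame",
    "write_titration_tsv", "read_titration_tsv", "write_competition_tsv",
    "read_competition_tsv", "read_intervals", "write_intervals",
]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: GenomeModel, path, width: int = 70):
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq("".join(genome.sequence[name])), id=name, description="")
        for name, _ in genome.chromosomes
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio.SeqIO import parse

    return {rec.id: np.array(list(str(rec.seq))) for rec in parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk)

def _gtf_attrs(**kv) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items() if v is not None)


def write_gtf(genome: GenomeModel, path):
    rows = []
    for g in genome.genes:
        base = dict(gene_id=g.gene_id, gene_biotype=g.biotype)
        rows.append((g.chromosome, "gene", g.start + 1, g.end, g.strand, _gtf_attrs(**base)))
        for tx in g.transcripts:
            attrs = dict(base, transcript_id=tx.transcript_id)
            rows.append(
                (g.chromosome, "transcript", tx.start + 1, tx.end, g.strand, _gtf_attrs(**attrs))
            )
            for s, e in tx.exons:
                rows.append((g.chromosome, "exon", s + 1, e, g.strand, _gtf_attrs(**attrs)))
            if tx.cds is not None:
                rows.append(
                    (g.chromosome, "CDS", tx.cds[0] + 1, tx.cds[1], g.strand, _gtf_attrs(**attrs))
                )
            for kind, ivs in (("five_prime_utr", tx.utr5), ("three_prime_utr", tx.utr3)):
                for s, e in ivs:
                    rows.append((g.chromosome, kind, s + 1, e, g.strand, _gtf_attrs(**attrs)))
    with open(path, "w") as fh:
        for chrom, feat, s1, e1, strand, attrs in rows:
            fh.write(
                f"{chrom}\tclipshift\t{feat}\t{s1}\t{e1}\t.\t{strand}\t.\t{attrs}\n"
            )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_annotation_gtf(path):
    """Rebuild GeneModel records from a GTF written by :func:`write_gtf`."""
    genes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _src, feat, s1, e1, _score, strand, _frame, attr_s = parts
            start, end = int(s1) - 1, int(e1)  # to 0-based half-open
            attrs = dict(_ATTR_RE.findall(attr_s))
            gid = attrs.get("gene_id")
            g = genes.setdefault(
                gid,
                {
                    "chromosome": chrom,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", "mRNA"),
                    "tx": {},
                },
            )
            tid = attrs.get("transcript_id")
            if feat in ("exon", "CDS", "five_prime_utr", "three_prime_utr"):
                t = g["tx"].setdefault(tid, {"exons": [], "cds": None, "utr5": [], "utr3": []})
                if feat == "exon":
                    t["exons"].append((start, end))
                elif feat == "CDS":
                    t["cds"] = (start, end)
                elif feat == "five_prime_utr":
                    t["utr5"].append((start, end))
                else:
                    t["utr3"].append((start, end))
    out = []
    for gid, g in genes.items():
        txs = []
        for tid, t in g["tx"].items():
            txs.append(
                TranscriptModel(
                    transcript_id=tid,
                    exons=tuple(sorted(t["exons"])),
                    cds=t["cds"],
                    utr5=tuple(sorted(t["utr5"])),
                    utr3=tuple(sorted(t["utr3"])),
                )
            )
        out.append(
            GeneModel(gid, g["chromosome"], g["strand"], g["biotype"], tuple(txs))
        )
    return sorted(out, key=lambda g: g.gene_id)


def read_genome(fasta_path, gtf_path, seed: int = 0) -> GenomeModel:
    seq = read_fasta(fasta_path)
    return GenomeModel(
        chromosomes=[(name, len(arr)) for name, arr in seq.items()],
        genes=read_annotation_gtf(gtf_path),
        sequence=seq,
        seed=seed,
    )


def write_bed12(genome: GenomeModel, path):
    with open(path, "w") as fh:
        for g in genome.genes:
            for tx in g.transcripts:
                sizes = ",".join(str(e - s) for s, e in tx.exons) + ","
                starts = ",".join(str(s - tx.start) for s, e in tx.exons) + ","
                cds = tx.cds or (tx.start, tx.start)
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                g.chromosome, tx.start, tx.end, tx.transcript_id, 0,
                                g.strand, cds[0], cds[1], 0, len(tx.exons), sizes, starts,
                            ),
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# reads (BED6+), mismatch columns in sense orientation

READ_COLUMNS = [
    "chromosome", "start", "end", "name", "score", "strand",
    "mismatch_offset", "ref_base", "alt_base", "copy_count",
]


def write_reads_bed(reads, path):
    rows = []
    for r in reads:
        if r.mismatches:
            offs = ",".join(str(o) for o, _, _ in r.mismatches)
            refs = ",".join(ref for _, ref, _ in r.mismatches)
            alts = ",".join(alt for _, _, alt in r.mismatches)
        else:
            offs = refs = alts = "."
        rows.append(
            (r.chromosome, r.start, r.end, r.read_id or ".", 0, r.strand,
             offs, refs, alts, r.copy_count)
        )
    pd.DataFrame(rows, columns=READ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_bed(path):
    df = pd.read_csv(path, sep="\t", dtype={"mismatch_offset": str, "ref_base": str, "alt_base": str})
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing read columns {sorted(missing)}")
    reads = []
    for row in df.itertuples(index=False):
        if row.mismatch_offset == ".":
            mm = ()
        else:
            mm = tuple(
                (int(o), ref, alt)
                for o, ref, alt in zip(
                    str(row.mismatch_offset).split(","),
                    str(row.ref_base).split(","),
                    str(row.alt_base).split(","),
                )
            )
        reads.append(
            AlignedRead(
                chromosome=row.chromosome, start=int(row.start), end=int(row.end),
                strand=row.strand, mismatches=mm, copy_count=int(row.copy_count),
                read_id=str(row.name),
            )
        )
    return reads


_COLLAPSER_NAME = re.compile(r"^\d+-(\d+)$")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def read_reads_sam(path):
    """Aligned reads from SAM/BAM; mismatches derived from the MD tag and
    flipped to sense orientation for reverse-strand alignments.  Collapsed
    copy counts are recovered from fastx_collapser-style names (rank-count)."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            strand = "-" if aln.is_reverse else "+"
            qlen = aln.query_length
            mm = []
            for qpos, _rpos, ref in aln.get_aligned_pairs(with_seq=True, matches_only=True):
                if ref is None or not ref.islower():
                    continue
                alt = aln.query_sequence[qpos]
                ref = ref.upper()
                if strand == "-":
                    # query_sequence is reported on the forward genome strand
                    mm.append((qlen - 1 - qpos, _COMP[ref], _COMP[alt]))
                else:
                    mm.append((qpos, ref, alt))
            m = _COLLAPSER_NAME.match(aln.query_name or "")
            reads.append(
                AlignedRead(
                    chromosome=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand=strand,
                    sequence=aln.query_sequence,
                    mismatches=tuple(sorted(mm)),
                    copy_count=int(m.group(1)) if m else 1,
                    read_id=aln.query_name or "",
                )
            )
    return reads


# ---------------------------------------------------------------------------
# peaks (BED6+)

PEAK_COLUMNS = [
    "chromosome", "start", "end", "name", "score", "strand",
    "n_reads", "n_converted_reads", "conversion_frequency",
    "conversion_sites", "anchor",
]


def write_peaks(peaks, path):
    rows = []
    for p in peaks:
        sites = ",".join(f"{pos}:{cnt}" for pos, cnt in p.conversion_sites)
        rows.append(
            (p.chromosome, p.start, p.end, p.peak_id or ".", p.n_reads, p.strand,
             p.n_reads, p.n_converted_reads, repr(p.conversion_frequency),
             sites, p.anchor)
        )
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peaks(path):
    df = pd.read_csv(path, sep="\t")
    peaks = []
    for row in df.itertuples(index=False):
        sites = [
            (int(p), int(c))
            for p, c in (kv.split(":") for kv in str(row.conversion_sites).split(","))
        ]
        peaks.append(
            Peak(
                chromosome=row.chromosome, start=int(row.start), end=int(row.end),
                strand=row.strand, n_reads=int(row.n_reads),
                n_converted_reads=int(row.n_converted_reads),
                conversion_frequency=float(row.conversion_frequency),
                conversion_sites=sites, anchor=int(row.anchor),
                peak_id=str(row.name),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# splice events (rMATS-style TSV)

EVENT_COLUMNS = [
    "ID", "chr", "strand", "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IncLevelDifference", "PValue", "FDR",
]


def events_to_frame(events, include_truth: bool = False) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "ID": ev.event_id, "chr": ev.chromosome, "strand": ev.strand,
            "exonStart_0base": ev.cassette_start, "exonEnd": ev.cassette_end,
            "upstreamES": ev.upstream_start, "upstreamEE": ev.upstream_end,
            "downstreamES": ev.downstream_start, "downstreamEE": ev.downstream_end,
            "IncLevelDifference": ev.delta_psi, "PValue": ev.p_value, "FDR": ev.fdr,
        }
        if include_truth:
            row["trueClass"] = ev.true_class
        rows.append(row)
    cols = EVENT_COLUMNS + (["trueClass"] if include_truth else [])
    return pd.DataFrame(rows, columns=cols)


def events_from_frame(df: pd.DataFrame):
    required = {
        "chr", "strand", "exonStart_0base", "exonEnd", "upstreamES",
        "upstreamEE", "downstreamES", "downstreamEE",
        "IncLevelDifference", "PValue", "FDR",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table is missing columns: {sorted(missing)}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        events.append(
            SpliceEvent(
                chromosome=str(row.chr), strand=row.strand,
                cassette_start=int(row.exonStart_0base), cassette_end=int(row.exonEnd),
                upstream_start=int(row.upstreamES), upstream_end=int(row.upstreamEE),
                downstream_start=int(row.downstreamES), downstream_end=int(row.downstreamEE),
                delta_psi=float(row.IncLevelDifference),
                p_value=float(row.PValue), fdr=float(row.FDR),
                event_id=str(getattr(row, "ID", i)),
                true_class=str(getattr(row, "trueClass", "")),
            )
        )
    return events


def write_events_tsv(events, path, include_truth: bool = False):
    events_to_frame(events, include_truth=include_truth).to_csv(path, sep="\t", index=False)


def read_events_tsv(path):
    return events_from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# EMSA tables

def write_titration_tsv(series: TitrationSeries, path):
    pd.DataFrame(
        {
            "protein_M": series.protein_M,
            "fraction_bound": series.fraction_bound,
            "species": series.species,
        }
    ).to_csv(path, sep="\t", index=False)


def read_titration_tsv(path, species: str | None = None) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t")
    if species is not None:
        df = df[df["species"] == species]
    sp = df["species"].iloc[0] if len(df) else "RNA"
    return TitrationSeries(
        protein_M=df["protein_M"].to_numpy(),
        fraction_bound=df["fraction_bound"].to_numpy(),
        species=str(sp),
    )


def write_competition_tsv(series: CompetitionSeries, path):
    rows = []
    for sp, frees in (("DNA", series.dna_free_fraction), ("RNA", series.rna_free_fraction)):
        for p, f in zip(series.protein_M, frees):
            rows.append({"protein_M": p, "free_fraction": f, "species": sp})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_competition_tsv(path, m: float = 1.0, n: float = 1.0) -> CompetitionSeries:
    df = pd.read_csv(path, sep="\t")
    d = df[df["species"] == "DNA"].sort_values("protein_M")
    r = df[df["species"] == "RNA"].sort_values("protein_M")
    if not np.allclose(d["protein_M"].to_numpy(), r["protein_M"].to_numpy()):
        raise ValueError(f"{path}: DNA and RNA series use different protein grids")
    return CompetitionSeries(
        protein_M=d["protein_M"].to_numpy(),
        dna_free_fraction=d["free_fraction"].to_numpy(),
        rna_free_fraction=r["free_fraction"].to_numpy(),
        m=m, n=n,
    )


# ---------------------------------------------------------------------------
# generic interval tables

INTERVAL_COLUMNS = ["chromosome", "start", "end", "name", "score", "strand"]


def read_intervals(path, fmt: str | None = None) -> pd.DataFrame:
    """BED6 or GTF into a 0-based half-open interval table."""
    fmt = fmt or ("gtf" if str(path).endswith((".gtf", ".gff")) else "bed")
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs >= 3 columns")
        df = df.iloc[:, :6]
        df.columns = INTERVAL_COLUMNS[: df.shape[1]]
        for col, default in (("name", "."), ("score", 0), ("strand", "+")):
            if col not in df.columns:
                df[col] = default
        return df
    if fmt == "gtf":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{lineno}: malformed GTF line")
                rows.append(
                    {
                        "chromosome": parts[0],
                        "start": int(parts[3]) - 1,
                        "end": int(parts[4]),
                        "name": parts[2],
                        "score": 0,
                        "strand": parts[6],
                    }
                )
        return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    raise ValueError("format must be 'bed' or 'gtf'")


def write_intervals(df: pd.DataFrame, path, fmt: str = "bed"):
    if fmt == "bed":
        df[INTERVAL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "gtf":
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.chromosome}\tclipshift\t{row.name}\t{row.start + 1}\t"
                    f"{row.end}\t.\t{row.strand}\t.\t.\n"
                )
    else:
        raise ValueError("format must be 'bed' or 'gtf'")
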