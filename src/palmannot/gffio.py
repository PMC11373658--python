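"""Core genomic data model plus FASTA/GFF3/BED readers and writers.

All coordinates are held internally as 0-based half-open intervals; the
1-based closed convention of GFF3 (and VCF) is converted at the I/O
boundary, BED passes through unchanged.  Assembly summary statistics
(N50/N90, GC, gap content) are computed natively from the in-memory
genome.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import percent, round_half_up

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}
_KNOWN_FEATURES = {"gene", "mRNA", "exon", "CDS"}


class FormatError(ValueError):
    """Structurally invalid input file (broken hierarchy, bad columns)."""


class ValidationError(ValueError):
    """Input parses but violates a model invariant (e.g. CDS outside exon)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass
class Transcript:
    """One isoform: exon and CDS intervals on a single chrom/strand."""

    transcript_id: str
    gene_id: str
    source: str  # {"setA", "setB", "merged"}
    exons: list[Interval]
    cds: list[Interval]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons} | {c.chrom for c in self.cds}
        strands = {e.strand for e in self.exons} | {c.strand for c in self.cds}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValidationError(
                f"{self.transcript_id}: mixed chrom/strand intervals")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds = sorted(self.cds, key=lambda c: c.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS {c.start}-{c.end} outside exons")

    # -- convenience accessors ------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def cds_start(self) -> int | None:
        """Genomic coordinate of the first base of the start codon, i.e. the
        translation start in transcription orientation."""
        if not self.cds:
            return None
        return self.cds[0].start if self.strand != "-" else self.cds[-1].end - 1

    @property
    def cds_stop(self) -> int | None:
        """Genomic coordinate of the last coding base (translation end)."""
        if not self.cds:
            return None
        return self.cds[-1].end - 1 if self.strand != "-" else self.cds[0].start

    def coordinate_key(self) -> tuple:
        """Full structural identity: span endpoints plus the CDS list."""
        return (self.chrom, self.strand, self.start, self.end,
                tuple((c.start, c.end) for c in self.cds))

    def span_key(self) -> tuple:
        return (self.chrom, self.strand, self.start, self.end)

    def exon_key(self) -> tuple:
        return tuple((e.start, e.end) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]
    representative: str | None = None
    gene_class: str | None = None

    def __post_init__(self):
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene without transcripts")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise ValidationError(f"{self.gene_id}: transcripts on several chroms")
        if self.representative is not None and self.representative not in {
                t.transcript_id for t in self.transcripts}:
            raise ValidationError(
                f"{self.gene_id}: representative {self.representative} not a member")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class GenomeSequence:
    """Named assembly: ordered map of chromosome name -> A/C/G/T/N string."""

    name: str
    chroms: dict[str, str]

    def __post_init__(self):
        if not self.chroms:
            raise ValidationError(f"{self.name}: empty genome")
        cleaned = {}
        for cname, seq in self.chroms.items():
            if not seq:
                raise ValidationError(f"{self.name}/{cname}: empty sequence")
            seq = seq.upper()
            if re.search(r"[^ACGTN]", seq):
                logger.warning(
                    "%s/%s: ambiguity codes other than N mapped to N",
                    self.name, cname)
                seq = re.sub(r"[^ACGTN]", "N", seq)
            cleaned[cname] = seq
        self.chroms = cleaned

    def __len__(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def gap_runs(self) -> list[Interval]:
        """Maximal runs of N per chromosome, as intervals."""
        gaps = []
        for cname, seq in self.chroms.items():
            for m in re.finditer(r"N+", seq):
                gaps.append(Interval(cname, m.start(), m.end()))
        return gaps


@dataclass
class AsmStats:
    n_scaffolds: int
    total_bases: int
    gc_percent: float
    gap_percent: float
    max_len: int
    min_len: int
    mean_len: int
    n50: int
    n90: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, name: str | None = None) -> GenomeSequence:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate FASTA record {rec.id}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(name or str(path), chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=cname, description="")
               for cname, seq in genome.chroms.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython's writer wraps at its default; kept for signature compat


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >=3 columns")
            strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"feature_{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[Transcript]:
    """Parse a gene/mRNA/exon/CDS GFF3 into Transcript records.

    Unknown feature types are skipped with a warning; an exon or CDS whose
    Parent is not an mRNA in the file is a format error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique")
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    seen_types = set(db.featuretypes())
    for ft in seen_types - _KNOWN_FEATURES:
        logger.warning("%s: ignoring unknown feature type %r", path, ft)

    # validate hierarchy with line context before assembling transcripts
    for ftype in ("exon", "CDS"):
        if ftype not in seen_types:
            continue
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            if not parents or not any(p in mrna_ids for p in parents):
                raise FormatError(
                    f"{path}: {ftype} with no mRNA parent "
                    f"(line: {str(feat)!r})")

    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = [Interval(f.seqid, f.start - 1, f.end, f.strand)
                 for f in db.children(mrna, featuretype="exon")]
        cds = [Interval(f.seqid, f.start - 1, f.end, f.strand)
               for f in db.children(mrna, featuretype="CDS")]
        attrs = {k: v[0] for k, v in mrna.attributes.items()
                 if k not in ("ID", "Parent")}
        source = attrs.pop("source_set", mrna.source)
        transcripts.append(Transcript(
            transcript_id=mrna.id, gene_id=gene_id, source=source,
            exons=exons, cds=cds, attributes=attrs))
    return transcripts


def write_gff3(transcripts: list[Transcript], path) -> None:
    """Write a gene/mRNA/exon/CDS GFF3 (1-based closed) with provenance and
    gene class carried as mRNA attributes."""
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene,
                              key=lambda g: (by_gene[g][0].chrom,
                                             min(t.start for t in by_gene[g]))):
            ts = by_gene[gene_id]
            chrom, strand = ts[0].chrom, ts[0].strand
            gstart = min(t.start for t in ts) + 1
            gend = max(t.end for t in ts)
            fh.write(f"{chrom}\tpalmannot\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                     f"ID={gene_id}\n")
            for t in ts:
                extra = "".join(
                    f";{k}={v}" for k, v in sorted(t.attributes.items()))
                fh.write(
                    f"{chrom}\tpalmannot\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene_id};"
                    f"source_set={t.source}{extra}\n")
                for i, e in enumerate(t.exons, 1):
                    fh.write(f"{chrom}\tpalmannot\texon\t{e.start + 1}\t{e.end}\t.\t"
                             f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                             f"Parent={t.transcript_id}\n")
                for i, c in enumerate(t.cds, 1):
                    fh.write(f"{chrom}\tpalmannot\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                             f"{t.strand}\t0\tID={t.transcript_id}.cds{i};"
                             f"Parent={t.transcript_id}\n")


def group_genes(transcripts: list[Transcript]) -> list[GeneModel]:
    """Group transcripts into GeneModel records by their gene_id."""
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [GeneModel(g, ts) for g, ts in by_gene.items()]


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

def _nx(lengths_desc: list[int], total: int, frac: float) -> int:
    """Smallest length L such that scaffolds >= L cover >= frac of total."""
    cum = 0
    for length in lengths_desc:
        cum += length
        if cum >= frac * total:
            return length
    return lengths_desc[-1]


def assembly_stats(genome: GenomeSequence) -> AsmStats:
    lengths = sorted(genome.lengths().values(), reverse=True)
    total = sum(lengths)
    if total == 0:
        raise ValidationError("empty genome")
    gc = n_count = 0
    for seq in genome.chroms.values():
        gc += seq.count("G") + seq.count("C")
        n_count += seq.count("N")
    non_n = total - n_count
    return AsmStats(
        n_scaffolds=len(lengths),
        total_bases=total,
        gc_percent=percent(gc, non_n) if non_n else 0.0,
        gap_percent=percent(n_count, total),
        max_len=lengths[0],
        min_len=lengths[-1],
        mean_len=mean_length(total, len(lengths)),
        n50=_nx(lengths, total, 0.50),
        n90=_nx(lengths, total, 0.90),
    )


def mean_length(total_bases: int, n_scaffolds: int) -> int:
    """Mean scaffold length, floor of the exact ratio."""
    if n_scaffolds <= 0:
        raise ValidationError("n_scaffolds must be positive")
    return math.floor(total_bases / n_scaffolds)


def percent_excess(larger: int, smaller: int, ndigits: int = 1) -> float:
    """How much larger (in %) *larger* is than *smaller*."""
    return round_half_up(100.0 * (larger - smaller) / smaller, ndigits)
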