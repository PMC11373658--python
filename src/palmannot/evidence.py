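"""Per-transcript support evidence from CAGE, expression and homology data.

CAGE tag clusters mark transcription start sites; a cluster supports a
transcript when its summit falls within -3000..+10 nt (inclusive) of the
CDS start in transcription orientation, and one cluster may support
several isoforms of one gene but never two genes.  RNA-seq support is a
TPM threshold over a transcripts x tissues matrix; homology support is a
coverage >= 50% and e-value <= 1e-5 filter over tabular hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .gffio import GeneModel, Interval, ValidationError

logger = logging.getLogger(__name__)

CAGE_UPSTREAM = 3000
CAGE_DOWNSTREAM = 10
TPM_THRESHOLD = 1.0
BLAST_COVERAGE_MIN = 50.0
BLAST_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class CageCluster:
    interval: Interval
    summit: int
    score: float = 0.0

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside cluster "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}")


@dataclass
class EvidenceBundle:
    """Evidence axes plus the quantitative attributes used for isoform ranking."""

    transcript_id: str
    cage_supported: bool = False
    rnaseq_supported: bool = False
    blast_supported: bool = False
    best_evalue: float | None = None
    n_tissues_expressed: int = 0
    max_tpm: float = 0.0
    cds_length: int = 0
    prediction_order: int = 0

    @property
    def axes(self) -> tuple[bool, bool, bool]:
        return (self.cage_supported, self.rnaseq_supported, self.blast_supported)


def read_cage_bed(path) -> list[CageCluster]:
    """BED6+1: columns 1-6 standard, column 7 the summit offset within the
    cluster.  Missing column 7 -> summit at the interval midpoint."""
    clusters = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{ln}: too few BED columns")
            start, end = int(f[1]), int(f[2])
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
            offset = int(f[6]) if len(f) > 6 else (end - start) // 2
            clusters.append(CageCluster(
                Interval(f[0], start, end, strand), start + offset, score))
    return clusters


def write_cage_bed(clusters: list[CageCluster], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tcage_{i:05d}\t"
                     f"{c.score:g}\t{iv.strand}\t{c.summit - iv.start}\n")


# ---------------------------------------------------------------------------
# CAGE association
# ---------------------------------------------------------------------------

def _cage_window(transcript) -> tuple[int, int] | None:
    """Inclusive genomic [lo, hi] for the -3000..+10 window around the CDS
    start, in transcription orientation."""
    cs = transcript.cds_start
    if cs is None:
        return None
    if transcript.strand != "-":
        return cs - CAGE_UPSTREAM, cs + CAGE_DOWNSTREAM
    return cs - CAGE_DOWNSTREAM, cs + CAGE_UPSTREAM


def associate_cage(
    clusters: list[CageCluster],
    genes: list[GeneModel],
) -> tuple[dict[int, str | None], dict[str, bool]]:
    """Assign each cluster to at most one gene and flag supported isoforms.

    Returns (cluster index -> gene_id or None, transcript_id -> flag).
    A cluster whose summit lands in windows of two or more genes goes to the
    gene with the nearest CDS start; an exact distance tie leaves it
    unassigned.
    """
    windows = []  # (chrom, lo, hi, gene_id, transcript_id, cds_start)
    flags: dict[str, bool] = {}
    for g in genes:
        for t in g.transcripts:
            flags.setdefault(t.transcript_id, False)
            w = _cage_window(t)
            if w is None:
                logger.warning("transcript %s has no CDS; excluded from CAGE "
                               "association", t.transcript_id)
                continue
            windows.append((t.chrom, w[0], w[1], g.gene_id, t.transcript_id,
                            t.cds_start))

    by_chrom: dict[str, list] = {}
    for w in windows:
        by_chrom.setdefault(w[0], []).append(w)

    assignment: dict[int, str | None] = {}
    for ci, cluster in enumerate(clusters):
        s = cluster.summit
        hits = [w for w in by_chrom.get(cluster.interval.chrom, ())
                if w[1] <= s <= w[2]]
        gene_ids = {w[3] for w in hits}
        if not gene_ids:
            assignment[ci] = None
            continue
        if len(gene_ids) == 1:
            target = next(iter(gene_ids))
        else:
            # nearest CDS start among candidate genes; exact tie -> unassigned
            per_gene = {}
            for w in hits:
                d = abs(s - w[5])
                per_gene[w[3]] = min(per_gene.get(w[3], d), d)
            best = min(per_gene.values())
            nearest = [g for g, d in per_gene.items() if d == best]
            if len(nearest) > 1:
                assignment[ci] = None
                continue
            target = nearest[0]
        assignment[ci] = target
        for w in hits:
            if w[3] == target:
                flags[w[4]] = True
    return assignment, flags


# ---------------------------------------------------------------------------
# RNA-seq support
# ---------------------------------------------------------------------------

def rnaseq_support(
    expression: pd.DataFrame,
    tpm_threshold: float = TPM_THRESHOLD,
) -> pd.DataFrame:
    """Row-wise support over a transcripts x tissues TPM matrix.

    Returns a frame indexed by transcript with columns ``supported``,
    ``n_tissues_expressed`` and ``max_tpm``.  Support means TPM >= threshold
    in at least one tissue (threshold inclusive).
    """
    if (expression.values < 0).any():
        raise ValidationError("negative expression values")
    above = expression >= tpm_threshold
    return pd.DataFrame({
        "supported": above.any(axis=1),
        "n_tissues_expressed": above.sum(axis=1).astype(int),
        "max_tpm": expression.max(axis=1) if expression.shape[1] else 0.0,
    })


# ---------------------------------------------------------------------------
# homology support
# ---------------------------------------------------------------------------

def blast_support(
    hits: pd.DataFrame,
    coverage_min: float = BLAST_COVERAGE_MIN,
    evalue_max: float = BLAST_EVALUE_MAX,
) -> pd.DataFrame:
    """Qualify hits at coverage >= *coverage_min* % and e-value <=
    *evalue_max* (both inclusive); per query, ``supported`` plus the best
    (minimum) e-value among qualifying hits."""
    if ((hits["qcov"] < 0) | (hits["qcov"] > 100)).any():
        raise ValidationError("query coverage outside [0, 100]")
    ok = hits[(hits["qcov"] >= coverage_min) & (hits["evalue"] <= evalue_max)]
    best = ok.groupby("query")["evalue"].min()
    out = pd.DataFrame({"best_evalue": best})
    out["supported"] = True
    return out


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def build_evidence(
    genes: list[GeneModel],
    cage_flags: dict[str, bool],
    rnaseq: pd.DataFrame,
    blast: pd.DataFrame,
    prediction_order: dict[str, int] | None = None,
) -> dict[str, EvidenceBundle]:
    """Collate per-transcript evidence into ranking-ready bundles."""
    bundles: dict[str, EvidenceBundle] = {}
    order = prediction_order or {}
    default_order = 0
    for g in genes:
        for t in g.transcripts:
            tid = t.transcript_id
            b = EvidenceBundle(tid, cds_length=t.cds_length,
                               prediction_order=order.get(tid, default_order))
            default_order += 1
            b.cage_supported = bool(cage_flags.get(tid, False))
            if tid in rnaseq.index:
                row = rnaseq.loc[tid]
                b.rnaseq_supported = bool(row["supported"])
                b.n_tissues_expressed = int(row["n_tissues_expressed"])
                b.max_tpm = float(row["max_tpm"])
            if tid in blast.index:
                b.blast_supported = True
                b.best_evalue = float(blast.loc[tid, "best_evalue"])
            bundles[tid] = b
    return bundles


def evidence_table(bundles: dict[str, EvidenceBundle]) -> pd.DataFrame:
    rows = [vars(b).copy() for b in bundles.values()]
    return pd.DataFrame(rows).set_index("transcript_id")
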