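"""Consolidation of two gene-prediction sets into one annotation.

The procedure mirrors the manual curation workflow used for palm genome
annotations:

1. ``merge_predictions`` — where a transcript occurs in both sets with the
   same genomic span endpoints *and* the same full CDS coordinate list,
   only the set-B copy is kept (set B is the designated kept-on-identity
   pipeline).  Where span endpoints agree but exon boundaries differ, both
   transcripts are retained as isoforms of the same gene.  Everything else
   passes through, and genes are regrouped from coordinate overlap.
2. ``filter_lncrna`` — transcripts called non-coding by either of two
   coding-potential callers and lacking significant homology (e-value
   <= 1e-5) are removed as candidate lncRNAs.
3. ``proximity_review`` — gene pairs closer than 150 nt on the same strand,
   or closer than 300 nt on opposite strands with overlapping 3' ends, are
   flagged; within flagged pairs, transcripts without RNA-seq junction
   support are removed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .gffio import Transcript, group_genes

logger = logging.getLogger(__name__)

LNCRNA_EVALUE_CUTOFF = 1e-5
SAME_STRAND_DISTANCE = 150
OPPOSITE_STRAND_DISTANCE = 300


@dataclass
class MergeReport:
    n_input_a: int = 0
    n_input_b: int = 0
    n_collapsed_identical: int = 0
    n_isoforms_added: int = 0
    n_lncrna_removed: int = 0
    n_proximity_flagged: int = 0
    n_removed_no_junction_support: int = 0
    provenance: dict[str, str] = field(default_factory=dict)
    flagged_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return (self.n_input_a + self.n_input_b
                - self.n_collapsed_identical
                - self.n_lncrna_removed
                - self.n_removed_no_junction_support)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("provenance", "flagged_pairs")}
        d["n_output"] = self.n_output
        return d


class InputError(ValueError):
    pass


def _check_unique_ids(transcripts: list[Transcript], label: str) -> None:
    ids = [t.transcript_id for t in transcripts]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate transcript_ids in {label}: {dup[:5]}")


def merge_predictions(
    set_a: list[Transcript],
    set_b: list[Transcript],
    report: MergeReport | None = None,
) -> tuple[list[Transcript], MergeReport]:
    """Combine two prediction sets; set B wins on full coordinate identity."""
    _check_unique_ids(set_a, "set A")
    _check_unique_ids(set_b, "set B")
    report = report or MergeReport()
    report.n_input_a = len(set_a)
    report.n_input_b = len(set_b)

    # Rule 1: identical span endpoints AND identical CDS list -> keep set B copy.
    b_by_key: dict[tuple, list[Transcript]] = {}
    for t in set_b:
        b_by_key.setdefault(t.coordinate_key(), []).append(t)
    for key in b_by_key:  # deterministic tie-break: smallest id represents the key
        b_by_key[key].sort(key=lambda t: t.transcript_id)

    kept: list[Transcript] = []
    collapsed_keys = set()
    for t in set_a:
        key = t.coordinate_key()
        if key in b_by_key:
            report.n_collapsed_identical += 1
            report.provenance[t.transcript_id] = (
                f"collapsed-into:{b_by_key[key][0].transcript_id}")
            collapsed_keys.add(key)
        else:
            kept.append(t)
            report.provenance[t.transcript_id] = "setA"
    for t in set_b:
        kept.append(t)
        if t.coordinate_key() in collapsed_keys:
            report.provenance[t.transcript_id] = "setB-identity-kept"
        else:
            report.provenance[t.transcript_id] = "setB"

    # Rule 2 bookkeeping: same span, different exon chains, both retained.
    by_span: dict[tuple, list[Transcript]] = {}
    for t in kept:
        by_span.setdefault(t.span_key(), []).append(t)
    for ts in by_span.values():
        if len(ts) > 1 and len({t.exon_key() for t in ts}) > 1:
            report.n_isoforms_added += len(ts) - 1
            for t in ts:
                report.provenance[t.transcript_id] += "+isoform-of-shared-span"

    merged = _regroup_genes(kept)
    return merged, report


def _cds_overlap(a: Transcript, b: Transcript) -> bool:
    return any(ca.overlaps(cb) for ca in a.cds for cb in b.cds)


def _regroup_genes(transcripts: list[Transcript]) -> list[Transcript]:
    """Union-find grouping: same span, or same-strand overlap with shared CDS
    overlap, puts transcripts under one merged gene_id."""
    n = len(transcripts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (transcripts[i].chrom,
                                            transcripts[i].start,
                                            transcripts[i].end))
    # sweep over start-sorted transcripts; only near neighbours can group
    active: list[int] = []
    for idx in order:
        t = transcripts[idx]
        active = [j for j in active
                  if transcripts[j].chrom == t.chrom and transcripts[j].end > t.start]
        for j in active:
            u = transcripts[j]
            if t.span_key() == u.span_key():
                union(idx, j)
            elif (t.strand == u.strand and t.span.overlaps(u.span)
                  and _cds_overlap(t, u)):
                union(idx, j)
        active.append(idx)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered_groups = sorted(
        groups.values(),
        key=lambda g: (transcripts[g[0]].chrom,
                       min(transcripts[i].start for i in g)))
    out = []
    for gnum, members in enumerate(ordered_groups, 1):
        gene_id = f"merged_gene_{gnum:05d}"
        for i in sorted(members, key=lambda i: transcripts[i].transcript_id):
            t = transcripts[i]
            out.append(Transcript(
                transcript_id=t.transcript_id, gene_id=gene_id,
                source=t.source, exons=t.exons, cds=t.cds,
                attributes=dict(t.attributes)))
    return out


def merge_predictions_bruteforce(
    set_a: list[Transcript], set_b: list[Transcript]
) -> list[Transcript]:
    """Quadratic all-pairs reference for the merge, for cross-checking."""
    kept = []
    b_keys = {}
    for t in set_b:
        b_keys.setdefault(t.coordinate_key(), []).append(t.transcript_id)
    for t in set_a:
        if t.coordinate_key() not in b_keys:
            kept.append(t)
    kept.extend(set_b)

    n = len(kept)
    adj = [[False] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        a, b = kept[i], kept[j]
        same_span = a.span_key() == b.span_key()
        grouped = (a.strand == b.strand and a.span.overlaps(b.span)
                   and _cds_overlap(a, b))
        if same_span or grouped:
            adj[i][j] = adj[j][i] = True
    # connected components by DFS
    comp = [-1] * n
    c = 0
    for i in range(n):
        if comp[i] != -1:
            continue
        stack = [i]
        while stack:
            k = stack.pop()
            if comp[k] != -1:
                continue
            comp[k] = c
            stack.extend(j for j in range(n) if adj[k][j] and comp[j] == -1)
        c += 1
    groups: dict[int, list[Transcript]] = {}
    for i, t in enumerate(kept):
        groups.setdefault(comp[i], []).append(t)
    ordered = sorted(groups.values(), key=lambda g: (g[0].chrom,
                                                     min(t.start for t in g)))
    out = []
    for gnum, members in enumerate(ordered, 1):
        for t in sorted(members, key=lambda t: t.transcript_id):
            out.append(Transcript(t.transcript_id, f"merged_gene_{gnum:05d}",
                                  t.source, t.exons, t.cds, dict(t.attributes)))
    return out


# ---------------------------------------------------------------------------
# lncRNA consensus filter
# ---------------------------------------------------------------------------

def filter_lncrna(
    transcripts: list[Transcript],
    coding_calls: pd.DataFrame,
    homology_hits: pd.DataFrame,
    evalue_cutoff: float = LNCRNA_EVALUE_CUTOFF,
    report: MergeReport | None = None,
) -> tuple[list[Transcript], list[Transcript], MergeReport]:
    """Remove candidate lncRNAs: non-coding by either caller AND no
    significant homology.

    *coding_calls*: columns transcript_id, caller, verdict ({coding,
    non-coding}); a transcript absent from the table counts as coding.
    *homology_hits*: columns query, evalue (extra columns ignored here).
    """
    report = report or MergeReport()
    known = {t.transcript_id for t in transcripts}
    unknown = set(coding_calls["transcript_id"]) - known
    if unknown:
        logger.warning(
            "%d coding calls refer to transcripts absent from the input "
            "(e.g. %s); ignored", len(unknown), sorted(unknown)[0])

    noncoding: dict[str, bool] = {}
    for tid, sub in coding_calls.groupby("transcript_id"):
        noncoding[tid] = (sub["verdict"] == "non-coding").any()

    significant = set(
        homology_hits.loc[homology_hits["evalue"] <= evalue_cutoff, "query"])

    kept, removed = [], []
    for t in transcripts:
        if noncoding.get(t.transcript_id, False) and \
                t.transcript_id not in significant:
            removed.append(t)
            report.provenance[t.transcript_id] = "removed-lncrna"
        else:
            kept.append(t)
    report.n_lncrna_removed = len(removed)
    return kept, removed, report


# ---------------------------------------------------------------------------
# proximity review
# ---------------------------------------------------------------------------

def _gene_distance(a, b) -> int:
    """Gap between nearest span endpoints; <= 0 when spans touch/overlap."""
    if a.start > b.start:
        a, b = b, a
    return b.start - a.end


def _three_prime_exons_overlap(ga, gb) -> bool:
    for ta in ga.transcripts:
        ea = ta.exons[-1] if ta.strand != "-" else ta.exons[0]
        for tb in gb.transcripts:
            eb = tb.exons[-1] if tb.strand != "-" else tb.exons[0]
            if ea.overlaps(eb):
                return True
    return False


def proximity_review(
    transcripts: list[Transcript],
    junction_support: dict[str, bool] | pd.DataFrame,
    same_strand_max: int = SAME_STRAND_DISTANCE,
    opposite_strand_max: int = OPPOSITE_STRAND_DISTANCE,
    report: MergeReport | None = None,
) -> tuple[list[Transcript], list[Transcript], MergeReport]:
    """Flag suspiciously close gene pairs and drop unsupported transcripts.

    Rule (a): same strand, inter-gene distance < *same_strand_max*.
    Rule (b): opposite strands, overlapping 3'-terminal exons and distance
    < *opposite_strand_max*.  Within flagged pairs, transcripts whose exon
    boundaries lack RNA-seq junction support are removed.  A transcript
    missing from *junction_support* counts as unsupported.
    """
    report = report or MergeReport()
    if isinstance(junction_support, pd.DataFrame):
        junction_support = dict(zip(junction_support["transcript_id"],
                                    junction_support["supported"].astype(bool)))
    genes = group_genes(transcripts)
    flagged_genes: set[str] = set()
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        for ga, gb in itertools.combinations(chrom_genes, 2):
            dist = _gene_distance(ga, gb)
            if dist >= max(same_strand_max, opposite_strand_max):
                continue
            if ga.strand == gb.strand and dist < same_strand_max:
                rule = "same-strand<%d" % same_strand_max
            elif (ga.strand != gb.strand and dist < opposite_strand_max
                    and _three_prime_exons_overlap(ga, gb)):
                rule = "opposite-strand-3p-overlap<%d" % opposite_strand_max
            else:
                continue
            report.flagged_pairs.append((ga.gene_id, gb.gene_id, rule))
            flagged_genes.update((ga.gene_id, gb.gene_id))
    report.n_proximity_flagged = len(report.flagged_pairs)

    kept, removed = [], []
    for t in transcripts:
        if t.gene_id in flagged_genes and not junction_support.get(
                t.transcript_id, False):
            removed.append(t)
            report.provenance[t.transcript_id] = "removed-no-junction-support"
        else:
            kept.append(t)
    report.n_removed_no_junction_support = len(removed)
    return kept, removed, report


# ---------------------------------------------------------------------------
# full consolidation pipeline
# ---------------------------------------------------------------------------

def consolidate(
    set_a: list[Transcript],
    set_b: list[Transcript],
    coding_calls: pd.DataFrame,
    homology_hits: pd.DataFrame,
    junction_support: dict[str, bool] | pd.DataFrame,
) -> tuple[list[Transcript], MergeReport]:
    """merge -> lncRNA filter -> proximity review, with one shared report."""
    merged, report = merge_predictions(set_a, set_b)
    kept, _, report = filter_lncrna(merged, coding_calls, homology_hits,
                                    report=report)
    final, _, report = proximity_review(kept, junction_support, report=report)
    assert len(final) == report.n_output, "merge count identity violated"
    return final, report
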