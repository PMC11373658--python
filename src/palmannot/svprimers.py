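"""Structural-variant filtering and diagnostic PCR primer design.

Given an interspecific SV call set between two assemblies (A, the
reference carrying sequence deleted in B, and B, the derived genome),
this module

* filters calls overlapping assembly gaps and applies the size
  thresholds used for large-SV selection (inversions >= 5 Mb,
  duplications/translocations >= 50 kb, both inclusive);
* computes an invariant mask: intervals of genome A whose sequence is
  locally collinear and base-identical in genome B, the only places
  shared primers may sit (minimising false-negative PCR from
  interspecies SNPs);
* designs the diagnostic primer schemes — for a deletion, pair D1
  (D1F in the shared 5' flank, D1R inside the A-only sequence) and pair
  D2 (D2F inside the A-only sequence, D2R in the shared 3' flank), both
  amplifying A only, plus the spanning pair D1F+D2R whose product is
  short only in B; for a tandem duplication the outward-facing pair
  U1F/U1R across the copy junction, amplifying B only; for a
  translocation, pairs T1/T2 straddling the two breakpoints of the
  un-rearranged genome, amplifying that genome only;
* predicts amplification by electronic PCR: exact-match primer search on
  both strands with a maximum product size.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from ._util import find_all, revcomp
from .gffio import GenomeSequence, Interval

logger = logging.getLogger(__name__)

INV_MIN = 5_000_000
DUP_MIN = 50_000
TRA_MIN = 50_000
PRIMER_LEN = 20
SEARCH_RADIUS = 1000
MAX_PRODUCT = 3000

SV_TYPES = {"deletion", "duplication", "translocation", "inversion",
            "transposition"}


class PrimerDesignError(RuntimeError):
    """Design infeasible for this event; the message carries the reason."""


@dataclass
class StructuralVariant:
    sv_id: str
    type: str
    coords_a: Interval
    coords_b: Interval | None = None
    size: int = 0
    overlaps_gap: bool = False

    def __post_init__(self):
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.size <= 0:
            self.size = len(self.coords_a)


@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str
    forward_site: Interval
    reverse_site: Interval
    # genome name -> predicted product size (bp), or None for no product
    expected_pattern: dict[str, int | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SV I/O and filtering
# ---------------------------------------------------------------------------

def read_svs_tsv(path) -> list[StructuralVariant]:
    """Tabular SV calls: sv_id, type, chromA, startA, endA[, chromB, startB,
    endB] (0-based half-open)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        coords_b = None
        if "chromB" in df.columns and isinstance(r.get("chromB"), str):
            coords_b = Interval(r["chromB"], int(r["startB"]), int(r["endB"]))
        out.append(StructuralVariant(
            str(r["sv_id"]), r["type"],
            Interval(r["chromA"], int(r["startA"]), int(r["endA"])),
            coords_b))
    return out


def write_svs_tsv(svs: list[StructuralVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("sv_id\ttype\tchromA\tstartA\tendA\tchromB\tstartB\tendB\tsize\n")
        for sv in svs:
            b = sv.coords_b
            bt = f"{b.chrom}\t{b.start}\t{b.end}" if b else "\t\t"
            fh.write(f"{sv.sv_id}\t{sv.type}\t{sv.coords_a.chrom}\t"
                     f"{sv.coords_a.start}\t{sv.coords_a.end}\t{bt}\t{sv.size}\n")


def _gap_tree(gaps: list[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gaps:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    return trees


def filter_svs(
    svs: list[StructuralVariant],
    gaps_a: list[Interval],
    gaps_b: list[Interval],
    inv_min: int = INV_MIN,
    dup_min: int = DUP_MIN,
    tra_min: int = TRA_MIN,
) -> list[StructuralVariant]:
    """Drop calls overlapping a gap in either assembly; keep inversions >=
    *inv_min* and duplications/translocations/transpositions >= the
    corresponding minimum (thresholds inclusive).  Deletions have no size
    threshold here — they feed the small-variant PCR validation branch."""
    trees_a, trees_b = _gap_tree(gaps_a), _gap_tree(gaps_b)
    out = []
    for sv in svs:
        a = sv.coords_a
        in_gap = bool(trees_a.get(a.chrom, IntervalTree()).overlap(a.start, a.end))
        if sv.coords_b is not None and not in_gap:
            b = sv.coords_b
            in_gap = bool(trees_b.get(b.chrom, IntervalTree()).overlap(b.start, b.end))
        sv.overlaps_gap = in_gap
        if in_gap:
            continue
        if sv.type == "inversion" and sv.size < inv_min:
            continue
        if sv.type == "duplication" and sv.size < dup_min:
            continue
        if sv.type in ("translocation", "transposition") and sv.size < tra_min:
            continue
        out.append(sv)
    return out


# ---------------------------------------------------------------------------
# invariant mask
# ---------------------------------------------------------------------------

def invariant_mask(
    genome_a: GenomeSequence,
    non_invariant: list[Interval],
) -> dict[str, list[tuple[int, int]]]:
    """Intervals of genome A (per chromosome, sorted, half-open) outside any
    known difference to genome B.

    *non_invariant* lists the A-coordinates of everything that breaks local
    base identity: SNP positions (width-1 intervals), deleted regions,
    inverted regions.  Assembly gaps (N runs) are excluded as well.
    """
    excluded: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_a.chroms}
    for iv in list(non_invariant) + genome_a.gap_runs():
        excluded.setdefault(iv.chrom, []).append((iv.start, iv.end))
    mask: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in genome_a.chroms.items():
        merged: list[list[int]] = []
        for s, e in sorted(excluded.get(chrom, [])):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        runs, cur = [], 0
        for s, e in merged:
            if s > cur:
                runs.append((cur, s))
            cur = max(cur, e)
        if cur < len(seq):
            runs.append((cur, len(seq)))
        mask[chrom] = runs
    return mask


def mask_contains(mask: dict[str, list[tuple[int, int]]],
                  chrom: str, start: int, end: int) -> bool:
    runs = mask.get(chrom, [])
    starts = [r[0] for r in runs]
    i = bisect_right(starts, start) - 1
    return i >= 0 and runs[i][0] <= start and end <= runs[i][1]


# ---------------------------------------------------------------------------
# electronic PCR
# ---------------------------------------------------------------------------

def _site_occurrences(seq: str, site: str) -> int:
    n = len(find_all(seq, site))
    rc = revcomp(site)
    if rc != site:
        n += len(find_all(seq, rc))
    return n


def count_occurrences(genome: GenomeSequence, site: str) -> int:
    """Exact both-strand occurrence count of a sequence across a genome."""
    return sum(_site_occurrences(seq, site) for seq in genome.chroms.values())


def epcr(pair: PrimerPair, genome: GenomeSequence,
         max_product: int = MAX_PRODUCT) -> list[tuple[str, int, int, int]]:
    """Predict PCR products by exact primer matching on both strands.

    Returns (chrom, start, end, size) for every convergent primer pairing
    with product length <= *max_product*."""
    if min(len(pair.forward), len(pair.reverse)) < 15:
        raise ValueError("primers must be >= 15 nt")
    products = []
    for chrom, seq in genome.chroms.items():
        for p1, p2 in ((pair.forward, pair.reverse),
                       (pair.reverse, pair.forward)):
            plus = find_all(seq, p1)
            minus = find_all(seq, revcomp(p2))
            if not plus or not minus:
                continue
            for i in plus:
                for j in minus:
                    if j < i:
                        continue
                    size = j + len(p2) - i
                    if size <= max_product:
                        products.append((chrom, i, j + len(p2), size))
    return sorted(set(products))


def amplifies(pair: PrimerPair, genome: GenomeSequence,
              max_product: int = MAX_PRODUCT) -> bool:
    return bool(epcr(pair, genome, max_product))


# ---------------------------------------------------------------------------
# primer placement
# ---------------------------------------------------------------------------

def _pick_primer(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    chrom: str,
    lo: int,
    hi: int,
    orientation: str,           # "forward" | "reverse"
    expect_a: int,
    expect_b: int,
    mask: dict | None = None,
    primer_len: int = PRIMER_LEN,
    prefer: str = "left",
) -> tuple[str, Interval]:
    """Scan [lo, hi) for a primer site meeting mask and uniqueness
    constraints; *prefer* picks the scan direction."""
    seq = genome_a.chroms[chrom]
    lo = max(lo, 0)
    hi = min(hi, len(seq))
    if hi - lo < primer_len:
        raise PrimerDesignError(
            f"window {chrom}:{lo}-{hi} too small for a {primer_len} nt primer")
    starts = range(lo, hi - primer_len + 1)
    if prefer == "right":
        starts = reversed(starts)
    for p in starts:
        site = seq[p:p + primer_len]
        if "N" in site:
            continue
        if mask is not None and not mask_contains(mask, chrom, p, p + primer_len):
            continue
        if count_occurrences(genome_a, site) != expect_a:
            continue
        if count_occurrences(genome_b, site) != expect_b:
            continue
        primer = site if orientation == "forward" else revcomp(site)
        return primer, Interval(chrom, p, p + primer_len,
                                "+" if orientation == "forward" else "-")
    reason = ("no invariant flank" if mask is not None
              else "no unique primer site")
    raise PrimerDesignError(
        f"{reason} in {chrom}:{lo}-{hi} ({orientation})")


# ---------------------------------------------------------------------------
# design schemes
# ---------------------------------------------------------------------------

def design_deletion_primers(
    sv: StructuralVariant,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    mask: dict,
    primer_len: int = PRIMER_LEN,
    search_radius: int = SEARCH_RADIUS,
    max_product: int = MAX_PRODUCT,
) -> dict[str, PrimerPair]:
    """D1 (shared-flank F, internal R) and D2 (internal F, shared-flank R)
    amplify genome A only; the spanning pair D1F+D2R yields a short product
    only where the deletion removed the intervening sequence (genome B)."""
    if sv.type != "deletion":
        raise ValueError("not a deletion")
    c, s, e = sv.coords_a.chrom, sv.coords_a.start, sv.coords_a.end
    if e - s < primer_len:
        raise PrimerDesignError(
            f"{sv.sv_id}: deletion too small ({e - s} bp) for an internal primer")
    na, nb = genome_a.name, genome_b.name

    d1f, d1f_site = _pick_primer(genome_a, genome_b, c, s - search_radius, s,
                                 "forward", 1, 1, mask, primer_len, "right")
    d1r, d1r_site = _pick_primer(genome_a, genome_b, c, s,
                                 min(e, s + search_radius),
                                 "reverse", 1, 0, None, primer_len, "left")
    d2f, d2f_site = _pick_primer(genome_a, genome_b, c,
                                 max(s, e - search_radius), e,
                                 "forward", 1, 0, None, primer_len, "right")
    d2r, d2r_site = _pick_primer(genome_a, genome_b, c, e, e + search_radius,
                                 "reverse", 1, 1, mask, primer_len, "left")

    d1_size = d1r_site.end - d1f_site.start
    d2_size = d2r_site.end - d2f_site.start
    span_a = d2r_site.end - d1f_site.start
    span_b = span_a - (e - s)
    if d1_size > max_product or d2_size > max_product:
        raise PrimerDesignError(f"{sv.sv_id}: flanking products exceed "
                                f"max product size")
    pairs = {
        "D1": PrimerPair("D1", d1f, d1r, d1f_site, d1r_site,
                         {na: d1_size, nb: None}),
        "D2": PrimerPair("D2", d2f, d2r, d2f_site, d2r_site,
                         {na: d2_size, nb: None}),
        "spanning": PrimerPair(
            "spanning", d1f, d2r, d1f_site, d2r_site,
            {na: span_a if span_a <= max_product else None,
             nb: span_b if span_b <= max_product else None}),
    }
    return pairs


def design_duplication_primers(
    sv: StructuralVariant,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    mask: dict,
    primer_len: int = PRIMER_LEN,
    search_radius: int = SEARCH_RADIUS,
    max_product: int = MAX_PRODUCT,
) -> dict[str, PrimerPair]:
    """Outward-facing pair across the tandem-duplication junction: U1F from
    the 3' end of the duplicated region, U1R from its 5' end.  The junction
    (copy-1 end joined to copy-2 start) exists only in genome B."""
    if sv.type != "duplication":
        raise ValueError("not a duplication")
    c, s, e = sv.coords_a.chrom, sv.coords_a.start, sv.coords_a.end
    seq_a = genome_a.chroms[c]
    k = min(25, e - s)
    junction = seq_a[e - k:e] + seq_a[s:s + k]
    if not any(junction in bseq for bseq in genome_b.chroms.values()):
        raise PrimerDesignError(
            f"{sv.sv_id}: duplication copies are not tandem "
            f"(no copy junction in {genome_b.name})")

    u1f, u1f_site = _pick_primer(genome_a, genome_b, c,
                                 max(s, e - search_radius), e,
                                 "forward", 1, 2, None, primer_len, "right")
    u1r, u1r_site = _pick_primer(genome_a, genome_b, c, s,
                                 min(e, s + search_radius),
                                 "reverse", 1, 2, None, primer_len, "left")
    size_b = (e - u1f_site.start) + (u1r_site.end - s)
    if size_b > max_product:
        raise PrimerDesignError(f"{sv.sv_id}: junction product {size_b} bp "
                                f"exceeds max product size")
    return {"U1": PrimerPair("U1", u1f, u1r, u1f_site, u1r_site,
                             {genome_a.name: None, genome_b.name: size_b})}


def design_translocation_primers(
    sv: StructuralVariant,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    mask: dict,
    primer_len: int = PRIMER_LEN,
    search_radius: int = SEARCH_RADIUS,
    max_product: int = MAX_PRODUCT,
) -> dict[str, PrimerPair]:
    """Junction pairs T1/T2 straddle the two breakpoints of the translocated
    segment in the genome where the segment sits in its original context
    (genome A); in genome B the segment has moved, so neither pair finds a
    convergent site pair and only genome A amplifies."""
    if sv.type not in ("translocation", "transposition"):
        raise ValueError("not a translocation/transposition")
    c, s, e = sv.coords_a.chrom, sv.coords_a.start, sv.coords_a.end
    na, nb = genome_a.name, genome_b.name

    t1f, t1f_site = _pick_primer(genome_a, genome_b, c, s - search_radius, s,
                                 "forward", 1, 1, mask, primer_len, "right")
    t1r, t1r_site = _pick_primer(genome_a, genome_b, c, s,
                                 min(e, s + search_radius),
                                 "reverse", 1, 1, mask, primer_len, "left")
    t2f, t2f_site = _pick_primer(genome_a, genome_b, c,
                                 max(s, e - search_radius), e,
                                 "forward", 1, 1, mask, primer_len, "right")
    t2r, t2r_site = _pick_primer(genome_a, genome_b, c, e, e + search_radius,
                                 "reverse", 1, 1, mask, primer_len, "left")
    t1_size = t1r_site.end - t1f_site.start
    t2_size = t2r_site.end - t2f_site.start
    if max(t1_size, t2_size) > max_product:
        raise PrimerDesignError(f"{sv.sv_id}: junction products exceed max "
                                f"product size")
    return {
        "T1": PrimerPair("T1", t1f, t1r, t1f_site, t1r_site,
                         {na: t1_size, nb: None}),
        "T2": PrimerPair("T2", t2f, t2r, t2f_site, t2r_site,
                         {na: t2_size, nb: None}),
    }


_DESIGNERS = {
    "deletion": design_deletion_primers,
    "duplication": design_duplication_primers,
    "translocation": design_translocation_primers,
    "transposition": design_translocation_primers,
}


def design_sv_primers(
    svs: list[StructuralVariant],
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    mask: dict,
    **kwargs,
) -> dict[str, dict]:
    """Run the appropriate scheme per SV; failures are recorded, not raised.

    Returns sv_id -> {"status": "ok"|"failed", "pairs": {...}, "reason": str}.
    """
    results: dict[str, dict] = {}
    for sv in svs:
        designer = _DESIGNERS.get(sv.type)
        if designer is None:
            results[sv.sv_id] = {"status": "failed", "pairs": {},
                                 "reason": f"no primer scheme for {sv.type}"}
            continue
        try:
            pairs = designer(sv, genome_a, genome_b, mask, **kwargs)
            results[sv.sv_id] = {"status": "ok", "pairs": pairs, "reason": ""}
        except PrimerDesignError as exc:
            logger.warning("%s: %s", sv.sv_id, exc)
            results[sv.sv_id] = {"status": "failed", "pairs": {},
                                 "reason": str(exc)}
    return results


def write_primer_tsv(results: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("sv_id\tpair\tforward\treverse\tchrom\tfwd_start\trev_end\t"
                 "expected_pattern\n")
        for sv_id, res in results.items():
            if res["status"] != "ok":
                fh.write(f"{sv_id}\tFAILED\t.\t.\t.\t.\t.\t{res['reason']}\n")
                continue
            for name, pair in res["pairs"].items():
                pat = ";".join(f"{g}={s if s is not None else 'no-product'}"
                               for g, s in pair.expected_pattern.items())
                fh.write(f"{sv_id}\t{name}\t{pair.forward}\t{pair.reverse}\t"
                         f"{pair.forward_site.chrom}\t{pair.forward_site.start}\t"
                         f"{pair.reverse_site.end}\t{pat}\n")
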