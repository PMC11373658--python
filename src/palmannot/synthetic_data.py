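"""Synthetic inputs with machine-readable ground truth.

Every input the consolidation/classification/profiling/SV pipeline
consumes can be generated here with known, planted structure:

* a random genome with planted assembly gaps (N runs);
* two gene-prediction sets whose transcripts fall into controlled
  coordinate-agreement categories (identical, same span bounds with
  different exon chains, set-specific, overlapping-conflict), plus planted
  lncRNAs and near-neighbour gene pairs at distances bracketing the
  150/300 nt proximity-review thresholds;
* CAGE clusters, a tissue expression matrix, homology hits, coding
  potential calls and per-cytosine methylation calls, all drawn to be
  consistent with each gene's planted evidence class (N1..N6);
* a diverged second genome carrying planted deletions, tandem
  duplications, reciprocal translocations, inversions and background
  SNPs, with exact coordinates on both genomes.

All generators are deterministic for a fixed seed; each draws from its
own labelled substream of the master seed so adding one generator never
perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import revcomp
from .gffio import GenomeSequence, Interval, Transcript, GeneModel
from .svprimers import StructuralVariant

AGREEMENT_CATEGORIES = ("identical", "same-bounds-diff-exons", "setA-only",
                        "setB-only", "overlapping-conflict")
GENE_CLASSES = ("N1", "N2", "N3", "N4", "N5", "N6")

# methylation templates: (body/baseline level, anchor dip level)
_METH_TEMPLATES = {
    "expressed": {"CG": (0.60, 0.10), "CHG": (0.50, 0.08), "CHH": (0.05, 0.05)},
    "silent": {"CG": (0.85, 0.85), "CHG": (0.80, 0.80), "CHH": (0.10, 0.10)},
}
_DIP_WIDTH = 150.0  # gaussian half-width of the anchor trough, nt


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    class_mixture: dict = field(default_factory=lambda: {
        "N1": 0.25, "N2": 0.15, "N3": 0.20, "N4": 0.15, "N5": 0.15, "N6": 0.10})
    agreement_mixture: dict = field(default_factory=lambda: {
        "identical": 0.40, "same-bounds-diff-exons": 0.20,
        "setA-only": 0.15, "setB-only": 0.15, "overlapping-conflict": 0.10})
    n_tissues: int = 8
    tpm_threshold: float = 1.0
    lncrna_fraction: float = 0.05
    # (kind, value): same-strand pairs at the given inter-gene distance,
    # opposite-strand pairs with the given 3' overlap
    proximity_pair_specs: tuple = (("same", 100), ("same", 149),
                                   ("same", 151), ("opposite", 10))
    n_gaps_per_chrom: int = 2
    gap_length_range: tuple = (200, 800)
    # SV simulation
    sv_counts: dict = field(default_factory=lambda: {
        "deletion": 6, "duplication": 4, "translocation": 2, "inversion": 2})
    n_sv_gap_decoys: int = 2
    deletion_size_range: tuple = (500, 20_000)
    duplication_size_range: tuple = (2_000, 8_000)
    translocation_size_range: tuple = (50_000, 80_000)
    inversion_size_range: tuple = (10_000, 30_000)
    divergence_snp_rate: float = 0.005

    def validate(self) -> None:
        for name, mix in (("class_mixture", self.class_mixture),
                          ("agreement_mixture", self.agreement_mixture)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} proportions must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{name} has a negative proportion")
        if self.n_genes < 0 or self.n_chroms < 1 or self.chrom_length < 1:
            raise ConfigError("counts must be non-negative, sizes positive")
        # rough capacity check: max gene footprint ~6 kb incl. spacing
        if self.n_genes * 6000 > 0.95 * self.n_chroms * self.chrom_length:
            raise ConfigError(
                f"cannot place {self.n_genes} genes with minimum spacing in "
                f"{self.n_chroms} x {self.chrom_length} bp")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Labelled substream of the master seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode()) & 0x7FFFFFFF])


@dataclass
class TruthTable:
    gene_class: dict[str, str] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)
    agreement: dict[str, str] = field(default_factory=dict)       # per transcript
    lncrna: dict[str, bool] = field(default_factory=dict)         # per transcript
    junction_support: dict[str, bool] = field(default_factory=dict)
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)
    removed_by_proximity: set = field(default_factory=set)
    cage_target: dict[int, str] = field(default_factory=dict)     # cluster -> gene
    svs: list[StructuralVariant] = field(default_factory=list)
    snp_positions: list[tuple[str, int]] = field(default_factory=list)
    # generated objects (not serialised to JSON)
    genes: list[GeneModel] = field(default_factory=list)
    set_a: list[Transcript] = field(default_factory=list)
    set_b: list[Transcript] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "gene_class": self.gene_class,
            "representative": self.representative,
            "agreement": self.agreement,
            "lncrna": {k: bool(v) for k, v in self.lncrna.items()},
            "junction_support": {k: bool(v)
                                 for k, v in self.junction_support.items()},
            "flagged_pairs": self.flagged_pairs,
            "removed_by_proximity": sorted(self.removed_by_proximity),
            "cage_target": self.cage_target,
            "svs": [dict(sv_id=s.sv_id, type=s.type,
                         chromA=s.coords_a.chrom, startA=s.coords_a.start,
                         endA=s.coords_a.end,
                         chromB=s.coords_b.chrom if s.coords_b else None,
                         startB=s.coords_b.start if s.coords_b else None,
                         endB=s.coords_b.end if s.coords_b else None,
                         size=s.size, overlaps_gap=s.overlaps_gap)
                    for s in self.svs],
            "snp_positions": self.snp_positions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig, name: str = "simA"
                    ) -> tuple[GenomeSequence, list[Interval]]:
    """Uniform A/C/G/T background with planted N-run gaps."""
    config.validate()
    rng = _rng(config.seed, "genome:" + name)
    chroms: dict[str, str] = {}
    gaps: list[Interval] = []
    for ci in range(config.n_chroms):
        cname = f"chr{ci + 1}"
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                         size=config.chrom_length)
        lo, hi = config.gap_length_range
        placed: list[tuple[int, int]] = []
        for _ in range(config.n_gaps_per_chrom):
            for _attempt in range(100):
                glen = int(rng.integers(lo, hi + 1))
                gstart = int(rng.integers(5000, config.chrom_length - glen - 5000))
                if all(gstart + glen + 1000 < s or gstart > e + 1000
                       for s, e in placed):
                    placed.append((gstart, gstart + glen))
                    break
            else:
                raise ConfigError("cannot place gaps without overlap")
        for gstart, gend in sorted(placed):
            seq[gstart:gend] = b"N"
            gaps.append(Interval(cname, gstart, gend))
        chroms[cname] = seq.tobytes().decode()
    return GenomeSequence(name, chroms), gaps


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _gene_structure(rng, chrom: str, start: int, strand: str) -> dict:
    """Random multi-exon structure with the CDS anchored inside the first
    and last exons; returns exon intervals plus genomic CDS bounds."""
    n_exons = int(rng.integers(2, 5))
    exon_lens = rng.integers(600, 1000, n_exons)
    intron_lens = rng.integers(100, 400, n_exons - 1) if n_exons > 1 else []
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    cds_lo = exons[0][0] + int(rng.integers(30, 150))
    cds_hi = exons[-1][1] - int(rng.integers(30, 150))
    return {"chrom": chrom, "strand": strand, "exons": exons,
            "cds_lo": cds_lo, "cds_hi": cds_hi, "end": pos}


def _cds_pieces(exons, cds_lo, cds_hi):
    out = []
    for s, e in exons:
        lo, hi = max(s, cds_lo), min(e, cds_hi)
        if lo < hi:
            out.append((lo, hi))
    return out


def _build_transcript(tid, gene_id, source, struct, cds_lo=None, cds_hi=None,
                      exons=None) -> Transcript:
    chrom, strand = struct["chrom"], struct["strand"]
    exons = exons if exons is not None else struct["exons"]
    cds_lo = cds_lo if cds_lo is not None else struct["cds_lo"]
    cds_hi = cds_hi if cds_hi is not None else struct["cds_hi"]
    return Transcript(
        transcript_id=tid, gene_id=gene_id, source=source,
        exons=[Interval(chrom, s, e, strand) for s, e in exons],
        cds=[Interval(chrom, s, e, strand)
             for s, e in _cds_pieces(exons, cds_lo, cds_hi)])


def _shift_internal_boundary(exons: list[tuple[int, int]], delta: int):
    """Move one internal exon boundary by *delta*; span endpoints unchanged."""
    exons = [list(e) for e in exons]
    if len(exons) >= 2:
        exons[0][1] += delta  # donor site of the first intron
    return [tuple(e) for e in exons]


def generate_gene_models(
    config: SimConfig,
    genome: GenomeSequence,
) -> tuple[list[Transcript], list[Transcript], TruthTable]:
    """Place genes and emit the two prediction sets plus ground truth.

    Genes are placed non-overlapping with >= 1 kb spacing except for the
    planted near-neighbour pairs; each gene's transcripts are assigned to
    the sets according to the agreement mixture, a fraction is flagged as
    planted lncRNA, and each non-lncRNA gene carries a planted class and a
    planted representative isoform (decided by quantitative evidence the
    evidence generator will emit).
    """
    config.validate()
    rng = _rng(config.seed, "genes")
    truth = TruthTable()
    chrom_names = list(genome.chroms)
    gap_by_chrom: dict[str, list[Interval]] = {}
    for g in genome.gap_runs():
        gap_by_chrom.setdefault(g.chrom, []).append(g)

    n_lnc = int(round(config.lncrna_fraction * config.n_genes))
    n_classified = config.n_genes - n_lnc
    classes = rng.choice(GENE_CLASSES, size=max(n_classified, 1),
                         p=[config.class_mixture[c] for c in GENE_CLASSES])
    agreements = rng.choice(
        AGREEMENT_CATEGORIES, size=config.n_genes,
        p=[config.agreement_mixture[c] for c in AGREEMENT_CATEGORIES])

    pair_specs = list(config.proximity_pair_specs)
    genes_out: list[GeneModel] = []
    set_a: list[Transcript] = []
    set_b: list[Transcript] = []
    order_counter = 0
    gi = 0
    ci = 0
    cursor = 2000
    n_pairs_started = 0
    pending_pair: tuple | None = None  # (kind, value, prev_struct, prev_gid)

    def overlaps_gap(chrom, start, end):
        return any(g.start < end and start < g.end
                   for g in gap_by_chrom.get(chrom, ()))

    while gi < config.n_genes:
        if ci >= config.n_chroms:
            raise ConfigError(
                f"ran out of sequence after placing {gi} of {config.n_genes} "
                f"genes; increase chrom_length or n_chroms")
        chrom = chrom_names[ci]
        gid = f"gene_{gi + 1:05d}"
        is_lnc = gi >= n_classified

        # a pair partner must land on the same chromosome, right after its
        # host; the host's placement reserved the extra room
        # does this gene host a planted near-neighbour pair?
        hosts_pair = (pending_pair is None and n_pairs_started < len(pair_specs)
                      and not is_lnc)
        next_spec = pair_specs[n_pairs_started] if hosts_pair else None

        if pending_pair is not None:
            kind, value, prev_struct, prev_gid = pending_pair
            pending_pair = None
            if kind == "same":
                start = prev_struct["end"] + value  # exact planted distance
                strand = prev_struct["strand"]
            else:  # opposite strands, 3'-terminal exons overlapping by *value*
                strand = "-"  # host was forced to "+"; 3' ends meet here
                start = prev_struct["end"] - value
            struct = _gene_structure(rng, chrom, start, strand)
            truth.flagged_pairs.append((prev_gid, gid))
            is_partner = True
        else:
            spacing = 3500 + int(rng.exponential(1500))
            start = cursor + spacing
            strand = "+" if rng.random() < 0.5 else "-"
            if next_spec is not None and next_spec[0] == "opposite":
                # the 3' end of a + gene is its right edge, where the
                # partner's (genomically first) 3' exon will overlap it
                strand = "+"
            struct = _gene_structure(rng, chrom, start, strand)
            is_partner = False
        tail_margin = 10_000 if hosts_pair else 2000

        if struct["end"] + tail_margin > len(genome.chroms[chrom]):
            if is_partner:
                raise ConfigError("pair partner fell off the chromosome")
            ci += 1
            cursor = 2000
            continue
        if not is_partner and overlaps_gap(
                chrom, struct["exons"][0][0] - 3200,
                struct["end"] + tail_margin):
            cursor = struct["end"]
            continue

        # isoforms: margin variation at the 3' (transcription) CDS end keeps
        # the translation start shared across isoforms, and makes CDS
        # lengths distinct for the ranking cascade
        n_iso = 1 if is_lnc else int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        agreement = agreements[gi]
        transcripts: list[Transcript] = []
        emitted_ids: list[str] = []
        for iso in range(n_iso):
            shrink = 33 * iso
            if struct["strand"] != "-":
                cds_lo, cds_hi = struct["cds_lo"], struct["cds_hi"] - shrink
            else:
                cds_lo, cds_hi = struct["cds_lo"] + shrink, struct["cds_hi"]
            iso_agreement = agreement if iso == 0 else "identical"
            a_id = f"{gid}.A{iso + 1}"
            b_id = f"{gid}.B{iso + 1}"
            if iso_agreement == "identical":
                ta = _build_transcript(a_id, gid, "setA", struct, cds_lo, cds_hi)
                tb = _build_transcript(b_id, gid, "setB", struct, cds_lo, cds_hi)
                set_a.append(ta)
                set_b.append(tb)
                transcripts.append(tb)  # the survivor after Rule 1
                truth.agreement[a_id] = truth.agreement[b_id] = iso_agreement
                emitted_ids += [a_id, b_id]
            elif iso_agreement == "same-bounds-diff-exons":
                ta = _build_transcript(a_id, gid, "setA", struct, cds_lo, cds_hi)
                exons_b = _shift_internal_boundary(struct["exons"], -3)
                tb = _build_transcript(b_id, gid, "setB", struct, cds_lo, cds_hi,
                                       exons=exons_b)
                set_a.append(ta)
                set_b.append(tb)
                transcripts.extend([ta, tb])
                truth.agreement[a_id] = truth.agreement[b_id] = iso_agreement
                emitted_ids += [a_id, b_id]
            elif iso_agreement == "setA-only":
                ta = _build_transcript(a_id, gid, "setA", struct, cds_lo, cds_hi)
                set_a.append(ta)
                transcripts.append(ta)
                truth.agreement[a_id] = iso_agreement
                emitted_ids.append(a_id)
            elif iso_agreement == "setB-only":
                tb = _build_transcript(b_id, gid, "setB", struct, cds_lo, cds_hi)
                set_b.append(tb)
                transcripts.append(tb)
                truth.agreement[b_id] = iso_agreement
                emitted_ids.append(b_id)
            else:  # overlapping-conflict: different spans, same-strand CDS overlap
                ta = _build_transcript(a_id, gid, "setA", struct, cds_lo, cds_hi)
                exons_b = [(s, e) for s, e in struct["exons"]]
                exons_b[-1] = (exons_b[-1][0], exons_b[-1][1] + 120)
                tb = _build_transcript(b_id, gid, "setB", struct,
                                       cds_lo, cds_hi, exons=exons_b)
                set_a.append(ta)
                set_b.append(tb)
                transcripts.extend([ta, tb])
                truth.agreement[a_id] = truth.agreement[b_id] = iso_agreement
                emitted_ids += [a_id, b_id]
        for tid in emitted_ids:
            truth.lncrna[tid] = is_lnc
            truth.junction_support.setdefault(tid, True)
        for t in transcripts:
            t.attributes["prediction_order"] = str(order_counter)
            order_counter += 1

        genes_out.append(GeneModel(gid, transcripts))
        if not is_lnc:
            truth.gene_class[gid] = str(classes[gi])
        cursor = max(cursor, struct["end"])
        if hosts_pair:
            pending_pair = (*pair_specs[n_pairs_started], struct, gid)
            n_pairs_started += 1
        gi += 1

    # proximity truth: which planted pairs the review should flag, and which
    # transcript loses junction support (hence gets removed)
    flag_rng = _rng(config.seed, "proximity")
    truly_flagged = []
    for (ga, gb), (kind, value) in zip(truth.flagged_pairs, pair_specs):
        if kind == "same" and value >= 150:
            continue  # at/over the threshold: not flagged
        truly_flagged.append((ga, gb))
        victim_gene = ga if flag_rng.random() < 0.5 else gb
        cands = next(g for g in genes_out
                     if g.gene_id == victim_gene).transcripts
        victim = cands[int(flag_rng.integers(len(cands)))]
        truth.junction_support[victim.transcript_id] = False
        truth.removed_by_proximity.add(victim.transcript_id)
    truth.flagged_pairs = truly_flagged

    for t in set_a + set_b:
        truth.junction_support.setdefault(t.transcript_id, True)
        truth.lncrna.setdefault(t.transcript_id, False)

    # provisional planted representative; the evidence generator keeps it
    # where a quantitative axis (homology e-value or expression breadth) can
    # be planted to favour it, and overrides it to the structural winner
    # (longest CDS, then first predicted) for evidence-free genes
    rep_rng = _rng(config.seed, "representative")
    for gene in genes_out:
        if gene.gene_id not in truth.gene_class:
            continue
        cands = gene.transcripts
        winner = cands[int(rep_rng.integers(len(cands)))]
        truth.representative[gene.gene_id] = winner.transcript_id
    truth.genes = genes_out
    truth.set_a = set_a
    truth.set_b = set_b
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def _class_axes(cls: str, rng) -> tuple[bool, bool, bool]:
    """(CAGE, RNA-seq, BLAST) axes consistent with the planted class."""
    if cls == "N1":
        return True, True, True
    if cls == "N2":
        return (True, True, False) if rng.random() < 0.5 else (True, False, True)
    if cls == "N3":
        return False, True, True
    if cls == "N4":
        return (True, False, False) if rng.random() < 0.5 else (False, True, False)
    if cls == "N5":
        return False, False, True
    return False, False, False


@dataclass
class EvidenceFiles:
    cage: list          # CageCluster
    expression: pd.DataFrame
    homology: pd.DataFrame
    coding_calls: pd.DataFrame
    methylation: pd.DataFrame
    axes: dict[str, tuple[bool, bool, bool]]  # per gene


def generate_evidence(config: SimConfig, truth: TruthTable) -> EvidenceFiles:
    """Emit CAGE/expression/homology/coding-potential/methylation inputs
    consistent with each gene's planted class, and fix the planted
    representative so that exactly one ranking criterion discriminates."""
    from .evidence import CageCluster

    rng = _rng(config.seed, "evidence")
    meth_rng = _rng(config.seed, "methylation")
    tissues = [f"tissue_{i + 1}" for i in range(config.n_tissues)]

    clusters: list = []
    expr_rows: dict[str, np.ndarray] = {}
    hom_rows: list[dict] = []
    coding_rows: list[dict] = []
    axes_by_gene: dict[str, tuple[bool, bool, bool]] = {}

    # every emitted transcript id (both sets, including copies that the merge
    # will collapse) needs coding-potential verdicts and expression rows
    all_tids = sorted(truth.agreement)
    ids_by_gene: dict[str, list[str]] = {}
    for tid in all_tids:
        ids_by_gene.setdefault(tid.rsplit(".", 1)[0], []).append(tid)

    # transcript windows, for decoy placement checks
    def in_any_window(chrom: str, pos: int) -> bool:
        for g in truth.genes:
            for t in g.transcripts:
                cs = t.cds_start
                if cs is None or t.chrom != chrom:
                    continue
                lo, hi = ((cs - 3000, cs + 10) if t.strand != "-"
                          else (cs - 10, cs + 3000))
                if lo <= pos <= hi:
                    return True
        return False

    chrom_lengths = {}
    for g in truth.genes:
        chrom_lengths.setdefault(g.chrom, 0)
        chrom_lengths[g.chrom] = max(chrom_lengths[g.chrom], g.end + 5000)

    for gene in truth.genes:
        gid = gene.gene_id
        isoforms = gene.transcripts
        is_lnc = truth.lncrna.get(isoforms[0].transcript_id, False)
        cls = truth.gene_class.get(gid)

        if is_lnc or cls is None:
            # both callers non-coding, no homology, no expression; the
            # set-A/set-B twins share the verdicts
            for tid in ids_by_gene.get(gid, []):
                for caller in ("coding_caller_1", "coding_caller_2"):
                    coding_rows.append({"transcript_id": tid,
                                        "caller": caller,
                                        "verdict": "non-coding"})
                expr_rows[tid] = rng.uniform(
                    0, 0.4 * config.tpm_threshold, config.n_tissues)
            continue

        c_ax, r_ax, b_ax = _class_axes(cls, rng)
        axes_by_gene[gid] = (c_ax, r_ax, b_ax)

        # decide the planted representative from the discriminating axis
        if b_ax:
            winner = truth.representative[gid]
        elif r_ax:
            winner = truth.representative[gid]
        else:
            # no quantitative evidence: longest CDS wins, then first order
            winner = min(isoforms,
                         key=lambda t: (-t.cds_length,
                                        int(t.attributes["prediction_order"]))
                         ).transcript_id
            truth.representative[gid] = winner

        # CAGE: one cluster with summit near the shared translation start
        if c_ax:
            t0 = isoforms[0]
            cs = t0.cds_start
            if t0.strand != "-":
                summit = int(rng.integers(cs - 300, cs + 11))
            else:
                summit = int(rng.integers(cs - 10, cs + 301))
            width = int(rng.integers(1, 51))
            start = max(0, summit - int(rng.integers(0, width)))
            clusters.append(CageCluster(
                Interval(t0.chrom, start, start + width, t0.strand),
                summit, float(rng.integers(5, 500))))
            truth.cage_target[len(clusters) - 1] = gid

        # expression: distinct tissue breadths, winner broadest
        if r_ax:
            breadths = rng.choice(np.arange(1, config.n_tissues + 1),
                                  size=len(isoforms), replace=False)
            # give the winner the largest breadth
            wi = [t.transcript_id for t in isoforms].index(winner)
            bi = int(np.argmax(breadths))
            breadths[wi], breadths[bi] = breadths[bi], breadths[wi]
            for t, br in zip(isoforms, breadths):
                row = rng.uniform(0, 0.4 * config.tpm_threshold,
                                  config.n_tissues)
                on = rng.choice(config.n_tissues, size=int(br), replace=False)
                row[on] = config.tpm_threshold + rng.lognormal(1.5, 1.0, int(br))
                expr_rows[t.transcript_id] = row
        elif b_ax:
            # homology decides the representative before TPM is consulted,
            # so sub-threshold background expression is harmless here
            for t in isoforms:
                expr_rows[t.transcript_id] = rng.uniform(
                    0, 0.4 * config.tpm_threshold, config.n_tissues)
        else:
            # evidence-free genes (N6, CAGE-only N4): no quantification at
            # all, so the longest-CDS criterion discriminates cleanly
            for t in isoforms:
                expr_rows[t.transcript_id] = np.zeros(config.n_tissues)

        # homology: qualifying hits, winner strictly best e-value
        if b_ax:
            for t in isoforms:
                best_exp = (rng.uniform(-50, -30) if t.transcript_id == winner
                            else rng.uniform(-25, -6))
                for h in range(int(rng.integers(1, 4))):
                    hom_rows.append({
                        "query": t.transcript_id,
                        "subject": f"ref_{rng.integers(1, 10 ** 6):06d}",
                        "pident": float(rng.uniform(60, 100)),
                        "qcov": float(rng.uniform(50, 100)),
                        "evalue": 10.0 ** (best_exp + 3 * h),
                    })
            # a kept edge case: one caller says non-coding but homology rescues
            if rng.random() < 0.10:
                coding_rows.append({"transcript_id": isoforms[0].transcript_id,
                                    "caller": "coding_caller_1",
                                    "verdict": "non-coding"})
        else:
            # occasional decoy hit that fails the support thresholds
            if rng.random() < 0.30:
                t = isoforms[0]
                hom_rows.append({
                    "query": t.transcript_id,
                    "subject": f"ref_{rng.integers(1, 10 ** 6):06d}",
                    "pident": float(rng.uniform(40, 80)),
                    "qcov": float(rng.uniform(5, 49.5)),
                    "evalue": 10.0 ** rng.uniform(-20, -6),
                })

    # decoy CAGE clusters in intergenic space, outside every window
    n_decoys = max(2, len(truth.genes) // 20)
    chroms = sorted(chrom_lengths)
    for _ in range(n_decoys):
        for _attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, chrom_lengths[chrom]))
            if not in_any_window(chrom, pos):
                width = int(rng.integers(1, 51))
                start = max(0, pos - width // 2)
                clusters.append(CageCluster(
                    Interval(chrom, start, start + width, "."),
                    min(max(pos, start), start + width - 1),
                    float(rng.integers(1, 50))))
                break

    # default "coding" verdicts for everyone not already listed
    listed = {r["transcript_id"] for r in coding_rows}
    for tid in all_tids:
        if tid not in listed:
            for caller in ("coding_caller_1", "coding_caller_2"):
                coding_rows.append({"transcript_id": tid, "caller": caller,
                                    "verdict": "coding"})

    expression = pd.DataFrame.from_dict(expr_rows, orient="index",
                                        columns=tissues)
    expression.index.name = "transcript_id"
    homology = pd.DataFrame(
        hom_rows, columns=["query", "subject", "pident", "qcov", "evalue"])
    coding_calls = pd.DataFrame(coding_rows)
    methylation = _generate_methylation(config, truth, meth_rng)
    return EvidenceFiles(clusters, expression, homology, coding_calls,
                         methylation, axes_by_gene)


def _generate_methylation(config: SimConfig, truth: TruthTable,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Per-cytosine calls over each classified gene +/- 600 nt whose mean
    level follows the class template: CG/CHG troughs at the translation
    start/end for expressed classes, uniformly dense CG/CHG for silent
    classes, CHH low throughout."""
    frames = []
    for gene in truth.genes:
        gid = gene.gene_id
        cls = truth.gene_class.get(gid)
        if cls is None:
            continue
        rep = gene.get(truth.representative[gid])
        if not rep.cds:
            continue
        a1, a2 = sorted((rep.cds_start, rep.cds_stop))
        lo, hi = a1 - 600, a2 + 600
        positions = np.arange(lo, hi)
        keep = rng.random(len(positions)) < 0.22
        pos = positions[keep]
        if len(pos) == 0:
            continue
        ctx = rng.choice(np.array(["CG", "CHG", "CHH"]), size=len(pos),
                         p=[0.34, 0.33, 0.33])
        strand = rng.choice(np.array(["+", "-"]), size=len(pos))
        d = np.minimum(np.abs(pos - a1), np.abs(pos - a2)).astype(float)
        kind = "expressed" if cls in ("N1", "N2", "N3", "N4") else "silent"
        mean = np.empty(len(pos))
        for context, (body, dip) in _METH_TEMPLATES[kind].items():
            m = ctx == context
            mean[m] = body - (body - dip) * np.exp(-((d[m] / _DIP_WIDTH) ** 2))
        kappa = 40.0
        level = rng.beta(np.maximum(mean * kappa, 1e-3),
                         np.maximum((1 - mean) * kappa, 1e-3))
        n_total = rng.integers(10, 41, len(pos))
        n_meth = rng.binomial(n_total, level)
        frames.append(pd.DataFrame({
            "chrom": rep.chrom, "pos": pos, "strand": strand, "context": ctx,
            "n_methylated": n_meth, "n_total": n_total}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "n_methylated", "n_total"])
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos"], kind="stable",
                          ignore_index=True)


# ---------------------------------------------------------------------------
# gene/repeat density landscape
# ---------------------------------------------------------------------------

def generate_density_landscape(
    seed: int,
    n_windows: int = 60,
    window_bp: int = 1_000_000,
    centromere_fraction: float = 0.3,
) -> tuple[dict[str, list[Interval]], dict[str, int]]:
    """One chromosome with a repeat-dense pericentromere and gene-dense
    arms: Copia-like retroelements concentrate in the central
    *centromere_fraction* of the chromosome (anti-correlated with genes),
    while LINE-like elements track gene density (positively correlated).

    Returns ({"genes": [...], "copia": [...], "line": [...]},
    chromosome-length map), with per-window counts drawn Poisson around
    the planted intensity profile.
    """
    rng = _rng(seed, "density")
    chrom = "chrPC"
    lengths = {chrom: n_windows * window_bp}
    mid = n_windows / 2.0
    half_centro = centromere_fraction * n_windows / 2.0
    features: dict[str, list[Interval]] = {"genes": [], "copia": [], "line": []}
    for w in range(n_windows):
        in_centro = abs(w + 0.5 - mid) <= half_centro
        lam_gene = 5.0 if in_centro else 40.0
        lam_copia = 60.0 if in_centro else 5.0
        n_gene = int(rng.poisson(lam_gene))
        n_copia = int(rng.poisson(lam_copia))
        n_line = int(rng.poisson(0.8 * n_gene + 2.0))
        for kind, n in (("genes", n_gene), ("copia", n_copia), ("line", n_line)):
            starts = rng.integers(w * window_bp, (w + 1) * window_bp - 100, n)
            for s in np.sort(starts):
                features[kind].append(Interval(chrom, int(s), int(s) + 100))
    return features, lengths


# ---------------------------------------------------------------------------
# diverged genome pair with planted SVs
# ---------------------------------------------------------------------------

def generate_sv_pair(
    config: SimConfig,
    genome_a: GenomeSequence,
) -> tuple[GenomeSequence, list[StructuralVariant], list[tuple[str, int]]]:
    """Derive genome B from genome A by applying the configured deletions,
    tandem duplications, reciprocal translocations and inversions, plus
    background SNPs; truth records coordinates on both genomes.

    Gap-overlap decoy deletions (``n_sv_gap_decoys``) are planted on top of
    assembly gaps so the gap filter has true positives to drop.
    """
    rng = _rng(config.seed, "sv")
    chrom_names = list(genome_a.chroms)
    lengths = genome_a.lengths()
    gaps = genome_a.gap_runs()

    size_ranges = {
        "deletion": config.deletion_size_range,
        "duplication": config.duplication_size_range,
        "translocation": config.translocation_size_range,
        "inversion": config.inversion_size_range,
    }

    # --- plan non-overlapping events on A ---------------------------------
    planned: dict[str, list[dict]] = {c: [] for c in chrom_names}
    margin = 3000

    def free(chrom, start, end):
        if start < 5000 or end > lengths[chrom] - 5000:
            return False
        for ev in planned[chrom]:
            if start - margin < ev["end"] and ev["start"] < end + margin:
                return False
        return True

    def gap_free(chrom, start, end):
        return not any(g.chrom == chrom and g.start < end and start < g.end
                       for g in gaps)

    sv_id = 0
    events: list[dict] = []

    def place(kind, size, must_overlap_gap=False, pair_with=None):
        nonlocal sv_id
        for _attempt in range(500):
            if must_overlap_gap:
                g = gaps[int(rng.integers(len(gaps)))]
                start = max(5000, g.start - int(rng.integers(0, size // 2)))
                chrom = g.chrom
            else:
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                if pair_with is not None and len(chrom_names) > 1:
                    others = [c for c in chrom_names if c != pair_with]
                    chrom = others[int(rng.integers(len(others)))]
                start = int(rng.integers(5000, lengths[chrom] - size - 5000))
            end = start + size
            if not free(chrom, start, end):
                continue
            if not must_overlap_gap and not gap_free(chrom, start, end):
                continue
            sv_id += 1
            ev = {"id": f"sv_{sv_id:03d}", "type": kind, "chrom": chrom,
                  "start": start, "end": end, "decoy_gap": must_overlap_gap}
            planned[chrom].append(ev)
            events.append(ev)
            return ev
        raise ConfigError(f"cannot place a {size} bp {kind} without overlap")

    for kind in ("deletion", "duplication", "inversion"):
        lo, hi = size_ranges[kind]
        for _ in range(config.sv_counts.get(kind, 0)):
            place(kind, int(rng.integers(lo, hi + 1)))
    lo, hi = size_ranges["deletion"]
    for _ in range(config.n_sv_gap_decoys):
        if gaps:
            place("deletion", int(rng.integers(max(lo, 2000), hi + 1)),
                  must_overlap_gap=True)
    # reciprocal translocations: a pair of swapped segments
    lo, hi = size_ranges["translocation"]
    tra_pairs = []
    for _ in range(config.sv_counts.get("translocation", 0)):
        ev1 = place("translocation", int(rng.integers(lo, hi + 1)))
        ev2 = place("translocation", int(rng.integers(lo, hi + 1)),
                    pair_with=ev1["chrom"])
        ev1["partner"], ev2["partner"] = ev2["id"], ev1["id"]
        tra_pairs.append((ev1, ev2))

    # --- build genome B ----------------------------------------------------
    by_id = {ev["id"]: ev for ev in events}
    b_chroms: dict[str, str] = {}
    blocks: dict[str, list[tuple[int, int, int]]] = {}  # collinear (a0, a1, b0)
    placed_b: dict[str, tuple[str, int, int]] = {}      # event id -> B location

    for chrom in chrom_names:
        seq = genome_a.chroms[chrom]
        evs = sorted(planned[chrom], key=lambda e: e["start"])
        parts: list[str] = []
        blist: list[tuple[int, int, int]] = []
        cur = 0
        b_pos = 0

        def emit_collinear(a0, a1):
            nonlocal b_pos
            if a1 > a0:
                parts.append(seq[a0:a1])
                blist.append((a0, a1, b_pos))
                b_pos += a1 - a0

        for ev in evs:
            emit_collinear(cur, ev["start"])
            seg = seq[ev["start"]:ev["end"]]
            if ev["type"] == "deletion":
                placed_b[ev["id"]] = (chrom, b_pos, b_pos + 1)
            elif ev["type"] == "duplication":
                parts.append(seg + seg)
                placed_b[ev["id"]] = (chrom, b_pos, b_pos + 2 * len(seg))
                b_pos += 2 * len(seg)
            elif ev["type"] == "inversion":
                parts.append(revcomp(seg))
                placed_b[ev["id"]] = (chrom, b_pos, b_pos + len(seg))
                b_pos += len(seg)
            else:  # translocation: the partner's segment lands here
                partner = by_id[ev["partner"]]
                pseg = genome_a.chroms[partner["chrom"]][
                    partner["start"]:partner["end"]]
                parts.append(pseg)
                placed_b[partner["id"]] = (chrom, b_pos, b_pos + len(pseg))
                b_pos += len(pseg)
            cur = ev["end"]
        emit_collinear(cur, len(seq))
        b_chroms[chrom] = "".join(parts)
        blocks[chrom] = blist

    # --- background SNPs ---------------------------------------------------
    snps: list[tuple[str, int]] = []
    subst = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    b_mut = {c: bytearray(s.encode()) for c, s in b_chroms.items()}
    for chrom in chrom_names:
        n_snps = rng.binomial(lengths[chrom], config.divergence_snp_rate)
        cand = np.sort(rng.choice(lengths[chrom], size=n_snps, replace=False))
        blist = blocks[chrom]
        starts = np.array([b[0] for b in blist])
        for p in cand.tolist():
            i = int(np.searchsorted(starts, p, side="right")) - 1
            if i < 0:
                continue
            a0, a1, b0 = blist[i]
            if not (a0 + 50 <= p < a1 - 50):  # keep clear of block edges
                continue
            base = genome_a.chroms[chrom][p]
            if base == "N":
                continue
            new = subst[base][int(rng.integers(3))]
            b_mut[chrom][b0 + (p - a0)] = ord(new)
            snps.append((chrom, p))

    genome_b = GenomeSequence(genome_a.name + "_derived",
                              {c: bytes(b).decode() for c, b in b_mut.items()})

    svs = []
    for ev in events:
        bc = placed_b.get(ev["id"])
        svs.append(StructuralVariant(
            ev["id"], ev["type"],
            Interval(ev["chrom"], ev["start"], ev["end"]),
            Interval(*bc) if bc else None,
            size=ev["end"] - ev["start"],
            overlaps_gap=not gap_free(ev["chrom"], ev["start"], ev["end"])))
    return genome_b, svs, snps


def non_invariant_intervals(svs: list[StructuralVariant],
                            snps: list[tuple[str, int]]) -> list[Interval]:
    """A-genome intervals that break base identity with B: SNP positions,
    deleted regions and inverted regions (duplicated and translocated
    sequence is still present identically in B)."""
    out = [Interval(c, p, p + 1) for c, p in snps]
    for sv in svs:
        if sv.type in ("deletion", "inversion"):
            out.append(sv.coords_a)
    return out


# ---------------------------------------------------------------------------
# one-call convenience wrapper
# ---------------------------------------------------------------------------

def simulate_annotation_inputs(config: SimConfig):
    """Genome + gene sets + evidence, as one deterministic bundle."""
    genome, gaps = generate_genome(config)
    set_a, set_b, truth = generate_gene_models(config, genome)
    files = generate_evidence(config, truth)
    return genome, gaps, set_a, set_b, truth, files
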