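"""Six-class evidence classification of gene models and representative
isoform selection.

Classes, from three boolean evidence axes (C = CAGE, R = RNA-seq,
B = homology), read so that the six labels partition all eight
combinations:

=====  ==========================
class  evidence
=====  ==========================
N1     C and R and B
N2     C and exactly one of R, B
N3     R and B, no C
N4     exactly one of C, R, no B
N5     B only
N6     no support
=====  ==========================

Genes in N1-N4 carry at least one source of expression evidence; N5/N6 do
not.  The representative isoform is chosen by a strict lexicographic
cascade: best per-isoform class, then best homology e-value, breadth of
tissues expressed, highest TPM, longest CDS, and finally the first model
predicted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from ._util import percent
from .evidence import EvidenceBundle
from .gffio import GeneModel


class GeneClass(str, Enum):
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    N4 = "N4"
    N5 = "N5"
    N6 = "N6"

    @property
    def rank(self) -> int:
        """1 (best supported) .. 6 (unsupported)."""
        return int(self.value[1])


EXPRESSED_CLASSES = (GeneClass.N1, GeneClass.N2, GeneClass.N3, GeneClass.N4)


def classify_axes(cage: bool, rnaseq: bool, blast: bool) -> GeneClass:
    """Total map {0,1}^3 -> {N1..N6}."""
    c, r, b = bool(cage), bool(rnaseq), bool(blast)
    if c and r and b:
        return GeneClass.N1
    if c and (r != b):
        return GeneClass.N2
    if r and b:  # c is False here
        return GeneClass.N3
    if (c != r) and not b:
        return GeneClass.N4
    if b:  # c and r both False
        return GeneClass.N5
    return GeneClass.N6


def classify_gene_models(
    genes: list[GeneModel],
    bundles: dict[str, EvidenceBundle],
) -> dict[str, GeneClass]:
    """Gene-level class from the OR of its isoforms' evidence axes.

    A gene with no evidence rows at all is classified from all-false axes
    (N6) with a warning."""
    import logging
    log = logging.getLogger(__name__)
    out: dict[str, GeneClass] = {}
    for g in genes:
        rows = [bundles[t.transcript_id] for t in g.transcripts
                if t.transcript_id in bundles]
        if len(rows) < len(g.transcripts):
            log.warning("gene %s: missing evidence for some isoforms", g.gene_id)
        c = any(b.cage_supported for b in rows)
        r = any(b.rnaseq_supported for b in rows)
        b_ = any(b.blast_supported for b in rows)
        cls = classify_axes(c, r, b_)
        out[g.gene_id] = cls
        g.gene_class = cls.value
    return out


def _ranking_key(bundle: EvidenceBundle) -> tuple:
    """Lexicographic sort key; smaller is better."""
    own_class = classify_axes(*bundle.axes)
    evalue = bundle.best_evalue if bundle.best_evalue is not None else float("inf")
    return (
        own_class.rank,              # 1. highest class
        evalue,                      # 2. best homology e-value (absent = worst)
        -bundle.n_tissues_expressed,  # 3. breadth of tissues
        -bundle.max_tpm,             # 4. expression level
        -bundle.cds_length,          # 5. longest CDS
        bundle.prediction_order,     # 6. first model predicted
    )


def select_representative(
    gene: GeneModel,
    bundles: dict[str, EvidenceBundle],
) -> str:
    """Choose the representative isoform by the six-criterion cascade."""
    best = min(
        gene.transcripts,
        key=lambda t: _ranking_key(
            bundles.get(t.transcript_id, EvidenceBundle(t.transcript_id))),
    )
    gene.representative = best.transcript_id
    return best.transcript_id


@dataclass
class ClassSummary:
    counts: dict[str, int]
    n_genes_total: int
    percent_expression_supported: float

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts),
                "n_genes_total": self.n_genes_total,
                "percent_expression_supported": self.percent_expression_supported}


def summarize_classes(classification: dict[str, GeneClass]) -> ClassSummary:
    """Class counts plus the percentage of genes with any expression
    evidence (classes N1-N4), rounded half-up to one decimal."""
    if not classification:
        raise ValueError("empty classification")
    counts = Counter(c.value for c in classification.values())
    n = len(classification)
    n_expr = sum(counts[c.value] for c in EXPRESSED_CLASSES)
    return ClassSummary(
        counts={c.value: counts.get(c.value, 0) for c in GeneClass},
        n_genes_total=n,
        percent_expression_supported=percent(n_expr, n),
    )


def expression_supported_percent(n_supported: int, n_total: int) -> float:
    """Share of gene models with >= 1 expression evidence source, in %."""
    return percent(n_supported, n_total)
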