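"""End-to-end pipeline experiments on synthetic data with planted truth.

Each function builds its inputs with the generators in
:mod:`palmannot.synthetic_data`, runs the relevant pipeline stages, and
scores the result against the planted ground truth.  They are the
building blocks of the reproduction script and of the integration tests,
and double as worked examples of how the pieces compose.
"""

from __future__ import annotations

import numpy as np

from . import classify as C
from . import evidence as E
from . import merge as M
from . import profiles as P
from . import svprimers as S
from .synthetic_data import (SimConfig, generate_density_landscape,
                             generate_genome, generate_gene_models,
                             generate_evidence, generate_sv_pair,
                             non_invariant_intervals,
                             simulate_annotation_inputs)


def _evidence_bundles(genes, files, tpm_threshold=1.0):
    _, cage_flags = E.associate_cage(files.cage, genes)
    rnaseq = E.rnaseq_support(files.expression, tpm_threshold)
    blast = E.blast_support(files.homology)
    order = {t.transcript_id: int(t.attributes.get("prediction_order", 0))
             for g in genes for t in g.transcripts}
    return E.build_evidence(genes, cage_flags, rnaseq, blast, order)


def classification_recovery(seed: int, n_genes: int = 500) -> dict:
    """Classify a planted-class synthetic gene set and score recovery of
    both the six-class labels and the representative isoforms."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_chroms=2,
                    chrom_length=max(1_000_000, n_genes * 9000),
                    lncrna_fraction=0.0)  # every gene carries a planted class
    genome, _ = generate_genome(cfg)
    _, _, truth = generate_gene_models(cfg, genome)
    files = generate_evidence(cfg, truth)
    genes = [g for g in truth.genes if g.gene_id in truth.gene_class]
    bundles = _evidence_bundles(genes, files, cfg.tpm_threshold)
    classification = C.classify_gene_models(genes, bundles)
    n_class_ok = sum(classification[g].value == truth.gene_class[g]
                     for g in classification)
    n_rep_ok = sum(
        C.select_representative(g, bundles) == truth.representative[g.gene_id]
        for g in genes)
    n = len(genes)
    return {
        "n_genes": n,
        "class_recovery_percent": 100.0 * n_class_ok / n,
        "representative_recovery_percent": 100.0 * n_rep_ok / n,
        "summary": C.summarize_classes(classification).as_dict(),
    }


def merge_equivalence(seed: int, n_per_set: int = 300) -> dict:
    """Merge two planted prediction sets and compare with the quadratic
    all-pairs reference implementation."""
    cfg = SimConfig(seed=seed, n_genes=max(40, int(n_per_set * 0.75)),
                    n_chroms=2,
                    chrom_length=max(1_000_000, n_per_set * 9000))
    genome, _ = generate_genome(cfg)
    set_a, set_b, truth = generate_gene_models(cfg, genome)
    set_a, set_b = set_a[:n_per_set], set_b[:n_per_set]
    merged, report = M.merge_predictions(set_a, set_b)
    brute = M.merge_predictions_bruteforce(set_a, set_b)

    ids_fast = sorted(t.transcript_id for t in merged)
    ids_brute = sorted(t.transcript_id for t in brute)
    grouping = lambda ts: sorted(  # noqa: E731
        tuple(sorted(t.transcript_id for t in ts if t.gene_id == g))
        for g in {t.gene_id for t in ts})
    identical = (ids_fast == ids_brute
                 and grouping(merged) == grouping(brute))
    return {
        "n_input": len(set_a) + len(set_b),
        "oracle_agreement_percent": 100.0 if identical else 0.0,
        "count_identity_holds": report.n_output == len(merged),
        "report": report.as_dict(),
    }


def methylation_contrast(seed: int, genes_per_class: int = 200) -> dict:
    """Build class-templated methylation calls and measure the CG contrast
    between silent (N5/N6) and expressed (N1) genes at the translation
    start."""
    n_genes = genes_per_class * 6
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_chroms=4,
                    chrom_length=max(1_000_000, n_genes * 9500 // 4),
                    class_mixture={c: 1 / 6 for c in
                                   ("N1", "N2", "N3", "N4", "N5", "N6")},
                    lncrna_fraction=0.0)
    genome, _ = generate_genome(cfg)
    _, _, truth = generate_gene_models(cfg, genome)
    files = generate_evidence(cfg, truth)
    genes = [g for g in truth.genes if g.gene_id in truth.gene_class]
    for g in genes:
        g.gene_class = truth.gene_class[g.gene_id]
        g.representative = truth.representative[g.gene_id]
    profs = P.methylation_metaprofile(files.methylation, genes)
    by = {(p.gene_class, p.context, p.anchor): p for p in profs}

    def anchor_mean(cls):
        p = by[(cls, "CG", "translation_start")]
        return float(p.mean_level[np.where(p.offsets == 0)[0][0]])

    n1 = by[("N1", "CG", "translation_start")]
    body = (n1.offsets >= 250) & (n1.offsets < 500)
    trough_depth = float(np.nanmean(n1.mean_level[body]) - anchor_mean("N1"))
    return {
        "n_genes": len(genes),
        "cg_anchor_mean_n5": anchor_mean("N5"),
        "cg_anchor_mean_n6": anchor_mean("N6"),
        "n1_trough_depth": trough_depth,
    }


def sv_validation(seed: int) -> dict:
    """Plant SVs on a ~10 Mb genome pair, filter against gaps and size
    thresholds, design the diagnostic primer schemes, and verify every
    predicted genome-specificity pattern by electronic PCR."""
    cfg = SimConfig(seed=seed, n_chroms=2, chrom_length=5_000_000, n_genes=0,
                    sv_counts={"deletion": 7, "duplication": 4,
                               "translocation": 2, "inversion": 3})
    genome_a, gaps_a = generate_genome(cfg, "genomeA")
    genome_b, svs, snps = generate_sv_pair(cfg, genome_a)
    gaps_b = genome_b.gap_runs()

    survivors = S.filter_svs(svs, gaps_a, gaps_b)
    expected = [s.sv_id for s in svs
                if not s.overlaps_gap
                and (s.type == "deletion"
                     or (s.type == "inversion" and s.size >= S.INV_MIN)
                     or (s.type == "duplication" and s.size >= S.DUP_MIN)
                     or (s.type in ("translocation", "transposition")
                         and s.size >= S.TRA_MIN))]
    filter_exact = [s.sv_id for s in survivors] == expected

    mask = S.invariant_mask(genome_a, non_invariant_intervals(svs, snps))
    targets = [s for s in svs if not s.overlaps_gap
               and s.type in ("deletion", "duplication", "translocation")]
    results = S.design_sv_primers(targets, genome_a, genome_b, mask)

    n_pairs = n_match = n_designed = 0
    for sv in targets:
        res = results[sv.sv_id]
        if res["status"] != "ok":
            continue
        n_designed += 1
        for pair in res["pairs"].values():
            for genome in (genome_a, genome_b):
                n_pairs += 1
                products = S.epcr(pair, genome)
                exp = pair.expected_pattern[genome.name]
                if exp is None:
                    n_match += products == []
                else:
                    n_match += any(p[3] == exp for p in products)
    return {
        "n_planted_svs": len(svs),
        "filter_exact": filter_exact,
        "n_after_filter": len(survivors),
        "n_designable": len(targets),
        "n_designed": n_designed,
        "n_pattern_checks": n_pairs,
        "epcr_pattern_match_percent": (100.0 * n_match / n_pairs
                                       if n_pairs else float("nan")),
    }


def density_signs(seed: int) -> dict:
    """Gene/repeat density correlation signs on a constructed chromosome
    with a repeat-dense pericentromere and gene-dense arms."""
    feats, lengths = generate_density_landscape(seed)
    genes = P.window_density(feats["genes"], lengths)
    copia = P.window_density(feats["copia"], lengths)
    line = P.window_density(feats["line"], lengths)
    rho_copia, n = P.density_correlation(genes, copia)
    rho_line, _ = P.density_correlation(genes, line)
    return {"n_windows": n, "gene_copia_rho": rho_copia,
            "gene_line_rho": rho_line}


def consolidation_truth(seed: int, n_genes: int = 200) -> dict:
    """Full consolidation on a default-scale bundle; score survivor-set
    agreement with the planted transcript fates."""
    cfg = SimConfig(seed=seed, n_genes=n_genes)
    genome, gaps, set_a, set_b, truth, files = \
        simulate_annotation_inputs(cfg)
    final, report = M.consolidate(set_a, set_b, files.coding_calls,
                                  files.homology, truth.junction_support)
    expected = set()
    for g in truth.genes:
        for t in g.transcripts:
            if truth.lncrna.get(t.transcript_id):
                continue
            if t.transcript_id in truth.removed_by_proximity:
                continue
            expected.add(t.transcript_id)
    got = {t.transcript_id for t in final}
    return {
        "n_output": len(final),
        "fate_agreement_percent": 100.0 if got == expected else
        100.0 * len(got & expected) / len(got | expected),
        "report": report.as_dict(),
    }
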