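"""Determinism and class-conditional consistency of the generators."""

import numpy as np
import pytest

from palmannot import evidence as E
from palmannot.gffio import assembly_stats
from palmannot.synthetic_data import (ConfigError, SimConfig,
                                      generate_evidence, generate_genome,
                                      generate_gene_models, generate_sv_pair)


def _small_cfg(seed=1, **kw):
    kw.setdefault("n_chroms", 1)
    kw.setdefault("chrom_length", 400_000)
    kw.setdefault("n_genes", 40)
    return SimConfig(seed=seed, **kw)


def test_genome_is_deterministic_for_fixed_seed():
    cfg = _small_cfg(seed=5, chrom_length=100_000, n_genes=0)
    g1, gaps1 = generate_genome(cfg)
    g2, gaps2 = generate_genome(cfg)
    assert g1.chroms == g2.chroms
    assert gaps1 == gaps2
    g3, _ = generate_genome(_small_cfg(seed=6, chrom_length=100_000, n_genes=0))
    assert g3.chroms != g1.chroms


def test_zero_gaps_gives_zero_gap_percent():
    cfg = _small_cfg(n_genes=0, chrom_length=100_000, n_gaps_per_chrom=0)
    genome, gaps = generate_genome(cfg)
    assert gaps == []
    assert assembly_stats(genome).gap_percent == 0.0


def test_gc_content_near_half_for_uniform_background():
    cfg = SimConfig(seed=2, n_chroms=1, chrom_length=1_000_000, n_genes=0,
                    n_gaps_per_chrom=0)
    genome, _ = generate_genome(cfg)
    # binomial(1e6, 0.5): 5 sigma ~ 0.25%, spec bound 0.5%
    assert abs(assembly_stats(genome).gc_percent - 50.0) <= 0.5


def test_invalid_mixtures_rejected():
    with pytest.raises(ConfigError):
        SimConfig(class_mixture={"N1": 0.5, "N2": 0.1, "N3": 0.1, "N4": 0.1,
                                 "N5": 0.1, "N6": 0.05}).validate()
    with pytest.raises(ConfigError):
        SimConfig(n_genes=10_000, n_chroms=1, chrom_length=100_000).validate()


def test_gene_sets_deterministic_and_categories_respected():
    cfg = _small_cfg(seed=9)
    genome, _ = generate_genome(cfg)
    a1, b1, t1 = generate_gene_models(cfg, genome)
    a2, b2, t2 = generate_gene_models(cfg, genome)
    assert [t.coordinate_key() for t in a1] == [t.coordinate_key() for t in a2]
    assert t1.gene_class == t2.gene_class
    a_ids = {t.transcript_id for t in a1}
    b_ids = {t.transcript_id for t in b1}
    by_id = {t.transcript_id: t for t in a1 + b1}
    for tid, cat in t1.agreement.items():
        if cat == "identical":
            twin = tid.replace(".A", ".B") if ".A" in tid else \
                tid.replace(".B", ".A")
            assert by_id[tid].coordinate_key() == by_id[twin].coordinate_key()
        elif cat == "same-bounds-diff-exons":
            twin = tid.replace(".A", ".B") if ".A" in tid else \
                tid.replace(".B", ".A")
            assert by_id[tid].span_key() == by_id[twin].span_key()
            assert by_id[tid].exon_key() != by_id[twin].exon_key()
        elif cat == "setA-only":
            assert tid in a_ids and tid.replace(".A", ".B") not in b_ids
        elif cat == "setB-only":
            assert tid in b_ids and tid.replace(".B", ".A") not in a_ids


def test_evidence_satisfies_each_planted_class_predicate(sim):
    """For every classified gene, the emitted evidence satisfies its class's
    defining predicate, checked axis by axis."""
    truth, files = sim.truth, sim.files
    genes = [g for g in truth.genes if g.gene_id in truth.gene_class]
    _, cage_flags = E.associate_cage(files.cage, genes)
    rnaseq = E.rnaseq_support(files.expression, sim.config.tpm_threshold)
    blast = E.blast_support(files.homology)
    for g in genes:
        tids = [t.transcript_id for t in g.transcripts]
        c = any(cage_flags.get(t, False) for t in tids)
        r = any(t in rnaseq.index and rnaseq.loc[t, "supported"] for t in tids)
        b = any(t in blast.index for t in tids)
        cls = truth.gene_class[g.gene_id]
        predicate = {
            "N1": c and r and b,
            "N2": c and (r != b),
            "N3": (not c) and r and b,
            "N4": (c != r) and not b,
            "N5": (not c) and (not r) and b,
            "N6": not (c or r or b),
        }[cls]
        assert predicate, (g.gene_id, cls, (c, r, b))


def test_planted_lncrnas_fail_both_callers_and_lack_homology(sim):
    calls = sim.files.coding_calls
    hits = set(sim.files.homology["query"])
    for tid, is_lnc in sim.truth.lncrna.items():
        if not is_lnc:
            continue
        sub = calls[calls["transcript_id"] == tid]
        assert len(sub) == 2 and (sub["verdict"] == "non-coding").all()
        assert tid not in hits


def test_sv_pair_deterministic_and_conserves_sequence():
    cfg = SimConfig(seed=13, n_chroms=2, chrom_length=1_000_000, n_genes=0,
                    sv_counts={"deletion": 2, "duplication": 1,
                               "translocation": 1, "inversion": 1},
                    n_sv_gap_decoys=0,
                    deletion_size_range=(2000, 5000),
                    duplication_size_range=(2000, 4000),
                    translocation_size_range=(20_000, 30_000),
                    inversion_size_range=(5000, 10_000))
    ga, _ = generate_genome(cfg)
    gb1, svs1, snps1 = generate_sv_pair(cfg, ga)
    gb2, svs2, snps2 = generate_sv_pair(cfg, ga)
    assert gb1.chroms == gb2.chroms and snps1 == snps2
    # single deletion conservation
    dels = [s for s in svs1 if s.type == "deletion"]
    dups = [s for s in svs1 if s.type == "duplication"]
    assert len(gb1) == len(ga) - sum(d.size for d in dels) + \
        sum(d.size for d in dups)
    # duplication truth spans both copies in B
    for d in dups:
        assert len(d.coords_b) == 2 * d.size
        seg = ga.chroms[d.coords_a.chrom][d.coords_a.start:d.coords_a.end]
        got = gb1.chroms[d.coords_b.chrom][d.coords_b.start:d.coords_b.end]
        assert got == seg + seg
    # translocated segments present at their recorded B location
    for s in svs1:
        if s.type != "translocation":
            continue
        seg = ga.chroms[s.coords_a.chrom][s.coords_a.start:s.coords_a.end]
        got = gb1.chroms[s.coords_b.chrom][s.coords_b.start:s.coords_b.end]
        assert got == seg
        assert s.coords_b.chrom != s.coords_a.chrom


def test_snps_recorded_where_genomes_differ():
    cfg = SimConfig(seed=17, n_chroms=1, chrom_length=200_000, n_genes=0,
                    sv_counts={"deletion": 0, "duplication": 0,
                               "translocation": 0, "inversion": 0},
                    n_sv_gap_decoys=0, n_gaps_per_chrom=0,
                    divergence_snp_rate=0.001)
    ga, _ = generate_genome(cfg)
    gb, _, snps = generate_sv_pair(cfg, ga)
    diff = {i for i, (x, y) in
            enumerate(zip(ga.chroms["chr1"], gb.chroms["chr1"])) if x != y}
    assert diff == {p for _, p in snps}
    assert len(diff) == pytest.approx(200, abs=80)  # ~binomial(2e5, 1e-3)
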