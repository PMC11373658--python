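"""SV filtering, invariant masking, primer schemes and electronic PCR."""

import numpy as np
import pytest

from palmannot import svprimers as S
from palmannot._util import revcomp
from palmannot.gffio import GenomeSequence, Interval
from palmannot.svprimers import PrimerPair, StructuralVariant
from palmannot.synthetic_data import (SimConfig, generate_genome,
                                      generate_sv_pair,
                                      non_invariant_intervals)


def _sv(sv_id, type_, chrom, start, end, chrom_b=None, start_b=0, end_b=1):
    cb = Interval(chrom_b, start_b, end_b) if chrom_b else None
    return StructuralVariant(sv_id, type_, Interval(chrom, start, end), cb)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_size_thresholds_are_inclusive():
    svs = [
        _sv("inv_ok", "inversion", "c", 0, 5_000_000),
        _sv("inv_small", "inversion", "c", 6_000_000, 10_900_000),
        _sv("dup_ok", "duplication", "c", 11_000_000, 11_050_000),
        _sv("dup_small", "duplication", "c", 12_000_000, 12_049_999),
        _sv("tra_ok", "translocation", "c", 13_000_000, 13_050_000),
    ]
    kept = S.filter_svs(svs, [], [])
    assert [s.sv_id for s in kept] == ["inv_ok", "dup_ok", "tra_ok"]


def test_gap_overlap_drops_sv_in_either_assembly():
    svs = [
        _sv("in_gap_a", "deletion", "c", 100, 2000),
        _sv("in_gap_b", "deletion", "c", 5000, 6000, "c", 500_000, 500_001),
        _sv("clean", "deletion", "c", 10_000, 12_000, "c", 9000, 9001),
    ]
    kept = S.filter_svs(svs, [Interval("c", 1500, 1600)],
                        [Interval("c", 499_900, 500_100)])
    assert [s.sv_id for s in kept] == ["clean"]
    assert svs[0].overlaps_gap and svs[1].overlaps_gap


def test_filter_matches_bruteforce_on_planted_set(sim_pair):
    ga, gaps_a, gb, svs, snps = sim_pair
    kept = S.filter_svs(svs, gaps_a, gb.gap_runs())

    def brute_keep(sv):
        if any(g.chrom == sv.coords_a.chrom and g.start < sv.coords_a.end
               and sv.coords_a.start < g.end for g in gaps_a):
            return False
        if sv.coords_b is not None and any(
                g.chrom == sv.coords_b.chrom and g.start < sv.coords_b.end
                and sv.coords_b.start < g.end for g in gb.gap_runs()):
            return False
        mins = {"inversion": 5_000_000, "duplication": 50_000,
                "translocation": 50_000, "transposition": 50_000}
        return sv.size >= mins.get(sv.type, 0)

    assert [s.sv_id for s in kept] == [s.sv_id for s in svs if brute_keep(s)]


# ---------------------------------------------------------------------------
# invariant mask
# ---------------------------------------------------------------------------

def test_mask_with_no_variants_covers_everything():
    g = GenomeSequence("a", {"c": "ACGT" * 100})
    mask = S.invariant_mask(g, [])
    assert mask["c"] == [(0, 400)]
    assert S.mask_contains(mask, "c", 0, 400)


def test_mask_excludes_snp_position():
    g = GenomeSequence("a", {"c": "ACGT" * 100})
    mask = S.invariant_mask(g, [Interval("c", 50, 51)])
    assert mask["c"] == [(0, 50), (51, 400)]
    assert not S.mask_contains(mask, "c", 40, 60)
    assert S.mask_contains(mask, "c", 51, 400)


def test_mask_matches_per_base_comparison_for_snp_only_pair():
    """For a SNP-only diverged pair, the mask equals the brute-force
    per-base diff of the two (equal-length, collinear) genomes."""
    cfg = SimConfig(seed=21, n_chroms=1, chrom_length=100_000, n_genes=0,
                    sv_counts={"deletion": 0, "duplication": 0,
                               "translocation": 0, "inversion": 0},
                    n_sv_gap_decoys=0, n_gaps_per_chrom=0,
                    divergence_snp_rate=0.002)
    ga, _ = generate_genome(cfg)
    gb, svs, snps = generate_sv_pair(cfg, ga)
    assert len(gb) == len(ga) and not svs
    mask = S.invariant_mask(ga, non_invariant_intervals(svs, snps))
    a, b = ga.chroms["chr1"], gb.chroms["chr1"]
    diff = [i for i in range(len(a)) if a[i] != b[i]]
    runs, cur = [], 0
    for d in diff:
        if d > cur:
            runs.append((cur, d))
        cur = d + 1
    if cur < len(a):
        runs.append((cur, len(a)))
    assert mask["chr1"] == runs


# ---------------------------------------------------------------------------
# electronic PCR
# ---------------------------------------------------------------------------

def _pair_from(seq, f_start, r_start, n=20, name="p"):
    fwd = seq[f_start:f_start + n]
    rev = revcomp(seq[r_start:r_start + n])
    return PrimerPair(name, fwd, rev,
                      Interval("c", f_start, f_start + n, "+"),
                      Interval("c", r_start, r_start + n, "-"))


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list("ACGT"), 50_000))
    return GenomeSequence("rand", {"c": seq})


def test_epcr_absent_primers_give_no_product(random_genome):
    pair = PrimerPair("p", "A" * 20, "C" * 20,
                      Interval("c", 0, 20), Interval("c", 100, 120))
    assert S.epcr(pair, random_genome) == []


def test_epcr_convergent_pair_product_size(random_genome):
    seq = random_genome.chroms["c"]
    pair = _pair_from(seq, 1000, 1480)  # product 1480 + 20 - 1000 = 500
    (prod,) = S.epcr(pair, random_genome, max_product=3000)
    assert prod == ("c", 1000, 1500, 500)


def test_epcr_respects_max_product(random_genome):
    seq = random_genome.chroms["c"]
    pair = _pair_from(seq, 1000, 9000)
    assert S.epcr(pair, random_genome, max_product=3000) == []


def test_epcr_symmetric_under_reverse_complement(random_genome):
    seq = random_genome.chroms["c"]
    pair = _pair_from(seq, 2000, 2700)
    flipped = GenomeSequence("flip", {"c": revcomp(seq)})
    out_fwd = S.epcr(pair, random_genome)
    out_rev = S.epcr(pair, flipped)
    assert [p[3] for p in out_fwd] == [p[3] for p in out_rev]


# ---------------------------------------------------------------------------
# design schemes on a planted genome pair
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sim_pair():
    cfg = SimConfig(seed=3, n_chroms=2, chrom_length=2_000_000, n_genes=0,
                    sv_counts={"deletion": 3, "duplication": 2,
                               "translocation": 1, "inversion": 1},
                    n_sv_gap_decoys=1,
                    deletion_size_range=(4000, 12_000),
                    translocation_size_range=(50_000, 60_000))
    ga, gaps = generate_genome(cfg, "A")
    gb, svs, snps = generate_sv_pair(cfg, ga)
    return ga, gaps, gb, svs, snps


def test_sequence_length_bookkeeping_is_exact(sim_pair):
    ga, _, gb, svs, _ = sim_pair
    delta = sum({"deletion": -s.size, "duplication": s.size}.get(s.type, 0)
                for s in svs)
    assert len(gb) - len(ga) == delta


def test_designed_patterns_match_epcr_on_both_genomes(sim_pair):
    """For every feasible design the predicted genome-specific pattern is
    exactly what exact-match e-PCR reports: D1/D2 and T1/T2 amplify the
    reference arrangement only, U1 and the spanning pair the derived
    genome only."""
    ga, _, gb, svs, snps = sim_pair
    mask = S.invariant_mask(ga, non_invariant_intervals(svs, snps))
    targets = [s for s in svs if not s.overlaps_gap
               and s.type in ("deletion", "duplication", "translocation")]
    results = S.design_sv_primers(targets, ga, gb, mask)
    n_ok = 0
    for sv in targets:
        res = results[sv.sv_id]
        if res["status"] != "ok":
            continue
        n_ok += 1
        for name, pair in res["pairs"].items():
            # every primer site sits wholly inside the invariant mask or,
            # for A-only internal primers, inside the event's A-span
            for site in (pair.forward_site, pair.reverse_site):
                assert (S.mask_contains(mask, site.chrom, site.start, site.end)
                        or sv.coords_a.contains(
                            Interval(site.chrom, site.start, site.end)))
            for genome in (ga, gb):
                products = S.epcr(pair, genome)
                expected = pair.expected_pattern[genome.name]
                if expected is None:
                    assert products == [], (sv.sv_id, name, genome.name)
                else:
                    assert any(p[3] == expected for p in products), \
                        (sv.sv_id, name, genome.name, expected, products)
    assert n_ok >= len(targets) - 1  # dense SNP flanks may defeat a design


def test_deletion_too_small_for_internal_primer(sim_pair):
    ga, _, gb, svs, snps = sim_pair
    mask = S.invariant_mask(ga, non_invariant_intervals(svs, snps))
    tiny = _sv("tiny", "deletion", "chr1", 100_000, 100_015)
    with pytest.raises(S.PrimerDesignError):
        S.design_deletion_primers(tiny, ga, gb, mask)


def test_non_tandem_duplication_is_a_design_failure(sim_pair):
    ga, _, gb, svs, snps = sim_pair
    mask = S.invariant_mask(ga, non_invariant_intervals(svs, snps))
    fake = _sv("fake_dup", "duplication", "chr1", 200_000, 204_000)
    with pytest.raises(S.PrimerDesignError, match="tandem"):
        S.design_duplication_primers(fake, ga, gb, mask)


def test_deletion_flanked_by_dense_snps_fails_with_reason(sim_pair):
    ga, _, gb, svs, snps = sim_pair
    real = next(s for s in svs if s.type == "deletion" and not s.overlaps_gap)
    a = real.coords_a
    dense = [Interval(a.chrom, p, p + 1)
             for p in range(a.start - 1200, a.start, 7)] + \
            [Interval(a.chrom, p, p + 1)
             for p in range(a.end, a.end + 1200, 7)]
    tight_mask = S.invariant_mask(
        ga, non_invariant_intervals(svs, snps) + dense)
    with pytest.raises(S.PrimerDesignError, match="invariant"):
        S.design_deletion_primers(real, ga, gb, tight_mask)
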