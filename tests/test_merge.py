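"""Two-set consolidation: identity collapse, isoform retention, lncRNA
consensus filter, proximity review."""

import pandas as pd
import pytest

from palmannot import merge as M
from palmannot.synthetic_data import SimConfig, simulate_annotation_inputs

from conftest import make_transcript


def _pair(exons_a, exons_b, cds_a, cds_b, gene="g"):
    ta = make_transcript("tA", exons_a, cds=cds_a, gene_id=gene, source="setA")
    tb = make_transcript("tB", exons_b, cds=cds_b, gene_id=gene, source="setB")
    return ta, tb


def test_identical_transcripts_collapse_to_set_b_copy():
    ta, tb = _pair([(0, 100), (200, 300)], [(0, 100), (200, 300)],
                   [(10, 100), (200, 250)], [(10, 100), (200, 250)])
    merged, report = M.merge_predictions([ta], [tb])
    assert [t.transcript_id for t in merged] == ["tB"]
    assert merged[0].source == "setB"
    assert report.n_collapsed_identical == 1
    assert report.n_output == len(merged)


def test_same_bounds_different_exons_kept_as_isoforms_of_one_gene():
    """Span endpoints identical, internal boundary differs by 3 bp."""
    ta, tb = _pair([(0, 100), (200, 300)], [(0, 97), (200, 300)],
                   [(10, 100), (200, 250)], [(10, 97), (200, 250)])
    merged, report = M.merge_predictions([ta], [tb])
    assert len(merged) == 2
    assert len({t.gene_id for t in merged}) == 1
    assert report.n_collapsed_identical == 0
    assert report.n_isoforms_added == 1


def test_set_unique_transcripts_pass_through():
    ta = make_transcript("onlyA", [(0, 500)], cds=[(50, 450)])
    tb = make_transcript("onlyB", [(10_000, 10_500)], cds=[(10_050, 10_450)])
    merged, _ = M.merge_predictions([ta], [tb])
    assert sorted(t.transcript_id for t in merged) == ["onlyA", "onlyB"]
    assert len({t.gene_id for t in merged}) == 2


def test_duplicate_ids_within_a_set_rejected():
    t1 = make_transcript("dup", [(0, 100)], cds=[(0, 99)])
    t2 = make_transcript("dup", [(500, 700)], cds=[(500, 600)])
    with pytest.raises(M.InputError):
        M.merge_predictions([t1, t2], [])


def test_merge_is_idempotent(sim):
    merged, _ = M.merge_predictions(sim.set_a[:60], sim.set_b[:60])
    again, report = M.merge_predictions(merged, [])
    assert sorted(t.transcript_id for t in again) == \
        sorted(t.transcript_id for t in merged)
    assert report.n_collapsed_identical == 0


def test_merge_matches_bruteforce_allpairs_oracle(sim):
    """Sweep-based merge equals the quadratic reference on planted sets."""
    set_a, set_b = sim.set_a, sim.set_b
    merged, report = M.merge_predictions(set_a, set_b)
    brute = M.merge_predictions_bruteforce(set_a, set_b)
    assert sorted(t.transcript_id for t in merged) == \
        sorted(t.transcript_id for t in brute)
    # same grouping structure (gene ids are synthetic labels; compare sets)
    by_gene = lambda ts: sorted(  # noqa: E731
        tuple(sorted(t.transcript_id for t in ts if t.gene_id == g))
        for g in {t.gene_id for t in ts})
    assert by_gene(merged) == by_gene(brute)
    assert report.n_output == len(merged)


def test_planted_agreement_categories_decide_transcript_fate(sim):
    merged, report = M.merge_predictions(sim.set_a, sim.set_b)
    surviving = {t.transcript_id for t in merged}
    for tid, cat in sim.truth.agreement.items():
        if cat == "identical" and ".A" in tid:
            assert tid not in surviving, f"{tid} should collapse into set B"
            assert report.provenance[tid].startswith("collapsed-into")
        else:
            assert tid in surviving, f"{tid} ({cat}) should survive"


def test_lncrna_removed_only_without_homology_rescue():
    ts = [make_transcript(f"t{i}", [(i * 1000, i * 1000 + 500)],
                          cds=[(i * 1000 + 10, i * 1000 + 400)])
          for i in range(4)]
    calls = pd.DataFrame([
        {"transcript_id": "t0", "caller": "c1", "verdict": "non-coding"},
        {"transcript_id": "t0", "caller": "c2", "verdict": "non-coding"},
        {"transcript_id": "t1", "caller": "c1", "verdict": "non-coding"},
        {"transcript_id": "t2", "caller": "c1", "verdict": "coding"},
        {"transcript_id": "t2", "caller": "c2", "verdict": "coding"},
    ])
    hits = pd.DataFrame([{"query": "t1", "evalue": 1e-6}])
    kept, removed, _ = M.filter_lncrna(ts, calls, hits)
    # t0: non-coding consensus, no hit -> removed; t1 rescued by 1e-6 hit;
    # t2 coding; t3 absent from the tables counts as coding
    assert [t.transcript_id for t in removed] == ["t0"]
    assert sorted(t.transcript_id for t in kept) == ["t1", "t2", "t3"]


def test_lncrna_evalue_cutoff_boundary():
    t = make_transcript("t", [(0, 500)], cds=[(10, 400)])
    calls = pd.DataFrame([{"transcript_id": "t", "caller": "c1",
                           "verdict": "non-coding"}])
    at_cutoff = pd.DataFrame([{"query": "t", "evalue": 1e-5}])
    kept, removed, _ = M.filter_lncrna([t], calls, at_cutoff)
    assert not removed, "e-value exactly at 1e-5 is significant homology"
    above = pd.DataFrame([{"query": "t", "evalue": 2e-5}])
    kept, removed, _ = M.filter_lncrna([t], calls, above)
    assert [t_.transcript_id for t_ in removed] == ["t"]


@pytest.mark.parametrize("gap,flagged", [(149, True), (150, False), (151, False)])
def test_same_strand_proximity_threshold_is_exclusive(gap, flagged):
    a = make_transcript("a1", [(0, 1000)], cds=[(10, 900)], gene_id="ga")
    b = make_transcript("b1", [(1000 + gap, 2500 + gap)],
                        cds=[(1100 + gap, 2400 + gap)], gene_id="gb")
    support = {"a1": True, "b1": False}
    kept, removed, report = M.proximity_review([a, b], support)
    assert (report.n_proximity_flagged > 0) == flagged
    assert ([t.transcript_id for t in removed] == ["b1"]) == flagged


def test_opposite_strand_flag_requires_three_prime_overlap():
    # + gene ends at 1000; - gene starts at 990: 3' terminal exons share 10 bp
    a = make_transcript("a1", [(0, 1000)], cds=[(10, 900)], gene_id="ga")
    b = make_transcript("b1", [(990, 2200)], cds=[(1100, 2100)],
                        gene_id="gb", strand="-")
    kept, removed, report = M.proximity_review(
        [a, b], {"a1": True, "b1": True})
    assert report.n_proximity_flagged == 1
    assert not removed  # both supported: flagged for audit, nothing dropped

    # same geometry but 3' ends apart: - gene's 3' exon is its leftmost, so
    # shifting it away removes the overlap
    c = make_transcript("c1", [(1200, 2400)], cds=[(1300, 2300)],
                        gene_id="gc", strand="-")
    _, _, report2 = M.proximity_review([a, c], {"a1": True, "c1": True})
    assert report2.n_proximity_flagged == 0


def test_consolidation_count_identity_and_planted_fates(sim):
    final, report = M.consolidate(
        sim.set_a, sim.set_b, sim.files.coding_calls, sim.files.homology,
        sim.truth.junction_support)
    assert len(final) == report.n_output
    surviving = {t.transcript_id for t in final}
    truth = sim.truth
    removed_lnc = {tid for tid, is_lnc in truth.lncrna.items()
                   if is_lnc and not (tid.count(".A") and
                                      truth.agreement[tid] == "identical")}
    assert removed_lnc.isdisjoint(surviving)
    assert truth.removed_by_proximity.isdisjoint(surviving)
    flagged_in_report = {g for pair in report.flagged_pairs for g in pair[:2]}
    planted_flagged = {g for pair in truth.flagged_pairs for g in pair}
    # merged gene ids differ from planted ids; compare via transcript origin
    assert report.n_proximity_flagged == len(truth.flagged_pairs)
    assert flagged_in_report  # non-empty given planted pairs
    assert planted_flagged
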