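import pytest

from palmannot.gffio import Interval, Transcript
from palmannot.synthetic_data import SimConfig, simulate_annotation_inputs


def make_transcript(tid, exons, cds=None, chrom="chr1", strand="+",
                    gene_id=None, source="setA", **attributes):
    """Hand-built transcript from (start, end) tuples."""
    return Transcript(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        source=source,
        exons=[Interval(chrom, s, e, strand) for s, e in exons],
        cds=[Interval(chrom, s, e, strand) for s, e in (cds or [])],
        attributes={k: str(v) for k, v in attributes.items()},
    )


class SimBundle:
    def __init__(self, config):
        (self.genome, self.gaps, self.set_a, self.set_b,
         self.truth, self.files) = simulate_annotation_inputs(config)
        self.config = config

    @property
    def classified_genes(self):
        genes = [g for g in self.truth.genes
                 if g.gene_id in self.truth.gene_class]
        for g in genes:
            g.gene_class = self.truth.gene_class[g.gene_id]
            g.representative = self.truth.representative[g.gene_id]
        return genes


@pytest.fixture(scope="session")
def sim():
    """Default-scale synthetic bundle shared across the suite."""
    return SimBundle(SimConfig(seed=11))
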