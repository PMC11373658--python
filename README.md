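# palmannot

Post-processing toolkit for palm genome annotation projects: it turns the
bespoke, mostly manual consolidation and validation steps that follow
genome annotation into a reusable, tested pipeline.

Large plant genome projects (the motivating case is the oil palms
*Elaeis guineensis* and *E. oleifera*) typically end up with **two**
gene-prediction sets from independent pipelines, several layers of
transcript evidence (CAGE tag clusters, multi-tissue RNA-seq, protein
homology), whole-genome bisulfite methylation calls, repeat annotations,
and a list of candidate structural variants between related assemblies.
`palmannot` implements the downstream logic that connects them:

* **Consolidation** (`palmannot.merge`) — combine two GFF3 prediction
  sets: transcripts identical in span endpoints *and* full CDS
  coordinates collapse to the designated set-B copy; identical spans with
  different exon chains are kept as isoforms of one gene; candidate
  lncRNAs (non-coding by either of two coding-potential callers *and* no
  homology hit at e-value ≤ 1e-5) are removed; gene pairs closer than
  150 nt (same strand) or 300 nt (opposite strands with overlapping 3′
  ends) are flagged and their junction-unsupported transcripts dropped.
* **Evidence** (`palmannot.evidence`) — CAGE cluster-to-gene assignment
  using a −3000..+10 nt window around the CDS start (one cluster may
  support several isoforms of one gene, never two genes), RNA-seq support
  at a TPM threshold over a transcripts × tissues matrix, and homology
  support at coverage ≥ 50% and e-value ≤ 1e-5.
* **Classification** (`palmannot.classify`) — the six-class evidence
  partition over the (CAGE, RNA-seq, BLAST) axes:
  N1 = all three; N2 = CAGE + one other; N3 = RNA-seq + BLAST;
  N4 = CAGE or RNA-seq alone; N5 = BLAST only; N6 = unsupported — plus
  representative-isoform selection by the strict cascade (class, best
  e-value, tissue breadth, max TPM, CDS length, first predicted).
* **Profiles** (`palmannot.profiles`) — CG/CHG/CHH methylation
  metaprofiles in 5-nt bins over ±500 nt around translation start/end
  per gene class, and gene/repeat densities in 1-Mb windows compared by
  Spearman correlation.
* **SV validation** (`palmannot.svprimers`) — gap and size filtering of
  interspecific SV calls (inversions ≥ 5 Mb, duplications/translocations
  ≥ 50 kb), an invariant-sequence mask to avoid interspecies SNPs, the
  diagnostic primer schemes D1/D2 + spanning (deletions), U1 (tandem
  duplications) and T1/T2 (translocation breakpoints), all verified by
  exact-match electronic PCR.
* **Synthetic data** (`palmannot.synthetic_data`) — deterministic
  generators for every input above with machine-readable planted truth,
  so each stage is testable end to end without any external download.

## Worked example

```python
from palmannot.synthetic_data import SimConfig, simulate_annotation_inputs
from palmannot import merge, evidence, classify

cfg = SimConfig(seed=1)            # 200 genes on 2 x 1 Mb chromosomes
genome, gaps, set_a, set_b, truth, files = simulate_annotation_inputs(cfg)

final, report = merge.consolidate(
    set_a, set_b, files.coding_calls, files.homology,
    truth.junction_support)
print(report.as_dict())
```

prints

```
{'n_input_a': 290, 'n_input_b': 291, 'n_collapsed_identical': 203,
 'n_isoforms_added': 59, 'n_lncrna_removed': 14, 'n_proximity_flagged': 3,
 'n_removed_no_junction_support': 3, 'n_output': 361}
```

i.e. of 581 input transcripts, 203 were identical between the two
pipelines (the set-B copy is kept), 59 extra isoforms share a gene with
another model, 14 candidate lncRNAs and 3 junction-unsupported
transcripts near flagged gene pairs were removed, leaving 361.
Continuing with classification:

```python
genes = [g for g in truth.genes if g.gene_id in truth.gene_class]
_, cage = evidence.associate_cage(files.cage, genes)
bundles = evidence.build_evidence(
    genes, cage,
    evidence.rnaseq_support(files.expression),
    evidence.blast_support(files.homology))
summary = classify.summarize_classes(
    classify.classify_gene_models(genes, bundles))
print(summary.counts, summary.percent_expression_supported)
```

```
{'N1': 51, 'N2': 30, 'N3': 40, 'N4': 22, 'N5': 29, 'N6': 18} 75.3
```

— the recovered class counts equal the planted ones exactly, and 75.3%
of genes carry at least one source of expression evidence (classes
N1–N4).

The same stages are available as a CLI for file-based use:
`palmannot simulate | stats | merge | evidence | classify | profile |
svprimers` (see `palmannot --help`).

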