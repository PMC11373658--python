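# Methods

This note documents the models, rules and numerical choices behind
`palmannot`, the assumptions of its synthetic-data generators, and the
limits of what the test suite demonstrates.

## Coordinate model

All coordinates are 0-based half-open on the internal side; GFF3 (and
VCF) 1-based closed coordinates are converted at the I/O boundary, BED
passes through unchanged. A `Transcript` carries sorted, non-overlapping
exons and a CDS chain contained in them; the *translation start* is the
first base of the start codon in transcription orientation (the CDS
chain's left edge on `+`, right edge − 1 on `−`), the *translation end*
the last coding base. Assembly statistics use the standard N50/N90
definition (smallest length such that scaffolds at least that long cover
50%/90% of total bases); the mean scaffold length is reported as the
floor of the exact ratio, and percentages are rounded half-up to one
decimal, matching how such tables are conventionally printed.

## Consolidation rules

Two prediction sets are merged with set B as the kept-on-identity set:

* **Rule 1** — identical genomic span endpoints *and* identical full CDS
  coordinate list ⇒ the pair collapses to the set-B transcript. The CDS
  comparison is exon-by-exon (the stricter reading) rather than CDS
  start/end only. When several set-B transcripts share the identity key,
  the lexicographically smallest id represents it, for determinism.
* **Rule 2** — identical span endpoints with different exon chains ⇒
  both transcripts are retained as isoforms of one gene.
* **Regrouping** — genes are recomputed as connected components under
  "identical span" or "same-strand overlap with ≥ 1 bp CDS overlap",
  via a start-sorted sweep; a quadratic all-pairs implementation is kept
  (`merge_predictions_bruteforce`) purely as a cross-check oracle.

The lncRNA consensus filter removes a transcript iff *either* of the two
coding-potential callers says non-coding *and* it has no homology hit at
e-value ≤ 1e-5 (the filter deliberately uses e-value alone, not the
coverage criterion of the support filter). Transcripts absent from the
calls table count as coding.

Proximity review flags a gene pair when (a) same strand and the gap
between nearest span endpoints is < 150 nt (exclusive; "within 150 nt"
is fixed as `< 150` for testability), or (b) opposite strands, gap
< 300 nt and the 3′-terminal exons share at least 1 bp. Within flagged
pairs, transcripts without RNA-seq junction support are removed; the
support flag is an input (read alignment is out of scope) and a
transcript missing from the table is treated as unsupported, since the
removal rule asks for positive evidence. Review only removes
transcripts; it never merges two genes into one.

## Evidence and classification

CAGE association tests the cluster's *summit* (a recorded single
position) against the window `[CDS start − 3000, CDS start + 10]` in
transcription orientation, both bounds inclusive. A cluster whose summit
falls in windows of one gene supports all of that gene's in-window
isoforms; with two or more candidate genes it goes to the nearest CDS
start, and an exact distance tie leaves it unassigned. RNA-seq support
means TPM ≥ threshold (default 1.0, the conventional presence cutoff;
no value is prescribed by the source protocol) in at least one tissue.
Homology support means ≥ 1 hit with coverage ≥ 50% and e-value ≤ 1e-5,
both inclusive.

The six classes are implemented so that they partition all eight
combinations of the (CAGE, RNA-seq, BLAST) booleans — N2's "either" and
N4's "or" are read exclusively, the only reading that makes the classes
mutually exclusive and exhaustive; an enumeration test asserts the
partition. The gene label uses OR-over-isoform axes; representative
ranking evaluates each isoform's own axes. The cascade is strictly
lexicographic: class, best e-value (absent ranks worse than any
present value), number of tissues at threshold, maximum TPM across
tissues (the unspecified aggregation; max is monotone with the breadth
criterion), CDS length, and finally prediction order.

## Methylation metaprofiles and densities

Profiles are anchored at the **translation** start/end of each gene's
representative isoform (the transcription-anchored variant is available
via the `anchors` argument; translation anchors are the default because
they are what the class-contrast result is about). Offsets run over
[−500, +500) in 5-nt bins (200 bins per anchor), strand-flipped for `−`
genes; the per-bin value is the unweighted mean of per-cytosine levels
(methylated/total), pooled over the genes of a class, and a bin with no
cytosines is NaN, never zero. Only the representative isoform anchors a
gene, avoiding double-counting.

Density tracks count features per tiling window (default 1 Mb) by start
position, so each feature is counted exactly once; tracks are compared
with Spearman rank correlation (average ranks on ties), requiring ≥ 3
windows.

## SV filtering and diagnostic primers

Calls overlapping an assembly gap in either genome are dropped; size
thresholds (inclusive) keep inversions ≥ 5 Mb and
duplications/translocations ≥ 50 kb. Deletions carry no size threshold
here: they feed the small-variant PCR branch, which is validated
per-event rather than size-selected.

Primer design works on genome A (the assembly carrying sequence deleted
in B) with defaults of 20 nt primers, a 1 kb search radius from each
junction and a 3 kb maximum product — the source protocol prescribes no
primer constraints, and with exact-match electronic PCR as the contract
a melting-temperature model adds nothing. Shared primers must lie wholly
inside the **invariant mask**: genome-A intervals outside every SNP,
deletion, inversion and gap run (duplicated and translocated sequence is
still base-identical in B, so it stays maskable). Every primer site is
additionally required to occur exactly the expected number of times in
each genome (1/1 for shared sites, 1/0 for deletion-internal, 1/2 for
duplication-internal), which prevents spurious e-PCR products.

The schemes: for a deletion, D1 (shared 5′-flank forward + internal
reverse) and D2 (internal forward + shared 3′-flank reverse) amplify A
only, and the spanning pair D1F+D2R amplifies B only whenever the A-side
product exceeds the maximum product size — for deletions smaller than
that the expected pattern honestly records amplification in both genomes
with a diagnostic size difference. For a tandem duplication, the
outward-facing U1F (3′ end of the copy) + U1R (5′ end) pair amplifies
only across the copy junction, which exists only in B; a missing
junction k-mer (non-tandem copies) is a design failure. For a
translocation, T1/T2 straddle the two breakpoints of the segment in its
original context, so both amplify only the un-rearranged genome; one
pair is emitted per feasible breakpoint. Electronic PCR is an
exact-match search of both primers on both strands reporting every
convergent pairing within the product limit.

## Synthetic data: what it emulates, and what it does not

All generators draw from labelled substreams of one master seed
(`numpy` `default_rng` seeded with `[seed, crc32(label)]`), so outputs
are byte-reproducible and adding a generator never perturbs the others.

* **Genome**: i.i.d. uniform A/C/G/T with planted N-run gaps
  (2 per chromosome, 200–800 bp). Uniform background makes 20-mers
  unique with overwhelming probability, which the primer-uniqueness
  logic relies on; real genomes have repeats that would make design
  fail more often (failures are reported, not hidden).
* **Gene models**: 2–4 exons of 600–1000 bp, introns 100–400 bp, CDS
  margins 30–150 bp inside the terminal exons; ~8.3 kb of sequence per
  gene including spacing. Isoforms vary only at the 3′ CDS margin
  (distinct CDS lengths, shared translation start). Agreement categories
  (identical 40%, same-bounds-diff-exons 20%, set-specific 15% + 15%,
  overlapping-conflict 10%) are planted per gene; near-neighbour pairs
  are planted at 100/149/151 nt same-strand and a 10 bp opposite-strand
  3′ overlap, bracketing the review thresholds; 5% of genes are planted
  lncRNAs (non-coding by both simulated callers, no homology hit).
* **Evidence** is drawn to satisfy each gene's planted class predicate
  exactly: CAGE summits within [−300, +10] of the translation start
  (close anchoring keeps nearest-gene resolution unambiguous even for
  planted neighbour pairs), log-normal TPM above threshold in a planted
  number of tissues with distinct per-isoform breadths, homology hits
  with log-uniform e-values where the planted winner is strictly best,
  plus decoy clusters in intergenic space and decoy sub-threshold hits.
  Genes with no quantitative evidence axis emit no expression at all, so
  the longest-CDS criterion decides their representative. TPM ranges and
  cluster widths are chosen for discriminative power, not realism — no
  distributional parameters exist to emulate.
* **Methylation**: cytosines at density 0.22/bp over each gene ± 600 nt,
  contexts ~⅓ each; per-cytosine levels are Beta draws (concentration
  40) around a class template — expressed classes: CG body 0.60 / CHG
  0.50 with Gaussian troughs to 0.10/0.08 (half-width 150 nt) at both
  translation ends, CHH flat 0.05; silent classes: flat CG 0.85 / CHG
  0.80 / CHH 0.10 — then binomial counts at 10–40× coverage. The
  template is symmetric and noise is independent per cytosine; real
  bisulfite data has positional autocorrelation and coverage bias that
  the generator does not model, so passing tests demonstrate correct
  *computation* of metaprofiles, not biological inference.
* **SV pair**: genome B is built per chromosome from collinear blocks
  with planted deletions (0.5–20 kb), tandem duplications (2–8 kb),
  reciprocal cross-chromosome segment swaps (50–80 kb) and inversions
  (10–30 kb), ≥ 3 kb apart, plus gap-overlap decoy deletions and
  background SNPs at 5 × 10⁻³/bp placed ≥ 50 bp from block edges.
  Liftover coordinates are recorded exactly during construction, and the
  signed event lengths account for the B−A length difference exactly.

## Scales used in the shipped experiments

The integration experiments (`palmannot.workflows`, also run by
`scripts/acceptance.py`) use 500 genes for classification recovery,
300 + 300 transcripts for the merge/brute-force equivalence, 200 genes
per class for the methylation contrast, a 2 × 5 Mb genome pair with 20
planted SVs for the filtering/primer study, and 60 × 1 Mb windows for
the density correlation. These sizes give exact recovery targets and
tight sampling bounds (hundreds of cytosines per 5-nt bin; binomial GC
fluctuation ≤ 0.25% at 1 Mb) while keeping a full run in tens of
seconds; genome-scale gene counts are not reproducible at this scale
and are not attempted.

## Known limitations

* The merge's gene regrouping uses single-linkage overlap, so one
  promiscuous transcript can chain otherwise distinct genes into one.
* CAGE ambiguity resolution by nearest CDS start is deterministic but
  arbitrary at exact ties (unassigned), and windows of adjacent genes
  may overlap; decisions are recorded in the assignment map for audit.
* e-PCR is exact-match only: a single SNP under a primer abolishes a
  product that real PCR might tolerate; conversely no mismatch/dimer
  model exists. The invariant mask exists precisely to keep designs out
  of that regime.
* `window_density` assigns features by start position; a feature
  spanning a window boundary contributes only to the window containing
  its start.
* The proximity review treats a transcript missing from the junction
  table as unsupported; supply explicit flags to override.
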