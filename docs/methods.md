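# Methods

`tdrscape` quantifies tRNA-derived small RNAs (tDRs) from AlkB-facilitated
small-RNA sequencing (ARM-seq) style reads and derives the downstream
objects of a stress-response profiling study: fragmentation signatures,
differential signatures, knockout-dependence classes, and sample-
discrimination scores.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Coordinate system and reference model

All positional analysis happens on the transcript strand in 1-based
inclusive coordinates; genomic coordinates never enter the pipeline.
Mature transcripts are isodecoder-level objects: introns spliced, the
post-transcriptional `CCA` appended, genes with byte-identical mature
sequence collapsed into one transcript (the collapsed transcript keeps the
canonically first gene's name and a copy count).  Precursors keep the
unspliced body plus leader/trailer flanks; trailer bases are labelled
`T1, T2, ...` outward from the body 3' end and leader bases `L1, L2, ...`
outward from the 5' end.

Mature fragments are summarized on a consensus axis 1..76 with the
anticodon pinned at 34-36 and the CCA at 74-76.  For transcripts whose
length is not 76 the mapping is piecewise: the 5' arm indexed forward from
1, the anticodon block forced onto 34-36 (the anticodon's position is found
by locating the anticodon 3-mer nearest its length-scaled canonical
position), and the 3' arm anchored backward from 76.  Extra variable-loop
bases of long tRNAs share label 37; short variable loops simply skip
labels.  Full Sprinzl insertion codes, His G-1 addition and
mitochondrial-specific numbering are deliberately out of scope; position 1
is always the first encoded base.  The mapping is monotone and pins the
last three bases to 74/75/76, which is what the CCA-status calls rely on.

## tDR nomenclature

Names have the shape
`tDR-<start>:<end>-<Isotype>-<Anticodon>-<No>[-<Copy>][-M<k>][-<variants>]`.
The parser also accepts `-` between the start and end labels (both
spellings occur in print) and isoacceptor-level names without a transcript
number (`tDR-1:36-Glu-TTC`); canonical re-emission uses `:`.  The
gene-copy token appears only on precursor-derived names, and `-M<k>` only
when the fragment maps equally well to k >= 2 isodecoders.

Variant codes are fragment-relative and 1-based: `A1G` on a fragment
starting at transcript position 37 means a misincorporation at position 37.
`<Ref><Pos><Obs>` is a substitution; `D<Pos><Ref>` is read as a deletion of
reference base Ref at fragment position Pos.  The deletion reading is an
interpretation (the printed examples do not define it), so it is isolated
inside the `VariantCode` type where it can be corrected without touching
anything else.

## Synthetic ARM-seq generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing chemistry.  Reads are emitted already adapter-merged,
single-end, capped at 75 nt.  One seeded generator drives a run; each
sample uses the substream `(seed, sample index)`, so libraries are
reproducible and per-sample independent.

* **Fragment-class mixtures.**  A library profile is a weighted mixture of
  fragment classes, each with distributions over start/end labels
  (consensus positions for mature classes, `T`/`L` labels for precursor
  classes).  The default extracellular mixture is 70% 5' halves ending at
  consensus 33, 20% trimmed 3' halves ending at 74, 10% miRNA background;
  the default cellular mixture is dominated by 3' fragments with intact
  CCA ending at 76 over broad start positions.  These defaults mirror the
  compartment contrast the analysis is designed to detect.
* **RT-stop model.**  Modified positions default to {m1A58}.  Scanning a
  read 3'->5' (the direction reverse transcription proceeds), each covered
  modified position stops the RT with probability 1 - read-through,
  truncating the read to the bases strictly 3' of the modification; on
  read-through, a random non-reference base replaces the true base with
  probability 0.3 (misincorporation).  Read-through is 0.1 without AlkB
  treatment and 0.99 with it.  The untreated stall probability is a free
  parameter of this generator, not a measured value.
* **Counting model.**  Expected counts per (transcript, class) cell are
  the mixture probabilities times the read target, modulated by per-cell
  log2 condition effects.  The per-sample total is negative-binomially
  jittered around its target (library-size variability) and reads are then
  allocated to cells multinomially, so within-sample class fractions
  converge to the configured mixture at binomial rate — the property the
  recovery checks rely on.  Feature-level NB counts for the statistics
  modules come from dedicated count-level simulators
  (`simulate_nb_counts`, `simulate_ko_design`, `simulate_condition_matrix`)
  that sample NB(mean, dispersion) directly.
* **Noise.**  Per-base sequencing error 0.1% (substitutions only); with
  probability 0.15 a 3' adapter prefix of 6-20 nt is appended.  Quality
  strings are constant Phred+33; PCR duplicates, UMIs and ligation bias
  are not modeled.

What passing tests on this generator do **not** show about real data:
alignment ambiguity is limited to the planted shared 5' halves and
identical gene copies (real tRNA families are far more repetitive); the
error model is substitution-only; modification positions other than 58 are
absent unless configured; and abundances are clean NB draws without batch
structure.

## Trimming, alignment, counting

Adapter trimming removes the longest read suffix that matches an adapter
prefix (>= 6 exact bases, or the full adapter with <= 1 mismatch); reads
shorter than 15 nt after trimming are discarded.  The default adapter is
`AGATCGGAAGAGCACACGTC`.

Because tDRs are contiguous transcript substrings, alignment is an exact
ungapped end-to-end scan: every placement of the read on every reference
feature with <= 2 mismatches (tolerating one misincorporation plus one
sequencing error) is found by a vectorized Hamming comparison over all
length-m windows of the reference, with per-unique-sequence memoization.
Up to 100 alignments per read are kept; minimal-mismatch hits are flagged
best.  No heuristics and no missed hits, which is what makes the
brute-force oracle comparison exact.  An `ingest_sam` path reconstructs
the same hit objects from an external aligner's SAM/BAM for users who
prefer one.

Counting uses only best hits and contributes each read to exactly one
record.  The best-hit transcript set (mature preferred over precursor at
equal score unless only a precursor explains the read), the boundaries on
the canonically first transcript, and the representative hit's mismatch
codes form the fragment key.  Reads whose best hits are only miRNA/other
features are counted to the canonically first such feature.  Reads
multi-mapping across isotypes therefore go to the canonical-first key —
logged, since published pipelines do not document their tie-breaking
either.

## Fragment classification

Classification runs on consensus boundaries and is total: precursor
fragments overlapping leader/trailer go to `pre_leader`/`pre_trailer`;
mature fragments starting at consensus <= 3 are 5' halves if they end in
[30, 40] and 5' fragments if earlier; fragments ending at >= 74 are 3'
halves if they start in [30, 44] and 3' fragments if later; everything
else is internal.  CCA status is read off the end position (76 intact, 75
two C, 74 single C, else absent).  The empirical peaks (33, 74, 76) are
well supported; the window *edges* are an operational choice and are
exposed in `ClassifyConfig` rather than hard-coded.  Positional summaries
(length distribution, consensus coverage, end frequency) are
abundance-weighted; precursor fragments are excluded from the consensus
axis and summarized on their own label space.

## Normalization and differential abundance

Size factors are median-of-ratios: `s_j = median_i(c_ij / geomean_i)` over
features positive in every sample (an explicit opt-in pseudo-reference
handles sparse matrices).  Note the geometric-mean reference makes column
scaling a between-sample statement: tripling one column triples its factor
relative to the others, while all factors absorb a common constant.

The two-group test is a negative-binomial Wald test re-implemented here
(the signature logic, not the DE engine, is the point; an external engine
can be swapped in at the `de_test` seam).  Per-feature dispersions are
method-of-moments estimates on normalized counts, floored at 1e-8 and
shrunk arithmetically toward a parametric trend `a0 + a1/mean` fitted
across features (arithmetic rather than log-scale shrinkage because the
moment estimate collapses to the floor for a large minority of features at
n = 3, and log-averaging would let those floors dominate).  The Wald
statistic is the log2 fold change of pseudocounted group means over a
delta-method SE; its reference distribution is a moderated t with
`residual df + prior df` degrees of freedom (default prior 8), reflecting
the information borrowed from the trend — a plain normal reference is
visibly anticonservative at n = 3 and a plain t at the residual df
overcorrects.  Features below 10 total normalized counts are excluded from
testing and from the Benjamini-Hochberg family.  On the bundled benchmark
(1000 features, 10% true |LFC| = 2, dispersion 0.1, n = 3 vs 3) this
test's observed FDR at padj < 0.05 is ~2% with ~87% power, verified by the
test suite, and its fold changes agree with an independently developed NB
GLM engine to r > 0.99.

Significance everywhere means padj < 0.05 with no fold-change threshold
(configurable).  Signature sets are direction-stratified significant
feature-name sets; overlaps enumerate all membership patterns.
Knockout-dependence classifies each feature (outer join over WT and KO
contrasts; untested counts as not significant): `independent` if
same-direction significant in both, else `induced`/`depleted` if
significant only in WT, `ko_only` if significant only in KO, else
`unchanged` — a partition by construction.  AGO2 dependence is the
significantly-decreased set of a KO-vs-WT contrast.  Cross-species
conservation intersects names exactly, or on
(start, end, isotype, anticodon) in relaxed mode.  The tracking filter
keeps features with > 5 reads in every replicate of at least one
condition; the same default serves tDRs and miRNAs because no separate
tDR cutoff is documented anywhere.

## Discrimination

Embedding inputs are `log2(count/size_factor + 1)`; whether published
analyses variance-stabilized instead is not documented, so the simpler
transform was chosen and recorded here.  PCA (first two components) is the
asserted method; UMAP is provided for parity but treated as qualitative —
only determinism under a fixed seed is tested, because its geometry is
neighbor- and seed-sensitive.  Sample similarity uses Spearman
correlation; undefined correlations (constant samples) are reported
missing, never zero.

The scalar surrogate for "better discrimination" is the mean silhouette
over samples with distance `1 - Spearman`, computed per feature kind on
the same samples.  Its permutation null (labels shuffled, 200 rounds) is
slightly negative, as silhouette nulls are; the tests require the null to
sit within 3 SD of zero and the true-label score to beat it.

## Problem sizes and numerical choices

The bundled reference is 13 synthetic genes / 12 isodecoders plus 23
non-tRNA features; simulated libraries are 4,000-50,000 reads per sample
(50,000 for the fragmentation-recovery check, which is comfortably past
the 3-binomial-SE resolution at the 70/20 mixture), 1,000 features x 20
seeds for DE calibration, 500 features x 10 seeds for KO recovery, and
4 x 3 samples x 10 seeds for discrimination.  These sizes were chosen so
each recovery statement is made at the precision its tolerance needs.
Ties and degenerate inputs are handled explicitly throughout: empty
libraries produce empty outputs, zero-read length distributions return
empty maps instead of dividing by zero, boundary draws that do not fit a
transcript are resampled with a hard cap, and multi-hit ties break on the
canonical (isotype, anticodon, transcript number) order.

## Known limitations

Indels are not aligned (the internal aligner is substitution-only by
design); deletion variant codes can be parsed and formatted but are never
produced by the internal pipeline.  The DE engine is a two-group Wald
test — no multi-factor designs, no shrunken fold-change estimator, no
time-course models.  Consensus numbering for non-canonical tRNA lengths is
an anchoring convention, not a structural alignment.  Real-data mapping
rates, DE counts and signature sizes depend on reference completeness and
read depth and are not reproduced by the synthetic benchmarks.
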