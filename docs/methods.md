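# Methods

This note documents the models, rules and numerical choices behind
`lncforge`, the assumptions they rest on, and what the synthetic-data
experiments do and do not demonstrate about real data.

## Coordinates and data model

All genomic coordinates are 1-based inclusive (GTF-native) end to end; the
only half-open arithmetic lives inside the interval-tree helpers. A
transcript is a stranded chain of non-overlapping exons; spliced length is
Σ(end − start + 1). Overlap means ≥ 1 shared base; the gap between two
features is the number of bases strictly between them (0 when they
overlap). Single-exon transcripts are readable and flow through the
pipeline — the ≥ 2 exon rule is a filter, not a parser constraint.

## Five-stage filter cascade

Stages run in a fixed order; stages 2–5 are pure per-transcript
predicates, so the retained set is invariant to input order, and retained
counts are non-increasing (monotone attrition). Percentages are always
recomputed from counts and printed to 2 decimals.

1. **Known-coding removal.** "Filtered against coding gene sequences" is
   under-specified in pipelines of this kind, so the rule is explicit: a
   candidate is removed iff it has an intron chain identical to a coding
   reference transcript on the same strand, or it is a same-strand
   contained fragment sharing ≥ 1 splice boundary (mono-exon: inside one
   reference exon with an end on that exon's boundary; multi-exon: its
   intron chain is a contiguous sub-chain of the reference's). Mere exonic
   overlap is *not* removal — otherwise the later "sense" lncRNA class
   could not exist. Candidates on chromosomes absent from the reference
   are retained with a logged warning.
2. **Protein similarity.** Removed iff best E-value ≤ 1e-5 (boundary
   removed: a hit exactly at the cutoff is still a hit). Absence from the
   hit table means "no hit" and retains; hit tables are naturally sparse,
   whereas missing rows in the (dense) coding-potential score table are a
   hard error. This asymmetry is deliberate.
3. **Structure.** Removed iff spliced length < 200 nt or < 2 exons.
4. **Coding-potential consensus.** Retained iff CNCI < 0 and PLEK < 0 and
   CPAT < 0.44, strict inequalities as the thresholds are conventionally
   quoted; the retained set is exactly the three-way intersection of the
   single-tool pass sets.
5. **Detection.** "Identified in at least two samples" is read as
   FPKM > 0 in ≥ 2 samples; the FPKM floor is configurable because no
   floor is standard. Transcripts missing from the matrix are treated as
   unexpressed (removed, with a warning).

## Positional classification

Categories are mutually exclusive and exhaustive, assigned by precedence:
sense (≥ 1 base same-strand exon–exon overlap with a PCG), else antisense
(opposite strand), else intronic (whole span inside a single intron of one
reference transcript, strand-agnostic — intron containment is a positional
property, not a strand property), else intergenic. Exon-level overlap was
chosen over span-level for sense/antisense because exonic evidence is what
distinguishes overlapping transcription from mere locus sharing. Nearest
PCG is by minimal genomic gap with lexicographic gene-id tie-break;
distance is 0 for any overlap class. The production classifier uses
per-chromosome interval trees and is checked in the tests against an
O(n²) all-pairs oracle on random catalogs, and against planted truth.

Length histograms default to bins 200–400/401–600/601–800/801–1000/>1000
(plus an underflow bin so totals always equal input counts); exon bins are
1…10 and >10.

## Differential expression

log₂FC = log₂((mean FPKM_trt + c)/(mean FPKM_ctl + c)) with pseudocount
c = 1 by default (zero-FPKM groups would otherwise make FC undefined); the
test is a two-sided two-sample t on log₂(FPKM + c). The pooled-variance
(Student) form is the default rather than Welch: with three replicates per
group, Welch's Satterthwaite degrees-of-freedom approximation is markedly
conservative (empirical size ≈ 0.033 at nominal 0.05 on exactly normal
data), while the pooled test is exact under the homoscedastic log-normal
model the generator (and, plausibly, small-replicate FPKM data) follows;
`equal_var=False` switches to Welch. Transcripts with degenerate
statistics (e.g. identical groups) get p = 1 and direction `ns`. No
multiple-testing correction is applied by default (raw P < 0.05 is the
convention this pipeline reproduces); fold-change bins use linear |FC|
(|FC| > 2 ⇔ |log₂FC| > 1), so bins nest monotonically and up + down =
total in every row.

qPCR: ΔCt = Ct_target − Ct_reference per replicate, ΔΔCt = mean
ΔCt(treatment) − mean ΔCt(control), relative expression 2^(−ΔΔCt), log₂FC
= −ΔΔCt. Concordance is plain Pearson r over paired log₂ fold changes and
refuses degenerate input (n < 3 or zero variance).

## Target prediction

* **trans** — Pearson correlation of FPKM profiles over all samples,
  both groups pooled: pooling is what makes shared-regulation signals
  visible with six samples. Zero-variance rows are excluded and tallied
  rather than silently producing undefined correlations. The retained set
  uses strict |r| > 0.99; the summary bins *all* computed correlations
  into width-0.2 bins on [−1, 1].
* **cis** — same chromosome and gap ≤ 100 kb between closest transcript
  ends, boundary inclusive, strand ignored, overlap ⇒ gap 0; the score is
  the gap. Genes are reported at gene level with the minimal gap over
  their transcripts.
* **similarity** — Smith–Waterman local alignment (match +1, mismatch −1,
  gap open −2, gap extend −1; all configurable — the method's canonical
  parameters are not standardized, so these are declared defaults, not
  community constants). A pair is reported when the best local alignment
  *contains* ≥ 100 contiguous alignment columns at ≥ 90% identity. The
  window form matters: the score-optimal alignment extends a perfect
  shared core into random flanks whenever extension is net-positive,
  which can dilute whole-alignment identity below the gate even for a
  planted exact 150-mer; a windowed gate is immune to that dilution while
  remaining equally strict on unrelated sequences (no window of 100
  columns in random-sequence alignments approaches 90% identity).

## Network and enrichment

The interaction network is a multigraph: one edge per supporting mode
between a pair (trans_positive, trans_negative, cis, similarity), so a
pair supported by two modes keeps two distinctly typed edges. Pairs
referencing unknown node ids are an error that lists the offenders. An
optional restriction keeps flagged genes (e.g. a heat-shock-protein
family flag) and their lncRNA neighbours.

Enrichment is database-agnostic: the caller supplies the gene → term map
and the background universe (which universe to use — expressed genes vs.
genome — is a modelling decision left explicit). Per term,
p = P(X ≥ k) under Hypergeometric(N, K, n) and fold enrichment is
(k/n)/(K/N) (0 when k = 0). Upper-tail only; Benjamini–Hochberg q-values
are available behind a flag but off by default.

## Synthetic-data generator

The generator emulates a two-group, three-replicate design: ~50 stranded
multi-exon PCGs (2–5 exons of 400–900 nt, introns 4–12 kb, total exonic
length > 1000 nt) laid out on two 4-Mb chromosomes with 20–50 kb
inter-gene gaps, every fifth gap widened to 260 kb so that intergenic
candidates planted at its centre have no gene within the 100 kb cis
window. Candidates (default 50 per positional class + 10 coding-like) are
placed so their class is unambiguous by construction and never overlap
one another; coding-like candidates copy a dedicated template gene's
intron chain and are the stage-1 failures. Filter fates are assigned
60/10/10/10/10% (pass/fail at stages 2–5) and realized in the score, hit,
structure and expression inputs with clear margins around every threshold.

Expression is log-normal: log FPKM = μ_t + (log₂FC·ln 2)·1{treated} +
shared latent factor (sd 1.5, trans pairs only) + N(0, noise_sd), with
μ_t ~ U(ln 5, ln 200) and noise_sd = 0.1 by default; stage-5 failures are
zeroed in all but one sample. DE effects (|log₂FC| = 3 on 10% of
candidates) are planted only on transcripts whose expression is
recoverable — not on stage-5 failures (one detected sample admits no
two-sample test) and not on trans-pair members (the latent factor is
per-sample variation that would mask a group effect at n = 3). At
noise_sd = 0 every fate, class, DE call and cis pair is recovered
exactly, and trans-pair profiles are exactly proportional (r = 1).

The dedicated trans-recovery experiment uses 10 samples per group rather
than the study's 3. The null distribution of Pearson r over n samples has
density ∝ (1 − r²)^((n−4)/2): at n = 6 an unstructured pair crosses
|r| > 0.99 with probability ≈ 1.5×10⁻⁴, so a 50×50 screen expects ~0.4
background pairs and exact planted-set recovery would be a seed lottery —
consistent with real screens at this design, where millions of pairs
yield thousands above 0.99. At n = 20 the crossing probability is
< 10⁻¹², making exact recovery a meaningful check of the thresholding
machinery rather than of luck.

Everything derives from one integer seed through per-component seed
sequences; a fixed scenario reproduces byte-identical files.

**What the generator does not emulate:** read-level artifacts (alignment
error, assembly fragmentation, multi-mapping), FPKM mean–variance
coupling, correlated gene programs beyond the planted pairs, overlapping
genes, isoform families sharing gene ids, and the empirical score
distributions of the coding-potential tools. Passing tests therefore
demonstrate the correctness of the decision rules and accounting, not the
biological accuracy of any threshold on real libraries.

## Problem sizes

The default scenario (50 PCGs, 210 candidates, 6 samples) runs the full
pipeline in a few seconds; the test suite and the acceptance script use
that scale, plus 1500 null transcripts for the type-I measurement, a
50×50 co-expression screen, 20-seed brute-force equivalence sweeps for
the classifier and cis index, and exhaustive enumeration up to N = 12 for
the hypergeometric check.

## Known limitations

* Stage-1 structure matching implements one explicit, documented rule;
  other reasonable readings (e.g. any-overlap removal) give different
  retention counts.
* The cis rule is gene-body anchored; TSS-anchored windows would pair
  differently near long genes.
* With 3 replicates per group the DE test has high variance on real
  (non-log-normal) data; the type-I guarantee shown here is
  model-internal.
* The similarity search is all-vs-all Smith–Waterman; for genome-scale
  inputs a seeded heuristic (BLAST-like) front end would be needed.
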