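# Methods

This note documents the models and procedures implemented in `tsaquant`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic cohort generator does and does not
emulate, and the package's known limitations.

## Coordinate and unit conventions

Genomic coordinates are 0-based half-open internally; GTF I/O converts to
1-based inclusive, BED stays 0-based half-open. Transcript coordinates run
5'→3' (so exon order is reversed for minus-strand transcripts when mapping
a CDS). Expression is FPKM computed as `count · 1e9 / (length_nt ·
library_size)`; the healthy-panel filter is unit-agnostic ("same-unit
median ≤ 0.5") and callers must supply panel tables in units consistent
with their threshold — panels derived from different normalizations (e.g.
TPM) are accepted as-is.

## Transcript handling

One transcript per gene is assumed upstream (the loader enforces unique
transcript ids). Novel transcripts are kept when 300 ≤ spliced length ≤
91666 nt, both bounds inclusive — the upper bound is the longest annotated
tumor lncRNA (KCNQ1OT1). Unstranded novel transcripts take the strand of
the largest-overlap reference-catalog match (ties broken by lexicographic
reference id, a choice made for determinism); transcripts with no match
are discarded. Novel transcripts from different patients are merged by
single-linkage clustering on ≥ 1 bp *exonic* same-strand overlap; the
representative is the longest member (ties by id). Exonic rather than
genomic-span overlap was chosen because span overlap would chain
transcripts through shared introns; the choice matters only for multi-exon
input.

## ncORF enumeration and translation

Candidate starts are ATG and the near-cognates ACG/CTG/GTG/TTG; ORFs end
at an in-frame stop inside the transcript (ORFs truncated by the
transcript end are dropped) and span ≥ 30 nt *including* the stop codon,
so every reported ORF encodes at least one 9-mer. Per (frame, stop) the
most 5' viable start is taken, i.e. the longest of a same-frame
overlapping set. Codons containing N never match starts or stops, and
translate to X; 9-mer windows containing X are excluded downstream. The
initiator codon is translated as methionine regardless of identity,
reflecting initiator-tRNA behaviour (`initiator_as_met=False` restores
literal translation — the switch exists because downstream 9-mers depend
on it). Coding transcripts contribute only their annotated CDS.

## Translation calling

The score combines the two hallmarks of translation in P-site profiles:

* periodicity `f1`: the fraction of ORF P-site counts at positions
  congruent to the ORF start mod 3;
* homogeneity `h`: Shannon entropy of the per-codon count distribution
  divided by `log(n_codons)` (1 for an even spread, → 0 for a
  single-codon pileup; defined as 1 for a single-codon ORF).

`s = f1 · h ∈ [0, 1]`, and an ORF is translated when it has ≥ 5 footprints
and `s ≥ 0.5`. The published approach uses a trained SVM over similar
features with the same 0.5 cutoff semantics; this package substitutes the
transparent product score so results are reproducible without trained
weights. At the default simulated in-frame fraction of 0.58 and good
homogeneity the score clears 0.5; uniform noise sits near `1/3 · h <
0.4`. Overlapping translated ORFs of the same transcript and frame are
reduced to the longest (ties by 5'-most start, then id), applied greedily
by descending length.

The translation index of a class is `Σ length(translated ORFs) /
Σ length(tested ORFs)` — a length-weighted fraction, because it corrects
predicted-binder counts whose denominator is the full ncORF sequence
space. The tested set is all enumerated ncORFs on transcripts expressed
(> expr_cutoff) in ≥ 90% of tumor samples (threshold
`ceil(fraction · n_patients)`), not only ORFs with ≥ 5 reads: restricting
to covered ORFs would bias the index upward. The unweighted count
fraction is reported alongside.

## Tumor specificity

`tumor_specific = pass_matched AND pass_panel`, with strict inequalities
throughout (`> 1` / `< 0.1` FPKM by default; `> 2` / `< 0.2` as a
per-cohort override). The normal-specific set is the exact mirror under a
tumor↔normal swap. Testis/ovary panel expression and thymus expression
(median > 0.5) are recorded but never gate the call: germinal tissue does
not present HLA, and the thymus flag exists to annotate central-tolerance
risk on the candidate shortlist. Transcripts absent from a panel are
treated as unexpressed there with a warning (novel transcripts are absent
from annotation-based panels by construction). Panel filters are applied
uniformly per transcript whatever its class; supplying class-appropriate
panels is the caller's responsibility. The noncoding-enrichment test
computes per patient the noncoding:coding count ratio among tumor-specific
and normal-specific transcripts and applies the paired Wilcoxon
signed-rank test; patients with a zero coding count are dropped with a
warning.

## Antigen model

All 9-mers are enumerated per source (window length is configurable; only
9-mers are modelled by default). Mutation windows substitute the alternate
residue and keep every 9-mer containing it — 9 windows for an internal
position, fewer at termini — excluding windows identical to the reference.
Variants must be missense with depth > 10 and ≥ 3 supporting reads, and
(in the pipeline) lie in a gene expressed in that patient's tumor.

A peptide is a strong binder for a patient when IC50 < 50 nM (strict) for
at least one allele; patient-level sets are invariant to allele order and
duplicates. Counts are unique peptides per class (deduplicated across
alleles and across source ORFs of a class — the dedup policy was open and
peptide-level uniqueness was chosen as the unit of antigenicity). The self
set contains the 9-mers of every product of transcripts that are not
tumor-specific anywhere in the cohort, matched exactly (no mismatch
tolerance); a class's own tumor-specific products are deliberately not in
the self set, otherwise every coding-derived binder would match its own
gene. Corrected loads multiply lncRNA/novel counts by the class
translation index; coding and mutation counts pass through. "Shared"
means the identical 9-mer is a patient-level strong binder in ≥ 2
patients, counted per class independently; shared + private = 1 exactly.

## Cohort analyses

TE overlap is computed on exonic coordinates, requiring ≥ 1 bp on the same
strand; TE copies of a class are union-merged first so no base is counted
twice, and `fraction = overlap_bp / spliced_length`. Unknown-strand TE
features are rejected. Enrichment among tumor-specific versus other
tumor-expressed noncoding transcripts uses the two-sided Fisher's exact
test (one-sided available); the background set is all tumor-expressed
noncoding transcripts. No multiple-testing correction is applied across TE
classes by default. The candidate shortlist keeps transcripts
tumor-specific in ≥ `ceil(0.10 · n_patients)` patients (the ceiling
convention matches the 10%-of-117 → 12 instance), with tumor FPKM > 5
somewhere and expressed in < 1% of normal samples. Candidate
co-expression is the Pearson correlation over tumor samples, with
per-class means of off-diagonal entries; zero-variance candidates yield
missing correlations.

## Synthetic cohort generator

The generator emulates the *statistical structure* the pipeline is
designed to detect, with full ground-truth labels:

* **Expression.** Log-normal FPKM with class-dependent medians (coding ≈
  e³ ≈ 20 > lncRNA ≈ 4 > novel ≈ 2, σ = 0.8 on the log scale).
  Non-tumor-specific transcripts are either expressed in both tissues of
  every patient (floored well above the normal cutoff) or silent
  everywhere; activation events place carriers' tumor values above the
  tumor cutoff and matched normals below the normal cutoff. This
  construction makes ground truth exactly recoverable through the matched
  filter, which is intentional: it turns the specificity cascade into an
  exactly checkable operation. Real data have transcripts hovering at the
  cutoffs; the tests therefore say nothing about borderline-expression
  behaviour beyond the strict inequality convention.
* **Prevalence.** Carriers per event are drawn from a truncated geometric
  distribution (p = 0.35), so most events are private but some are shared
  by > 10% of patients, enabling the shortlist stage.
* **Footprints.** Translated ORFs receive Poisson(`mean_depth`, default
  300) P-sites, multinomial over positions with in-frame probability
  `inframe_read_fraction` (default 0.58, the observed periodicity of
  28-nt footprints) and uniform codon usage; untranslated ORFs receive
  Poisson(`mean_depth · noise_fraction`, default 0.1) uniform noise with
  expected in-frame fraction 1/3. Profiles are emitted at P-site
  resolution directly — read-length offsets are an alignment artifact
  outside this package's scope.
* **Sequence composition.** Noncoding transcripts are G-poor
  (A/C/G/T = 0.37/0.27/0.03/0.33). Every permitted start codon contains a
  G while the TAA stop does not, so candidate ORFs are short (~80 nt) and
  rarely overlap across frames. This is a deliberate generator property,
  not a claim about lncRNA composition: with uniform bases, candidate
  ORFs overlap so heavily that a labelled translated length fraction of
  0.5 is unreachable without co-translating overlapping ORFs, which the
  product score cannot resolve. The translated set is chosen
  length-weighted toward the class target (defaults 0.116 for lncRNAs,
  0.0053 for novel transcripts), never co-selecting overlapping ORFs.
* **HLA and affinity.** Six alleles per patient drawn without replacement
  from a 12-allele pool. The surrogate predictor scores a 9-mer with an
  allele-seeded N(0,1) position-weight matrix, standardizes by the PWM's
  analytic mean/sd under uniform residues, and maps the normal tail
  probability u through `50000 · u^α` with `α = log(50/50000) /
  log(strong_rate)`, so a `strong_rate` fraction (default 0.09, near
  observed per-allele strong-binder rates of 6.5–9.7%) of random peptides
  falls under 50 nM. It is deterministic and allele-specific but carries
  no binding-motif biology: anchor-residue effects, allele similarity and
  peptide-composition biases of real predictors are absent.
* **Mutations.** Poisson(8) somatic events per patient (a low-mutation
  tumor setting), private by default — distinct (gene, position) pairs
  across the cohort — with a configurable recurrence rate; ~15% of
  emitted records deliberately fail the depth/alt/consequence filters to
  exercise them.
* **TEs.** HERV intervals are placed on noncoding exons with background
  probability 0.15 and odds multiplied by `herv_enrichment_odds` (default
  4) for tumor-specific transcripts: `p_ts = odds·p / (1 − p + odds·p)`.
  Opposite-strand HERVs and other TE classes are sprinkled as negative
  controls.

Regenerating a bundle from the same seed is byte-identical (single RNG,
fixed draw order, deterministic writers with fixed float formatting).

Because all distributions are stand-ins, passing tests demonstrate
*operational correctness and recoverability of planted signal*, not
performance on real data: real cohorts add batch effects, borderline
expression, overlapping translated frames, predictor biases and alignment
noise that the generator deliberately omits.

## Numerical choices and degenerate inputs

* Threshold semantics are strict everywhere they gate (">", "<"), and
  inclusive where stated (novel length bounds, panel median ≤ 0.5).
* Zero-read ORFs score 0/0/0 and are never translated; an empty tested
  set gives a translation index of 0 with a warning.
* Degenerate 2×2 margins give Fisher p = 1 with a warning; zero-variance
  candidates give missing correlations.
* Problem sizes used by the test-suite and acceptance measurements —
  500-ORF benchmarks at depth 300, 12-patient cohorts of 150 transcripts,
  50-seed power batches — were chosen so each planted effect is measured
  with comfortable statistical margin while a full run stays interactive
  on a laptop.

## Limitations

* The translation score is a transparent substitute for a trained
  classifier; absolute scores are not comparable to published SVM scores,
  only the cutoff semantics are preserved.
* The exact derivation of a published translation index from a count
  fraction cannot be verified without the original ORF length tables; the
  length-weighted definition implemented here is consistent with both
  statements and carried at full precision.
* Read alignment, de novo assembly, rRNA homology screening, HLA typing
  and MS immunopeptidomics searches are out of scope; the package consumes
  their outputs as tables (an rRNA exclusion list can be supplied as a
  precomputed hook).
* Whether shared-binder accounting should require the peptide to be
  strong under each carrier's own alleles (implemented) or any allele in
  the cohort is an open interpretation; with the surrogate predictor the
  difference is small.
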