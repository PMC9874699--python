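# Methods

`famsv` implements a family-based discovery analysis for medium-sized
structural variants (SVs, roughly 30–12,000 bp): events too large for
short-read indel calling and too small for SNP-array CNV detection, best
resolved by long-read sequencing. The design assumes a multiplex-family
cohort — several affected probands plus unaffected relatives from the same
lineages — in which high-penetrance rare SVs are expected to be present in
probands and absent from unaffected relatives.

The pipeline runs in a fixed order: per-sample multi-caller consensus →
pathogenicity-class filter → family exclusivity subtraction → gene and
intron/exon annotation → summary statistics → pathway over-representation →
pathway–gene bi-clustering → developmental brain-region enrichment with a
permutation family-wise error rate (FWER).

## Consensus calling

Long-read SV callers disagree substantially on individual events, so each
sample's calls are merged across callers before interpretation. Two
span-type calls (DEL/DUP/INV) describe the same event when their
**reciprocal overlap** — overlap length divided by the longer span,
computed on 0-based half-open intervals — is at least `ro_threshold`
(default 0.7). Reciprocal overlap is undefined for point insertions, so
two INS calls match when their anchors lie within `ins_window` (default
500 bp) and the shorter inserted length is at least `ins_ratio` (default
0.7, mirroring the reciprocal rule) of the longer.

Calls of one type on one contig are grouped by **single-linkage connected
components** of the pairwise match predicate — the standard choice in SV
merging tools, and invariant to input order. A component supported by at
least `min_support` distinct callers (default 2 of 4; "multiple tools" is
read in its weakest sense, configurable 2–4) emits one consensus SV. A
caller contributes one call per component: the call closest by start to the
component median, ties to the smaller start. Representative start and
length are medians over the contributing calls, rounded half-up — robust to
a single outlier caller. The consensus class is the most severe
pathogenicity class among members. Single-linkage can chain calls whose
mutual overlap is below the threshold; with realistic breakpoint scatter
this is rare and accepted.

## Family exclusivity filtering

Only consensus SVs of pathogenicity class ≥ `min_class` (default 4,
"likely pathogenic"; the 5-level ACMG-style scale is consumed as input,
never computed here) enter the subtraction. A case SV is then **removed if
any single-caller call of the same type in any control sample matches it**.
The asymmetry is deliberate and conservative in the right direction: a
case SV needs multi-caller support to exist, but one tool's evidence in a
control is enough to disqualify it as case-specific. Control calls are not
class-filtered. Matching is within-svtype only (a DUP in a control does not
absolve a case DEL). Both directions (proband-exclusive and
relative-exclusive) use the same machinery with roles swapped, and every
removal is written to an audit table with the matching control call.

**Control matching predicate.** A control call matches a case SV when it
satisfies the type predicate against the consensus representative *or any
member call*. For span types the reciprocal-overlap rule is supplemented
by the insertion-style proximity rule (breakpoint distance ≤ `ins_window`
and length ratio ≥ `ins_ratio`). This supplement is a deliberate design
choice: for events near the 30 bp minimum, a reciprocal overlap of 0.7
requires the breakpoint shift to stay within 30% of the span (≤ 18 bp for
a 60 bp event), which realistic breakpoint scatter routinely violates —
strict reciprocal overlap would leave shared family variants in the
"exclusive" set purely through caller jitter. The consensus stage keeps
the strict rule; only control-evidence matching is loosened. The known
cost is that a genuinely distinct small event within 500 bp of a control
call of similar size would be wrongly subtracted; at realistic SV
densities this is negligible, and the filter errs toward specificity of
the final case-exclusive list, which is its purpose.

## Gene annotation and summaries

Gene models come from GFF3 (longest transcript per gene, since a single
feature label per SV is reported) or BED12. Features are numbered 1..n in
**transcription order** — on the minus strand exon 1 is the genomic-
rightmost exon — matching RefSeq-style annotator conventions. Span SVs are
labeled by the first and last overlapped feature (`intron5`,
`exon30-intron30`); insertions by the feature containing their anchor.
Genes are matched by any overlap with the gene body (no promoter flank);
with several candidates the largest overlap wins, ties by name. Summary
statistics (counts, distinct genes, genes hit at two loci, length min /
max / mean / median per subset) are exact; means and medians are also
reported rounded half-up to the nearest integer, the convention used when
quoting such tables (a median over an even count can end in .5).

## Pathway over-representation

The query (genes hit by case-exclusive SVs) is tested against each pathway
with the hypergeometric upper tail P(X ≥ k), inclusive. Terms whose
background member count lies outside `[min_bg, max_bg]` (default
[30, 1000]) are excluded **before** the Benjamini–Hochberg adjustment, so
the correction spans only the tested terms — the per-analysis convention
of STRING-style services. Retention requires FDR < 0.05 **and** strength
= log10((k/n)/(K/N)) > 0.5; at k = 0 the strength is undefined and the
term can never be retained. The background defaults to the supplied gene
universe and is configurable (a genome-wide background is the intended
production use). The specific pathway lists of any given annotation
snapshot are out of scope; the statistic and filters are what is
implemented and tested.

## Bi-clustering

Retained pathways and their query genes form a binary membership matrix
(all-zero rows/columns pruned). Each axis is clustered independently with
average linkage over Jaccard distance — the standard pairing for binary
membership data — and cut into `k_pathways` (default 9) and `k_genes`
(default 8) flat clusters. The defaults are parameters, not estimates: how
many clusters a dendrogram "suggests" is a judgment call. Leaves are put
into a canonical order (membership pattern, then name) before linkage, so
results are deterministic and invariant to row/column permutations even
with tied merge heights.

## Brain-region enrichment

The expression input is a gene × (region, stage) matrix over 16 brain
regions and 5 developmental stages (prenatal, infant, child, adolescent,
adult). The **background** is the brain-biased gene set: genes with log2
fold-change strictly greater than 0.5 (brain vs other tissues) in either
of two reference summaries (union rule). Target genes absent from the
background or matrix are dropped with a log message, mirroring real
annotation gaps.

For each cell and each quantile cutoff q ∈ {0.5, 0.6, 0.7, 0.8, 0.9}
(five equally spaced values), the high-expression set is the genes
strictly above the q-th quantile of that cell's expression over background
genes (linear-interpolation quantile; strict `>`, so a constant cell has
an empty high set — these conventions are fixed for reproducibility). The
cell p-value is the hypergeometric upper tail with N = |background|,
K = |high set|, n = |target ∩ background|, k = |target ∩ high set|.

The **permutation FWER** draws R random gene sets of size n from the
background, recomputes all cell p-values, and records each permutation's
minimum p over the 80 region × stage cells *within one quantile's family*
(the per-quantile family matches how such results are tabulated, one FWER
column per cutoff; whether the reference procedure pools quantiles is not
documented, and per-quantile is the assumption made here). A cell's FWER
is the add-one estimator (1 + #{min-p ≤ observed p}) / (R + 1) — never
zero, floor 1/(R+1) — with ties counting against the observed value.

## Synthetic cohorts

The generator produces everything the pipeline consumes, so every stage is
testable without external data. What it emulates, and its defaults:

- **Cohort**: 10 probands, 5 unaffected relatives, 4 identically
  parameterized long-read caller profiles — the study design it mirrors.
- **SV lengths**: a three-component mixture on the log10 scale — weights
  0.55 / 0.35 / 0.10 for a small-event tail (shifted geometric on
  [30, 200] bp, median 60 bp), an Alu-like mode (log10-normal at 2.5,
  i.e. ~300 bp) and an L1-like mode (at 3.8, ~6 kb), both with scale 0.08;
  minimum length 30 bp. This reproduces the characteristic bimodal
  density of retrotransposon-driven events and a 60 bp median.
- **Truth structure**: shared SVs are family-background variants — each
  carried by a random subset of samples (each sample independently with
  probability 0.5) that always includes at least one unaffected relative,
  which is what makes them removable by the exclusivity subtraction and
  reflects variants segregating through the family. Case-specific SVs are
  each planted in one random proband and never in a relative; they carry
  class 4 while shared SVs are class 4 with configurable probability
  (default 0.5). Truth events are spaced ≥ 20 kb apart so distinct events
  never satisfy a match predicate. With gene models supplied, case-
  specific SVs are placed inside gene bodies so annotation and enrichment
  have a recoverable signal.
- **Caller errors**: per caller, each true SV is detected with
  `sensitivity` (default 0.9); detected calls get Gaussian start jitter
  (sd `breakpoint_jitter`, default 20 bp) and optional length jitter;
  spurious calls arrive at Poisson rate `false_rate` (default 5 per
  sample) at random positions. The profiles are free parameters, not
  estimates of any real caller.
- **Expression**: i.i.d. Normal(5, 1) baseline; target genes shifted by
  `effect` standard deviations in one chosen (region, stage) cell; 70% of
  genes marked brain-biased in the fold-change tables (targets forced
  brain-biased by default, emulating the selection of brain-expressed
  genes for this analysis).

What the generator does **not** emulate: sequence context (no reads, no
repeat structure, no alignment artifacts), correlated caller errors (real
callers fail on the same hard loci), pedigree transmission and linkage,
co-expression structure across genes, and region/stage autocorrelation in
expression. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its stated model, not
performance on real sequencing data.

## Verification studies and problem sizes

The test suite and `scripts/acceptance.py` rerun the same studies; sizes
were chosen to give stable Monte-Carlo answers at interactive runtimes:

- consensus merging vs a brute-force oracle (all-pairs predicate +
  connected components) on 1,000 random instances of up to 200 calls;
- the hypergeometric tail vs exhaustive combinatorial enumeration for all
  parameter combinations with N ≤ 12;
- planted-SV recovery on the default cohort with sensitivity 0.95 and
  20 bp jitter, 30 case-specific class-4 SVs against 200 shared SVs
  (recovery ≥ 90%, no shared variant retained);
- pathway-enrichment null calibration: 500 random 47-gene queries against
  random 200-term pathway collections over a 10,000-gene background
  (discrete hypergeometric p-values make the realized q < 0.05 rate far
  below nominal);
- brain-enrichment null (effect 0, R = 200; ≤ 5% of cells at FWER < 0.05)
  and power (+5 SD on 40 genes, R = 1000; the planted cell reaches
  FWER < 0.05 at q = 0.5).

## Known limitations

- No left-normalization or breakpoint standardization of input VCFs; two
  representations of the same event at different positions will not merge.
- BND/translocations and multi-allelic records are skipped on input.
- One transcript per gene; feature labels can differ from annotations
  based on another transcript set.
- The bundled 88-SV reference table ships with verbatim gene and feature
  labels; they are not recomputed from a transcript database.
- The permutation FWER treats genes as exchangeable under the null;
  correlated expression would make it anti-conservative on real data.
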