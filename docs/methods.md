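# Methods

## Clonotype calling

A clonotype is an identifier for a clonal lineage built from the paired
receptor chains of one cell. After filtering, contigs sharing a barcode
are merged; locus 1 is TRA (or TRG) and locus 2 TRB (or TRD) for T cells,
IGH then IGK/IGL for B cells. Four identifiers are constructed per cell:

| key      | built from                         | use                                  |
|----------|------------------------------------|--------------------------------------|
| CTgene   | V(D)JC segments, `.`-joined        | most sensitive (ignores junction)    |
| CTnt     | CDR3 nucleotide sequences          | strictest sequence-level call        |
| CTaa     | CDR3 amino-acid sequences          | convergent-recombination aware       |
| CTstrict | per-locus `gene:nt`                | genes and junction combined          |

Encoding rules: loci joined by `_`; a missing locus is the literal `NA`
(not an empty string), so single-chain cells remain distinguishable and
the strings stay splittable; same-locus duplicates joined by `;`. The
constant gene participates in `CTgene` — it adds isotype/locus resolution
at the cost of sensitivity to annotation differences; callers wanting a
V·J-only key can rebuild it from the per-chain columns.

**Duplicate chains.** Cells with more than two contigs of one locus keep
the two with the highest UMI count (ties: reads, then contig id) — two
productive alpha chains are biologically real in ~10% of T cells, while
third contigs are nearly always artifacts. The *retained* duplicates are
then ordered lexicographically by CDR3 nucleotide sequence (ties: amino
acid, then gene string) before joining. Ordering by content rather than
by UMI rank matters: two cells of the same clone sequence the same two
alpha chains with independent UMI noise, and a UMI-ordered join would
give them different keys. Content ordering makes clonotype keys a pure
function of the chain set.

**Barcode prefixing.** Barcodes are prefixed `sample_` (plus the group
label when given) to guarantee global uniqueness across samples. The
separator `_` collides with barcodes that already contain underscores;
the combiner warns rather than fails, since downstream joins only require
consistency, not splittability.

## Filtering defaults

Productive, high-confidence, called-cell contigs with ≥ 1 UMI, restricted
to {TRA, TRB} (TCR mode) or {IGH, IGK, IGL} (BCR mode). The reader itself
retains everything — including `Multi`/`None` chains and unproductive
contigs — so users can audit what the filters drop. Booleans parse
case-insensitively with Cell Ranger's tri-state `None` mapping to false.
AIRR Rearrangement files carry no cell-calling or confidence flags in the
core schema; records default to true for those fields, on the assumption
that a Rearrangement TSV contains called cells.

## Clonal-architecture statistics

*Homeostasis bins* default to Rare ≤ 10⁻⁴, Small ≤ 10⁻³, Medium ≤ 0.01,
Large ≤ 0.1, Hyperexpanded ≤ 1; bins are half-open on the left and closed
on the right, so 10,000 singletons (p = 10⁻⁴ each) are all Rare. *Clonal
proportion* ranks by descending count with lexicographic tie-break
(determinism over any claim about equal clones) and defaults to rank cuts
10/100/1,000/10,000/30,000/100,000. *Scaled unique quantification* is a
percentage (100 × unique/cells), not a fraction. *Combined CDR3 length*
sums only real sequence — the `NA` placeholder and separators are
excluded, otherwise every single-chain cell would gain a spurious +3 and
the single/dual-receptor bimodality of the combined distribution would be
distorted.

The bimodality check (`count_length_modes`) histograms integer lengths,
smooths with a 5-wide moving average, and counts peaks of prominence
≥ 10% of the tallest bin. It should be fed lengths of *distinct*
clonotypes: in clonal repertoires a single expanded clone otherwise
injects a cell-weighted spike at its own length that reads as a mode.

## Diversity estimators

Shannon entropy uses the natural log (the convention of the ecology
packages this field relies on); divide by ln 2 for bits. Chao1 uses the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined even without
doubletons; it differs from the classic F₁²/(2F₂) form by at most the
singleton term's curvature and coincides when F₂ ≫ F₁. ACE uses the
standard rare-class threshold of 10 (exposed as a parameter) and falls
back to Chao1 when every rare clone is a singleton (coverage 0). Both
richness estimators assume abundance-based sampling from a closed
repertoire; with 10x data the "individuals" are cells, so UMI-level
duplicates must already be collapsed (Cell Ranger does this).

"Morisita" overlap is implemented as Morisita-Horn on relative
abundances: the classic Morisita λ needs integer counts ≥ 2 per class
and degenerates on singleton-heavy repertoires, which single-cell data
always are. It is scale-invariant and abundance-weighted, 0 for disjoint
and 1 for proportionally identical repertoires.

## Clone-size distribution clustering

Samples are compared by the *shape* of their clone-size distributions,
independent of which clonotypes they contain: clone sizes are pooled to
fix log-spaced bin edges (default 30 bins) spanning the observed range,
each sample's histogram is normalised, and pairs are scored with base-2
Jensen-Shannon divergence (0 log 0 := 0; JSD ∈ [0, 1], 1 iff disjoint
support; √JSD is a metric). Binned empirical distributions were chosen
over parametric clone-size model fits: they are assumption-free,
deterministic, and adequate for clustering; fitting spliced heavy-tail
models is out of scope. Hierarchical clustering uses average linkage on
the JSD matrix with samples pre-sorted alphabetically, making leaf order
deterministic; the dendrogram exports as Newick.

## Metadata joining

`combine_expression` is a strict left join on barcode — never drops or
duplicates metadata rows. Clone frequency is computed per sample by
default: pooling samples first would inflate frequencies of public or
convergent clonotypes; a `global` scope is available. Frequency bins
default to Single ≤ 1, Small ≤ 5, Medium ≤ 20, Large ≤ 100,
Hyperexpanded ≤ 500 cells, with a proportion mode for cohorts of unequal
depth; frequencies beyond the last bound clamp into the last bin. A join
with zero barcode overlap raises immediately and names the likely cause
(mismatched prefixes) — the most common user failure.

## Synthetic repertoires

The generator emulates the features downstream statistics are sensitive
to, with defaults describing a typical 10x T-cell enrichment run:

| parameter          | default          | rationale                                   |
|--------------------|------------------|---------------------------------------------|
| clone sizes        | power law, α=2.5 | heavy tail typical of expanded repertoires  |
| dual-alpha rate    | 0.10             | ~10% of T cells carry two productive TRA    |
| chain dropout      | 0.08 per locus   | single-chain capture failure rate           |
| spurious contigs   | 0.02             | rare third low-UMI contig                   |
| CDR3 length        | 8–20 aa, peak 14 | discretised Gaussian (σ=2), in frame, Cys…Phe |

CDR3 nucleotide strings are random sense-codon strings (no stops), so
amino-acid fields are exact standard-code translations; lengths span
24–60 nt in steps of 3. UMI counts are ≥ 2 for real contigs and exactly
1 for spurious ones, so top-2-by-UMI retention provably removes the
latter.

Dropout and dual-alpha status are drawn per *clone*, not per cell, and
spurious contigs are attached only to dual-alpha cells: every cell of a
clone therefore carries an identical chain set, which is what makes the
planted clone structure recoverable *exactly* from clonotype keys — the
property the end-to-end tests assert. Real data violates this (dropout is
per cell), so passing recovery tests demonstrate the correctness of the
pipeline's bookkeeping, not robustness to per-cell chain loss. Other
unmodelled aspects: V(D)J gene-segment/junction structure (genes are
drawn independently of sequences), sequencing error, barcode collisions,
and shared clonotypes between samples (each sample's CDR3s are unique,
so between-sample overlap is genuinely zero in simulations).

## Problem sizes and numerical notes

Tests and the acceptance script use 3 samples × 2,000 cells (power-law
clones), which exercises every code path including multi-chain trimming
at sub-minute runtimes; statistics at this size are stable to the
asserted tolerances (1e-9 for estimator identities, 1e-12 for
conservation sums). Proportions are accumulated in double precision;
homeostasis and abundance sums conserve to 1e-12. Degenerate inputs:
empty count vectors raise for diversity/overlap (undefined) but return
empty/zero tables for descriptive statistics; a pooled clone-size range
of a single value collapses JSD binning to one bin (all distances 0).

## Known limitations

- BCR clonotypes are exact-string keyed; somatic-hypermutation-aware
  lineage clustering (edit-distance grouping) is not implemented.
- No bootstrap confidence intervals or rarefaction for diversity.
- Gamma/delta loci are accepted throughout but share the alpha/beta
  locus slots; mixed αβ/γδ samples should be filtered to one receptor
  class per run.
- Plotting is deliberately minimal (length histogram, homeostasis bars,
  embedding scatter); the exported tables are the primary interface.
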