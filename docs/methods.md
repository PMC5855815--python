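# Methods

`aposenet` implements a regulatory-genomics analysis for the unliganded
(apo) estrogen receptor alpha in hormone-deprived breast-cancer cells: it
predicts super-enhancers (SEs) from H3K27ac ChIP-seq peaks, intersects them
with apoER-alpha binding sites (aERBSs), associates SEs with coding and
lncRNA genes by TSS distance, quantifies the down-regulation bias of
receptor-bound genes, and builds a promoter/enhancer chromatin-interaction
network from ChIA-PET anchor pairs. A seeded synthetic-data generator
provides inputs with known planted structure, so every stage is scored
against ground truth without external downloads.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention); GTF input (1-based
inclusive) is converted on read. The TSS is the 5' end of the longest
annotated isoform (`start` on "+", `end - 1` on "-"). Chromosome names are
matched by exact string equality; no "chr" normalisation is applied, so a
naming mismatch between inputs surfaces as an empty overlap rather than
being silently patched.

## Super-enhancer calling

The caller follows the ROSE procedure:

1. **Stitching.** Per chromosome, H3K27ac peaks sorted by start are merged
   transitively whenever the gap between consecutive peaks is at most the
   stitch distance (default 12,500 bp, the published ROSE default).
   Stitching is idempotent and order-invariant; output regions are disjoint
   and separated by more than the stitch distance. An optional
   TSS-exclusion window (default 0 = disabled) removes promoter-proximal
   peaks before stitching.
2. **Ranking.** Each stitched region is scored by total ChIP signal minus
   total input signal over the region, in CPM x bp, floored at 0 (input can
   exceed ChIP in noise, and negative values would break the cutoff
   geometry). Total signal rather than per-bp density is used deliberately:
   wide peak clusters accumulating signal are exactly what super-enhancers
   are, and a density rank would penalise them.
3. **Cutoff.** With ranked net signals s_1 <= ... <= s_n and global slope
   m = (s_n - s_1)/(n - 1), each index i defines a slope-m line through
   (i, s_i); the tangent index i* maximises the number of points strictly
   above that line, i.e. it is the point where the line of average slope
   supports the ranked curve from below — the curve's elbow. Ties are
   resolved to the largest index, the conservative choice: on a perfectly
   linear or flat curve every count is zero and the threshold becomes the
   top value, so no region is called. Regions with net signal strictly
   greater than s_{i*} are super-enhancers; consequently at most n - 1
   regions can ever be called. SE membership is invariant under positive
   rescaling of the signal. The implementation is verified against an
   exhaustive enumeration oracle on random instances.

The SE center, used for gene association, is the floor midpoint of the
stitched interval.

## Binding-site integration and expression summaries

* **SE-aERBS selection**: an SE qualifies when its stitched interval
  overlaps at least one binding site (half-open overlap; adjacency does not
  count). Selection is monotone in the site set.
* **Gene association**: a gene associates with a region when
  |TSS - SE center| <= 100 kb (inclusive). The center-based rule is used
  everywhere for consistency; an edge-based distance (TSS to the stitched
  interval) is available behind `mode="edge"`. Each region also reports its
  nearest gene ("first proximal TSS"), read as nearest-TSS, with
  lexicographic gene-id tie-breaking for determinism.
* **DE classification**: down iff adjusted p < alpha and log2FC < 0; up iff
  adjusted p < alpha and log2FC > 0; everything else — including log2FC
  exactly 0 — is unchanged, so the classes partition cleanly. Defaults:
  alpha = 0.001 for the receptor-silencing contrast, 0.05 for the
  estradiol time course. Rows missing the adjusted p-value are skipped and
  counted, never silently dropped.
* **Binding bias**: per DE class, the fraction of genes with a binding site
  within 100 kb of the TSS, as a percentage rounded half-up to one decimal
  (exact decimal arithmetic, so 485/1376 -> 35.2 and 300/1110 -> 27.0). A
  two-sided Fisher exact test on the down/up x bound/unbound table is
  attached as an optional annotation; the bias claim itself requires no
  named test.
* **Cross-tabulation**: silencing labels x time-course labels, restricted
  to SE-associated genes; a gene measured on only one axis lands in that
  axis's "unmeasured" margin, so the matrix total always equals the gene
  universe.
* **FPKM**: normalised count / ((longest isoform length / 1000) x millions
  of counted fragments).

## Interaction network

Promoter footprints span -2,000/+500 bp around the TSS, oriented by strand
(mirrored on "-"; "around the TSS" is direction-ambiguous, and upstream is
taken in the transcriptional sense); aERBS footprints are sites extended by
1,000 bp on each side; both are clipped at coordinate 0. Every ChIA-PET
pair connects all nodes overlapping anchor 1 to all nodes overlapping
anchor 2 (combinatorial expansion — the data cannot distinguish co-located
footprints); self-links and same-anchor links are never created, since a
pair evidences only the anchor1-anchor2 contact. Per experiment the pair
counts linking a node pair are summed; the edge weight is the mean of these
sums over the experiments containing at least one such pair (a single
experiment degenerates to a plain count). The graph is undirected, so
reciprocal anchor orderings are equivalent. A `first_match` mode assigns
each anchor to its maximal-overlap footprint only; in that mode assigned
plus unassigned pair mass equals the input mass exactly, per experiment,
which serves as a conservation diagnostic. In the default combinatorial
mode a multiply-overlapped anchor intentionally multiplies its mass.

## Synthetic data

The generator emulates the statistical structure of the study inputs on a
small genome (two 6-Mb chromosomes by default):

* 500 non-overlapping genes with random strand and a biotype mix dominated
  by protein-coding genes plus the lncRNA classes used in the breakdowns;
* 3 planted SEs of 5 peaks inside a 10-kb window (intra-cluster gaps well
  below the stitch distance), each placed within 100 kb of a randomly
  chosen gene TSS, among 50 isolated background peaks separated by more
  than the stitch distance;
* a uniform input track at 1 CPM; ChIP enrichment of 2 CPM over background
  peaks and `se_signal_ratio` (default 5) times that over planted peaks;
* 1-3 aERBSs inside 70% of planted SEs; genes within 100 kb of a bound SE
  center down-regulated with probability 0.75 versus 0.4 elsewhere, with
  the residual probability split evenly between up and unchanged, realised
  as (log2FC, adjusted p) pairs matching the classification thresholds; an
  independently drawn estradiol time-course table in which 40% of
  SE-associated genes respond;
* 4 ChIA-PET pairs per planted SE-promoter loop (anchor 1 in a binding
  site, anchor 2 in the target promoter) plus 6 uniformly placed noise
  pairs, counts 1 + Poisson(1).

Each generator draws from its own stream derived from the master seed by a
fixed offset, so outputs are byte-identical under a fixed seed and adding
one generator never perturbs another.

**Idealisations.** Background peaks share one width and one enrichment
density, so the null ranked-signal curve is exactly flat and the tie-break
yields zero false SE calls; real rank curves carry continuous signal
variation, where the elbow geometry (tested separately against the
enumeration oracle on random vectors) decides. Signal tracks are noise-free
step functions; there is no read-level sampling, sequence content, copy
number, or mappability structure. Passing recovery suites therefore
demonstrates correctness of the analysis logic under the planted model, not
robustness to the full noise spectrum of real ChIP-seq.

## Numerical and degenerate-input choices

* Percentages: half-up rounding to one decimal via exact decimal
  arithmetic (float division would misround edge cases).
* Cutoff ties: largest index; ranking ties: (chrom, start) ascending.
* Fewer than two stitched regions: no cutoff exists; nothing is flagged
  super and the pipeline proceeds (an empty peak file yields an empty but
  complete report).
* Anchor-to-footprint ties in `first_match` mode: maximal overlap, then
  smaller node id.
* A pipeline run validates all input paths up front and aborts naming the
  missing file; a stage failure aborts naming the stage and its input.

## Problem sizes

Recovery suites use 20 seeded replicates of the default bundle (500 genes,
12 Mb, 53 peak regions, ~30 pairs); the whole test suite and the
acceptance script each complete in well under a minute on one core. The
dataset-scale counts of the original study (hundreds of SEs from
genome-wide ChIP-seq) depend on its deposited accessions and alignment
choices and are outside what the synthetic conditions reproduce; the
package reports them for whatever input it is given.

## Known limitations

* Peak calling, read alignment and DE model fitting are upstream and out
  of scope: the pipeline consumes peak BEDs, bedGraph tracks and DE tables.
* ChIA-PET loop calling from raw tags is not performed; pairs are taken as
  given, and Hi-C-style contact matrices are not supported.
* The caller implements the stitching/tangent-cutoff procedure itself; it
  does not shell out to the original ROSE scripts, so option-for-option
  parity with every ROSE release is not claimed.
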