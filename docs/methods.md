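# Methods

## The Orthology Index

A syntenic block is an ordered run of homologous gene pairs between two
genomic regions. For a block with `m` pairs of which `n` appear in a
set of pre-inferred ortholog pairs (from any upstream orthology
inference producing pairwise calls), the Orthology Index is
`OI = n/m ∈ [0, 1]`. Blocks arising from the speciation of the two
genomes approach 1 (limited only by the recall of the upstream
inference); blocks arising from a WGD that predates the speciation
approach 0 (limited by its precision). `n` and `m` are stored as the
truth; `OI` is their exact ratio in floating point, and an empty block
is a hard error rather than a silent 0/0.

Filtering retains blocks with `OI ≥ cutoff` — the boundary value is
kept, since only blocks *below* the threshold are discarded. The
default cutoff is 0.6, balancing false negatives (higher cutoffs
discard genuine orthologous blocks) against false positives (lower
cutoffs admit out-paralogous ones); 0.5 is the documented permissive
alternative. A `min_pairs` floor (default 1, i.e. inactive) optionally
restricts output to longer, more credible blocks.

Extraction emits **every** pair of a retained block as a syntenic
ortholog, including pairs absent from the upstream calls: within a
high-OI block such pairs are most plausibly orthologs the upstream
inference missed. A pair present in several retained blocks is
reported once, with the maximum block OI (documented choice; the
alternative — listing each supporting block — is recoverable from the
block file).

The OI distribution is summarized pair-weighted (each block contributes
`m` counts at its OI) in half-open bins of width 0.05, the last bin
closed. The *noise* statistic is the pair-weighted mass with OI in
[0.3, 0.7) — the dividing band that is nearly empty when the
distribution is polarized; a block-weighted variant is also reported.

## File formats

Gene tables are TSV (`chrom start end gene_id [strand]`) with 1-based
inclusive coordinates; gene order indices are 0-based ranks recomputed
per chromosome from start coordinates, ties broken by gene id so
ranking is deterministic. Blocks are read from MCScanX collinearity,
JCVI anchors, WGDI-style block-info CSV, or the package's own canonical
dialect, which is bit-stable (floats at 4 decimals, no timestamps) and
round-trips exactly. Ortholog pairs come as two-column TSV or
OrthoFinder-style rows; many-to-many rows are expanded to the Cartesian
product of the two gene lists (the package's documented resolution of
co-ortholog lists). Blocks violating within-block monotonicity parse
with a warning rather than an error — detector outputs contain minor
order noise and OI does not depend on within-block order. Tandem
duplicates are not collapsed at parse time; that is the upstream
detector's responsibility.

## Syntenic orthogroups

OI-filtered pairs from all genome pairs form the orthologous syntenic
graph: nodes are genes tagged with their genome, edges are distinct
syntenic-ortholog pairs weighted by the maximum supporting-block OI
(unit weights available for ablation). Within-genome edges are
rejected.

The graph is partitioned with a Markov Cluster implementation written
from first principles on a dense column-stochastic matrix:

1. self-loops with weight equal to the node's maximum incident edge
   weight (1 for isolated nodes) — standard MCL practice that prevents
   premature attractor collapse;
2. column normalization;
3. iterate expansion (matrix power, default 2) then inflation
   (entrywise power, default 1.5, followed by renormalization), pruning
   entries below 1e-5, until the maximum entrywise change falls below
   1e-6 or 100 iterations elapse. Non-convergence yields the current
   interpretation with a warning flag, never an exception.

Clusters are read from attractor rows (positive diagonal); attractors
sharing support form one attractor system, and each node joins the
system holding the largest share of its column mass, ties broken by the
lexicographically smallest attractor id. The result is always a
partition; disconnected components can never merge because expansion
preserves block structure. Inflation 1.5 follows the convention of the
orthogroup tools built on MCL; the edge weighting and tie-breaks are
this package's documented choices (the algorithm's uses elsewhere do
not pin them).

Clusters spanning ≥ 2 genomes become SOGs with per-genome copy counts;
a SOG is single-copy iff every represented genome holds exactly one
member. Filtering keeps SOGs missing at most 40% of the taxa by
default (boundary kept). Outgroup genes are attached after ingroup
clustering, each to the SOG holding its syntenic-ortholog partners
(most supporting pairs; ties by summed block OI, then smallest sog id);
outgroup membership never alters ingroup classification. Sequence
export writes one FASTA per SOG (`genome|gene` record names) for
downstream alignment and tree building, which are outside this
package's scope.

## Synteny depth and relative ploidy

The reference genome's chromosomes are tiled with windows of 50 genes
(gene ranks, not base pairs, so intergenic length variation cannot bias
depth; the last window may be short). A window's depth is the number
of blocks whose reference-side rank interval overlaps it — block-level
counting is robust to internal gene loss; a pair-counting mode is
provided since the counting unit is a design choice, with block-count
the default. Relative ploidy `p` is the modal depth over covered
(depth ≥ 1) windows, ties resolved toward the smaller depth with a
warning; `p = 0` only when nothing is covered, and sparse coverage
(< 50% of windows by default) attaches a warning. Comparing
`depth_ratio` in both directions before and after OI filtering
separates the two histories behind a 2:2 depth pattern: a shared WGD
collapses to 1:1 orthologous depth after filtering, lineage-specific
WGDs remain 2:2.

## Dot plots

Points are homologous pairs at cumulative gene-rank coordinates
(per-chromosome ranks offset by preceding chromosome sizes;
chromosomes ordered by descending gene count unless specified), colored
by block OI or pair Ks on a fixed low→cool / high→warm map; the Ks
scale is clipped at 3.0 by default so the tail of ancient duplications
does not flatten it. The figure adds the pair-weighted color histogram
and the two synteny-depth panels. SVG output uses a fixed hash salt
and carries no timestamps, so identical input yields byte-identical
files.

## The simulator

The generator emulates the validation design for the index: a shared
WGD followed, after a time lag `delta_t` (substitutions/site), by a
speciation into taxa A and B, with the four subgenomes A1, A2, B1, B2
treated as pseudo-species and an outgroup O; the species tree is

```
(((A1:0.2, B1:0.2):dT, (A2:0.2, B2:0.2):dT):0.2, O:dT+0.4):0.1
```

An ancestral genome of `n_genes` (default 500; 5 chromosomes) evolves
along each branch by Poisson-distributed event counts (rate × fold ×
branch length × gene count) applied in randomized order: gene loss,
segmental inversion and transposition (segment lengths geometric with
mean 5 genes), tandem duplication, and origination of novel genes.
All randomness flows from a single seeded generator, so a config
reproduces its history bit-for-bit. An alternative scenario
(speciation first, then an independent WGD per lineage) supports the
ploidy-pattern analyses.

Gene identity is tracked through every event via ancestor ids recorded
at the WGD node and at the speciation node, so each surviving A-vs-B
homolog pair is classified exactly by the node type of its most recent
common ancestor: speciation → true ortholog; the WGD itself → true
out-paralog; a small-scale duplication (before the WGD, or between WGD
and speciation) → a third class that, like pairs involving originated
genes, is excluded from the confusion counts — the benchmark scores
the separation of speciation- from WGD-derived pairs, which is what
the index claims to do.

Sequences are never evolved. Orthology-inference error is emulated
parametrically: each true ortholog pair is called with probability
`1 − fn(delta_t)` and each true out-paralog miscalled with probability
`fp(delta_t)`; the default tabulated model interpolates fp = fn from
0.15 at `delta_t ≤ 0.05` (the hidden-paralog regime of modern
orthology inference when a WGD barely predates speciation) to 0.01 at
`delta_t ≥ 0.5`, and both callables are user-overridable. Per-pair Ks
is the true divergence (twice the time to the MRCA) times
multiplicative gamma noise (shape 4, mean 1), giving realistic
overlapping Ks peaks for nearby events.

Collinear blocks are detected by deterministic anchor chaining: per
chromosome pair, pairs sorted by rank are appended to the open chain
with the smallest combined rank gap among those whose x-rank strictly
increases by ≤ 25, whose y-rank changes by ≤ 25, and whose direction
matches the chain; chains of ≥ 5 pairs become blocks. The 5-pair
minimum mirrors the block-length setting conventional for collinearity
tools; the gap of 25 is this package's choice.

Assembly/annotation degradation utilities support robustness studies:
`fragment_assembly` cuts chromosomes at random gene-rank breakpoints
until the gene-count N50 falls to a target fraction of the original;
`subsample_annotation` retains each gene with a fixed probability and
reports the removed genes so truth sets can be restricted.

### Calibration and scale

Base rearrangement rates (inversion 3.5e-4, transposition 1.75e-4 per
gene per unit branch length) are set so that at the heavy-rearrangement
condition (`fold = 1000`) the mean detected block size is ~10 genes at
the desk scale of 500 genes — the regime in which precision is hardest
to maintain. Loss (5e-5), duplication (2e-5) and origination (2e-5)
are plausible magnitudes for gene-order evolution at this scale. The
benchmark grid used by the tests and the acceptance script is
`delta_t ∈ {0.05, 0.1, 0.2, 0.5, 1}`, `fold = 1000`, 20 replicates per
condition at 500 genes: small enough to run in seconds, large enough
that condition medians are stable. Per-replicate seeds derive
deterministically from the master seed, so the whole table is
reproducible.

### What the generator does and does not emulate

It reproduces the structural signal the index relies on — collinear
blocks of the two age classes, their fragmentation under rearrangement,
biased visibility of old blocks (longer separating paths fragment
out-paralogous blocks more), co-orthologs from post-speciation
duplication, and an error-prone upstream orthology call. It does not
evolve sequences (Ks is a noisy function of true divergence, not of
substitutions), models orthology-inference errors as independent
per-pair coin flips rather than the spatially and family-correlated
errors of real inference, and uses a fixed five-taxon topology. Green
tests therefore show that the method behaves correctly when its
assumptions hold and degrade gracefully with rearrangement; they do
not certify performance on real genomes with correlated error
structure.

One measurable consequence of the independence assumption: with
~10-gene blocks and a 15% per-pair error rate (the `delta_t = 0.05`
condition), binomial scatter places roughly 8% of pair mass in the
[0.3, 0.7) OI band — the distribution is bimodal but not empty in the
band at that extreme, while conditions with `delta_t ≥ 0.1` stay below
5%. Real errors cluster within blocks, which sharpens polarization;
block-level precision is unaffected (filtered precision stays ≈ 1.0
at every condition).

## Numerical and degenerate-input conventions

Division-by-zero conventions: precision, recall and F1 are 0 when
their denominators vanish. Empty blocks, unknown dialects, cutoffs
outside [0, 1], negative Ks, non-positive MCL weights and
out-of-range fractions are hard errors; missing Ks values, missing
sequences at export and unattached outgroup genes are reported, not
fatal. Configurations whose loss rate would leave fewer than ~10
surviving genes are rejected with advice rather than producing
degenerate histories.
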