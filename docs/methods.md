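# Methods

`epicoord` reconstructs, as a reusable and tested pipeline, a
chromatin-coordination analysis for a paired two-condition design: an
epithelial and a mesenchymal sample profiled by ChIP-seq for a panel of
histone modifications, with matched expression data, functional
annotations, transcription-factor binding sites and a protein-interaction
network. This note describes the statistical procedures, their
assumptions, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Binned enrichments and scaled differences

Mapped tags are extended to 200 bp in their 3' direction (the expected
nucleosomal fragment) and counted into fixed 200-bp bins; a tag increments
*every* bin its extended interval overlaps, so an off-grid tag counts in
two bins. The raw enrichments (RE) of each mark's epithelial/mesenchymal
pair are normalized with median-of-ratios size factors: over bins where
both conditions have nonzero counts, each condition's factor is the
reciprocal of the median ratio of its count to the bin-wise geometric
mean. Scaled enrichments (SE) are REs times the factor, and the scaled
differential enrichment is

    SDE = MSE - ESE

per bin, so positive values are mesenchymal gains. Ratios are restricted
to doubly-nonzero bins (standard practice for count data; ratios at zero
counts are undefined or degenerate). Note the estimator needs informative
counts: at per-bin means near 1 the ratio distribution is so discrete that
the median collapses to 1 and library-size differences pass through
uncorrected.

## Gene segmentation and differential epigenetic profiles

Each gene is laid out on the fixed bin grid (bins are never shifted to the
TSS): a 3-bin TSS segment (the bin containing the strand-appropriate
transcription start plus one bin each side), a 25-bin promoter (PR)
immediately upstream, a 25-bin gene start (GS) immediately downstream, and
a whole-gene segment (WG) from the TSS reference bin to 5 bins past the
bin holding the termination site. Genes shorter than 1.2 kb cannot host
the minimal WG and are skipped with a warning; segments running off a
chromosome are clipped and flagged. For minus-strand genes the reference
bin holds the 5' cap base (txEnd - 1) and the layout mirrors so PR stays
transcriptionally upstream.

Within a segment, each mark's SDE is reduced to a **gain** (sum of
positive bins) and a **loss** (absolute sum of negative bins); gain - loss
always equals the plain SDE sum. Genes get 4 segments x marks x 2
directions features; enhancers are a single 11-bin segment. Each column
of the resulting matrix is scaled with

    z = 2 / (1 + exp(-2 x / u)) - 1,

u being the column's 95th percentile (linear-interpolation percentile).
The transform is approximately linear below u (z(u) = tanh 1 ≈ 0.762),
maps 0 to 0 and approaches 1 from below, putting every feature on a
common scale regardless of segment size or a mark's dynamic range. Scale
constants are persisted with the matrix so gene and enhancer matrices can
be rescaled reproducibly.

## Enhancer discovery

Putative enhancers derive from broad islands of the two core enhancer
marks, H3K4me1 and H3K27ac, called in each condition against the pan-H3
control. The island caller marks candidate bins whose count beats an
upper-tail test at p <= 0.05 given the library-scaled control expectation,
merges candidate runs separated by <= 600 bp, requires at least two
candidate bins per island (sustained enrichment — isolated outlier bins
never seed an island), and keeps islands at a BH-adjusted island-level
p <= 0.01. The count test is negative binomial with a method-of-moments
dispersion estimated from the track's bulk (bins at or below the 99th
percentile), degrading gracefully to Poisson when the data are not
over-dispersed; a pure Poisson test on over-dispersed data would flood
the genome with spurious single-bin islands. Externally produced island
BED files can be substituted for the built-in caller.

Each island is anchored on its maximally enriched bin (ties leftmost).
Anchors overlapping an H3K4me3 island in either condition are removed
(promoter-like), H3K4me1 anchors within 1 kb (bin-center distance) of an
H3K27ac anchor collapse onto the H3K27ac site, and the survivors extend
±1,000 bp into fixed 2,200-bp (11-bin) loci; anchors whose locus would
cross a chromosome edge are dropped so the length invariant is exact.

The six enhancer-associated marks (H3K4me1, H3K4me2, H3K27ac, H3K9ac,
H4K8ac, H3R17me2asym) are the default feature set; a correlation mode
instead selects every available mark whose per-locus summed SDE tracks a
core mark at Pearson r >= r_min.

## The extreme-value null and differential filtering

Each putative locus is summarized by its single largest scaled feature
(max over 6 marks x 2 directions). A Gaussian noise model is fitted to
the population of maxima: the location is the mode of a Gaussian-kernel
KDE (bandwidth 0.025, evaluated on a 2,001-point grid over [0, max]); the
spread is

    sigma^2 = sum_{x_i <= mu} (x_i - mu)^2 / (n_tail - 1)

over the left (sub-modal) tail only — the side uncontaminated by genuine
change. `n` in the denominator is the tail count; on a symmetric sample
this makes sigma an unbiased estimate of the full-sample SD (the
alternative full-sample denominator is exposed as an option). A locus is
*differential* when its upper-tail Gaussian probability is <= 0.05
(boundary retained); because the extreme value is already the maximum
over the enhancer-associated marks, this is identical to requiring a
significant change in at least one of them.

Two properties of this estimator matter in practice and are visible in
the tests:

- It needs a putative population dominated by non-differential loci, and
  in the low thousands: the fixed 0.025 bandwidth gives a noisy mode on a
  few hundred loci.
- Its calibration depends on the shape of the null maxima. Maxima of many
  near-independent features are right-skewed, and a mode-anchored,
  left-tail-scaled Gaussian is anti-conservative on skewed nulls. The
  95th-percentile column scaling rescues calibration when the
  non-differential bulk sits near its saturation region (the compressive
  part of z), which holds when differential loci are a small fraction of
  each column's values. Under the generator's defaults the realized
  false-call rate on no-effect loci is 2–6% at a nominal 5%.

Differential loci are assigned to genes whose cis-region they overlap:
each gene's cis-region runs from its TSS to the neighboring TSS on each
side, capped at 1 Mb per side (half-open intervals, multiple assignment
permitted — neighboring cis-regions intentionally overlap between
adjacent TSSs).

## Clustering and cluster scores

Scaled DEP matrices are clustered crisply. The default engine is a batch
self-organizing map on a 10x10 grid trained for 200 epochs with cosine
best-matching units and a Gaussian neighborhood annealed from half the
grid width to 0.5. Occupied map nodes are then agglomerated by single
linkage on codebook cosine distances; the cut height is chosen
automatically as the candidate maximizing the row-level mean silhouette,
with near-ties (within 0.05) resolved toward the finer partition so
sub-archetypes sharing part of their support are not absorbed into a
dominant split. Alternatives: k-medoids with cosine distance and
silhouette-selected k, and direct import of an external assignment file
so cluster solutions from other tools can be analyzed unchanged. All
engines yield crisp, exhaustive assignments with cluster ids dense from 1
in decreasing size.

Each enhancer cluster gets a **gain-loss score**: the mean of
(gain - loss) over members and enhancer-associated marks, computed on the
scaled matrix (consistent with what was clustered; a raw-value option
exists). Positive scores classify a cluster as gained/activated, ties and
negative scores as lost/repressed. Cluster scores are related to
expression by the Pearson correlation between scores and the mean
representative log2 fold-change of genes linked to each cluster through
its enhancers (>= 3 clusters with linked genes required). Per-gene
representative log2fc is the probe with the largest |log2fc| (a +/- tie
resolves to the positive value); percentile ranks are computed within the
full gene universe, a single-gene universe ranking 100 by convention.

## Functional similarity

Term enrichment is a two-sided Fisher exact test per term with
BH correction across terms; the fold (observed/expected) classifies a
significant term as enriched or depleted. The functional similarity score
between two gene sets thresholds both enrichment lists at q < 0.01 and
sums, over terms significant in both with concordant direction,
-log(p_A * p_B) (natural log; raw p enters the sum, q is only the gate).
E collects enriched-in-both terms, D depleted-in-both, FSS = E + D;
discordant terms contribute nothing. The sign is chosen so that larger
means more similar — a literal mode retaining the +log orientation is
available. The functional correlation matrix holds E and D separately for
every ordered cluster pair, columns in numeric cluster order and rows
ordered by Ward hierarchical clustering under the cosine metric.

## TFBS enrichment

Promoter windows are 5,400 bp: the TSS-containing bin extended by 13 bins
per side (clipped windows flagged). A locus hits a factor when >= 1 bp of
half-open overlap exists with any site — duplicated site records cannot
change the indicator. Per factor and cluster, a one-tailed (greater)
Fisher exact test contrasts cluster membership with hit status over all
loci of the same kind. The heat-map statistic is -log10 p standardized
within each row using the population SD (a sample SD would only rescale
each row); rows are restricted to the 10 strongest gain and 10 strongest
loss clusters by gain-loss score, and zero-variance rows are flagged and
zeroed.

## Network analysis

Interactions are kept at confidence >= 400 (inclusive, matching the
"medium confidence 0.400" convention of the source databases), duplicates
merged keeping the maximum, self-loops dropped. A seed gene list (either
genes below log2fc -2, strictly, or the members of selected clusters) is
expanded with every gene interacting with at least two seed genes; the
subnetwork is induced by seed plus mediators. Hubs are ranked by PageRank
on the undirected graph (damping 0.85, uniform teleport; scores sum to
1); modules come from Louvain modularity optimization at resolution 1.66
with a fixed seed for deterministic output. Note that at this resolution
very small graphs fragment (the resolution penalty gamma*k_i*k_j/2m
exceeds 1/m even inside a 6-clique), which is expected behavior of
resolution-parametrized modularity, not a defect.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
not raw sequencing. Defaults (one value per knob, chosen once):

| parameter | default | meaning |
|---|---|---|
| n_chroms x chrom_length | 2 x 50 Mb | enough bins (500k) for stable normalization and null fits |
| n_genes | 2,000 | one gene per 50-kb slot; slots prevent locus collisions |
| n_marks | 18 (+ pan-H3 control) | the profiled panel |
| n_enhancers | 300 | planted loci; differential ones stay <~5% of the putative population so column scaling stays anchored on the background bulk |
| n_gene_clusters | 4 | planted gene archetypes |
| effect_size | 25 tags/bin | planted per-bin elevation, well above background noise |
| background_rate | 10 tags/bin | informative counts for median-of-ratios |
| dispersion | 0.05 | mild NB over-dispersion, the realistic regime for pooled ChIP-seq bins |
| frac_null | 0.6 | fraction of genes/enhancers with no planted effect, matching the study-like ratio of unchanged loci |
| library_factor | 1.3 | mesenchymal/epithelial library-size ratio, so normalization is exercised |
| expression_effect | 3.0 | planted |log2fc| of regulated clusters |

Per-bin counts are negative binomial, independently per condition.
Gene archetypes add `effect_size` to three marks (drawn from the
non-enhancer panel, so gene-body effects never masquerade as enhancer
islands) over archetype-specific segments, in the mesenchymal condition
for gaining clusters and the epithelial one for losing clusters.
Enhancers are planted at reserved intergenic sites upstream of host genes
whose cluster direction matches (that is the planted coupling between
enhancer switching and expression); peaks are triangular over ±5 bins
with the anchor at the apex, present at 15% strength in the silent
condition and full strength in the active one, over the six
enhancer-associated marks in one of three subtype patterns. H3K4me3 is
elevated at every promoter in both conditions, and only there. Null
enhancers are recorded positions with no planted effect. Expression is
per-probe: gene truth plus Gaussian probe noise. Terms draw members
preferentially from their planted cluster; an activated and a repressed
TF get sites inside gain- and loss-planted enhancers respectively; the
PPI graph is dense planted blocks (among planted-cluster genes) over a
sparse background with confidences straddling the 400 cutoff. Each
artifact uses its own RNG stream (`seed + stream index`), so outputs are
bit-reproducible and files can be regenerated independently.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (mapability, duplicates,
GC bias), fragment-size variation, spatially correlated background
(domains), biological replicate variance (the design is one pooled pair
per mark), realistic enhancer-strength and gene-length distributions, and
annotation incompleteness. In particular the clean archetype structure
makes clustering recovery far easier than on real profiles.

## Numerical choices and degenerate inputs

- Percentiles are linear-interpolation (NumPy default).
- KDE grid: 2,001 points over [0, max]; mode = grid argmax
  (deterministic, resolution finer than the bandwidth).
- Tie-breaks: island anchors leftmost; probe representative prefers the
  positive value; zero gain-loss classifies as loss; cluster ids ordered
  by size then first appearance.
- Degenerate inputs raise informative errors: all-zero tracks cannot be
  normalized, identical extreme values cannot seed a null fit, a <2-row
  matrix cannot be clustered, an empty effective seed cannot induce a
  subnetwork. Zero-variance heat-map rows and clipped windows are flagged
  rather than fatal.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`, Louvain's seed); reruns of the pipeline
  with the same config produce byte-identical outputs, verified by
  content hash.

## Known limitations

- The mode-anchored, left-tail Gaussian null is anti-conservative when
  the non-differential maxima are right-skewed and unsaturated (see
  above); its calibration statement is tied to populations whose bulk
  sits near the scaling saturation.
- The island caller is a deliberately simple stand-in for dedicated broad
  peak callers; external island files are the recommended path for real
  data.
- Deterministic Louvain (fixed seed, sorted bookkeeping) reproduces
  itself, but module solutions from interactive tools will generally not
  be bit-identical.
- The orchestrated `run` command operates on simulated inputs; real-data
  analyses compose the stage functions and file readers directly.
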