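# Methods

## The screen model

The pipeline targets single-readout, plate-based RNAi screens with a
two-channel imaging endpoint: a DAPI channel counting all nuclei and a
phospho-histone-H3 (Ser10) channel counting mitotic cells. The per-image
mitotic index MI = pH3 / DAPI is treated as the phenotype; a gene's
phenotype is a robust summary of the MI over its duplexes and images. The
underlying assumptions are:

- cells in a well are exchangeable, so a Poisson model for per-image counts
  is adequate (counts ~ hundreds per image; a negative-binomial option
  covers overdispersed plates);
- systematic plate effects (seeding density, staining efficiency) act
  multiplicatively on counts and are shared by both channels, so
  plate-median scaling removes them without touching the MI signal;
- the large majority of genes are phenotypically null, which is what makes
  the median and MAD usable as location and scale of the null distribution.

## Pre-processing order and rationale

Filters run before normalization so corrupt records never influence plate
medians: (1) records whose DAPI *intensity* falls at or below the first
percentile of the intensity distribution are dropped — intensity, not
count, because a sparse or failed well shows up as a dim well even when
segmentation still reports objects; (2) records with more mitotic than
total cells (strictly greater) are dropped as physically inconsistent.
Both filters conserve records (kept + removed = input) and report what they
removed. When every intensity is tied (MAD zero) the percentile filter
removes nothing — a percentile cut on a constant column would otherwise
remove an arbitrary subset. Note the filters are idempotent with respect to
their computed threshold, not to re-estimation: re-running the percentile
filter on its own output with a freshly estimated percentile would chew
further into the distribution, which is why the cutoff is returned with the
result.

Each channel is then normalized per plate: `x / median(plate) *
median(all)`, with medians taken over sample wells only so that a strong
positive control cannot bias its plate. After this step every plate's
median equals the overall pre-normalization median to floating-point
accuracy; this invariant is tested at 1e-9 relative tolerance.

The MI is computed per record after normalization. A zero pH3 numerator is
replaced by a pseudocount (default 0.5, configurable; exclusion is the
alternative) so log2 MI is always defined. Records with zero DAPI are
flagged undefined rather than erroring. Genes are summarized by the median
over all surviving per-image MI values across their duplexes (mean
available); the median is the robust default and makes gene summaries
insensitive to one bad duplex. Finally z-scores are computed across the
screen as (x − median) / MAD with the normal-consistency constant 1.4826
(configurable, including 1.0); a per-plate z-score mode exists for screens
whose plate layout confounds genes with plates.

## Hit calling

On log2 of the summarized gene MI, hits satisfy |x − median| > k·MAD with
k = 2 by default; the boundary case (equality) is a non-hit. Low-MI and
high-MI groups follow the sign of x − median. A zero MAD raises an error
rather than calling everything or nothing — a screen where more than half
the genes share one value needs inspection. A per-duplex mode (hit if at
least 2 of 3 duplexes pass on the same side) is provided but off by
default, since calling operates on summarized values in the primary
workflow.

**False-call rate of the rule.** With f ≈ 13% of genes spiked at strong
effects, the spiked genes inflate the MAD of the pooled distribution only
modestly (the half-sample point of the mixture moves from 0.674σ to
≈ 0.79σ of the null scale, so 2·1.4826·MAD ≈ 2.35σ). Around 1.9% of null
genes therefore land beyond the threshold whatever the noise scale is —
the rule is scale-free, so more images or cells do not reduce this. On the
default synthetic conditions (714 genes, 41 + 50 spiked, ×0.2/×3 effects)
that yields a median sensitivity of 1.0 and a median false discovery rate
of ~0.12–0.13 over 20 seeds. This is a property of the median ± 2·MAD
selection under contamination, not of the implementation; the acceptance
suite reports it as measured.

Plate QC scores control wells as robust z against the plate's sample-well
log2 MI distribution (counts pooled over each well's images) and flags
plates whose positive/negative separation falls under a threshold (default
3 z-units); flagged plates are reported, never dropped silently.

## Image quantification

The imaging path is deliberately minimal, sized for screen images with
hundreds of well-separated nuclei. Background is a local median over a
square block (default 51 px, odd, at least 3) subtracted and clipped at
zero; the median is computed with a histogram-based rank filter on a
255-level quantization of the image, whose ≤1-level error is negligible
against spot amplitudes. Binarization is Otsu by default with a fixed
threshold available; objects are 8-connected components filtered by area
(default 20–2000 px²) and mean corrected intensity (default ≥ 10).
Touching nuclei are not split — no watershed — which is a stated
limitation: at screen densities the merge error is within the ±2 object
tolerance the tests assert, but the counter is not suitable for confluent
fields. Default thresholds were chosen on the synthetic fixtures; real
microscopes will need their own.

## Enrichment statistics

The hypergeometric upper tail P(X ≥ k) is summed from log-pmf values with
log-sum-exp, exact to ~1e-15 against rational enumeration on small
universes, and returns exactly 1.0 at or below the support minimum. Terms
annotating fewer than 3 universe genes (default) are not tested. The
two-list comparison builds, per term, the 2×2 table of annotated/not ×
list A/list B and applies the two-sided Fisher exact test; the reported
direction is the list with the higher annotated fraction. Both analyses
adjust p-values with Benjamini–Hochberg across tested terms. The default
universe for hit-group enrichment is the screened gene panel, not the
genome — a screen-restricted universe avoids library-composition bias;
any gene list can be passed as universe where genome-wide background is
wanted. Annotations are flat (gene, term) pairs: no ontology-graph
propagation is performed, so hierarchical annotations must be
pre-propagated upstream.

## Networks

Graphs are built by the first-neighbor rule: every interaction record with
a hit kinase at either end contributes its edge and partner node. Hit
kinases with no records are reported as unmapped, so mapped + unmapped =
hit-list size. Duplicate records for one unordered pair are merged keeping
the most informative relation class, precedence
substrate-and-interacting-phosphoprotein > interacting phosphoprotein >
substrate > interacting; conflicts are logged. The graph is undirected —
topology statistics (components, mean degree, clustering) are computed on
the undirected graph — while the kinase→substrate orientation of
substrate-class records is kept as an edge attribute for display. Both the
raw record count and the de-duplicated edge count are visible (table
length vs. graph edge count), covering either convention for reporting
interaction totals.

**Power-law fitting.** The degree-distribution exponent is estimated by
exact discrete maximum likelihood: maximizing `−n·ln ζ(γ, xmin) − γ·Σ ln k`
over the tail k ≥ xmin, with the Hurwitz zeta as normalizer. By default
xmin is chosen by scanning candidate cutoffs and minimizing the
Kolmogorov–Smirnov distance between the empirical tail and the fitted
model — the standard remedy for degree sequences that are power laws only
above a knee. For a clean power-law sample the scan settles on the minimum
degree and changes nothing (γ̂ ≈ 3.0 on ζ(3) samples); on
preferential-attachment graphs (asymptotic exponent 3, min degree m) it
skips the non-power-law head and lands at γ̂ ≈ 2.6–2.8 where a fixed
min-degree cutoff gives ≈ 2.5. The widely used continuous approximation
`1 + n / Σ ln(k/(xmin − ½))` is reported as a diagnostic only: at small
xmin it is severely biased (≈ 2.2 for a true exponent of 3 at xmin = 1).
The log–log histogram regression slope is reported as a second diagnostic
and never used for inference. All-equal degrees raise a fit error.

Modules are extracted two ways: ego networks (induced subgraph within a
hop radius of seed kinases; radius 0 gives the seed-induced subgraph,
disconnected seeds stay as isolates) and shared-neighbor search (all
hit-kinase pairs with at least `min_shared` common non-hit neighbors,
ranked by shared count, ties alphabetical). The latter operationalizes the
visual spotting of modules like two kinases jointly wired to a receptor
family; note that in dense graphs a pair of genuine hubs can legitimately
out-rank a planted 3-partner module, which is why recovery is reported as
a rate rather than asserted per graph.

## Synthetic data: what it emulates, what it does not

The screen generator reproduces the study conditions end to end: 714 genes
× 3 duplexes in 96-well plates (93 sample wells after one positive and two
negative control wells), 4 images per well, Poisson counts at 700 cells
per image, baseline MI 0.05, per-plate multiplicative log-normal effects
(sd 0.1) on cell counts — applied to counts, not MI, so plate
normalization has real work to do — DAPI intensity proportional to the
DAPI count with 5% log-normal noise so the intensity filter removes
genuinely sparse images, a ×4 positive control, and 41/50 spiked low/high
genes at ×0.2/×3. It does *not* emulate: off-target or seed-sequence
effects, duplex-to-duplex efficacy variation, edge-well spatial gradients,
cell-cycle dynamics, or optical artifacts beyond a smooth illumination
ramp. Passing recovery tests therefore demonstrates the statistical
machinery under the declared noise model, not robustness to the full
pathology of real screens.

The interactome generator uses a Barabási–Albert backbone (n = 2000,
m = 2 by default) for scale-free degree structure, draws each edge's
relation class from a configurable mix, and wires planted modules exactly
(class: interacting phosphoprotein). The annotation generator plants terms
that fully annotate a chosen subset plus background genes at a given rate.
All generators are pure functions of (config, seed); identical calls are
byte-identical.

## Numerical choices and degenerate inputs

- Quantiles: linear-interpolation empirical quantiles (NumPy default).
- MAD scale constant 1.4826 everywhere, configurable.
- Removal rule for the intensity filter: ≤ cutoff; tie-degenerate input
  (intensity MAD 0) removes nothing.
- Boundary ties at median ± k·MAD are non-hits (strict inequalities).
- Zero plate medians: the plate's records become NaN with a warning, never
  silently rescaled.
- Hypergeometric tail: log-space summation; k at or below the support
  minimum returns exactly 1.0.
- Power-law optimization: bounded scalar minimization of the negative
  log-likelihood on γ ∈ [1.01, 10].
- Pipeline problem sizes in tests and the acceptance script: 20 full-scale
  screens (8,856 records each), 10 interactomes of 2,000 proteins, 10
  image pairs of 512×512 px — sizes chosen to exercise full study scale
  while keeping a complete run in seconds to minutes.

## Known limitations

- No B-score/loess spatial correction or batch merging across screens.
- No nucleus splitting; image counts bias low in crowded fields.
- Flat annotations only; no GO-DAG semantics.
- The shared-neighbor module search scales quadratically in hit count —
  fine for tens of hits, not for thousands.
- The hit rule's false-call rate under heavy spiking is intrinsic (see
  above); if a calibrated FDR is needed, the z-scores support standard
  FDR procedures downstream.
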