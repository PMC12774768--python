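# Methods

## The positional coordinate system

The tissue model is a stack of unit-thickness cross-sections numbered
1..N along the proximal-distal axis, with section *s* centred at
z = *s* and spanning z ∈ (s − 0.5, s + 0.5).  Each section carries
concentric germ-layer rings — epiblast/ectoderm innermost, then
mesoderm, then endoderm — whose radii are half the per-layer
anterior-posterior diameters, r_layer = L_A-P^layer / 2.  Diameters may
be given directly or as an outermost diameter plus inter-layer ratios
(endoderm/mesoderm and mesoderm/ectoderm, both > 1 for a properly
nested model).  The bundled late-gastrula (E7.5) configuration uses
proximal-distal length 9, outer diameter 9 and both ratios 1.2, giving
r_End = 4.5, r_Mes = 3.75, r_Ect = 3.125.

A positional address is (stage, section, sector, layer) with
coordinate (R·cosθ, R·sinθ, s), where θ is the sector's nominal angle.
Orientation convention: posterior at θ = 0 (+x), anterior at θ = π
(−x), the right body side on +y; a config flag mirrors the x-axis.
R is a per-layer *placement radius* that defaults to the derived ring
radius but can be overridden — the bundled E7.5 config places the
epiblast ring at the published radius 3 rather than the derived 3.125,
so published address tables are reproduced exactly while new tissues
fall back to the derived value.

Each address owns an interior *region*: the layer's annulus at its
section, cut to a wedge of width 2π/#sectors centred on the nominal
angle.  Sector wedges are symmetric about their nominal angle, so a
ring's wedges partition the annulus; a midline sector (e.g. posterior)
straddles the midline, and the one printed boundary inequality of the
published position-8P model corresponds to one half of such a wedge.
The ectoderm ring needs an inner boundary that no inner layer provides;
by default the inter-layer ratio is continued one step inward
(r_Ect²/r_Mes), and it is configurable.  Degenerate on-axis pole
positions (the distal tip) get the full layer disc.  The half-oval
outer surface is used for rendering only, parameterized as an
axis-scaled hemisphere; no mapping arithmetic depends on it.

The *expanding-layer* variant models a layer that wraps progressively
around the structure (the nascent mesoderm at earlier stages): per
section, a partial annulus of angular extent f ∈ (0, 1] of the full
circle grows symmetrically from the posterior angle; extent 1
reproduces the full annulus.

The bundled E7.5 sector scheme — six epiblast sectors (P, R2, R1, A,
L1, L2 at multiples of π/3) on sections 2–9 plus one distal pole
position, and anterior/posterior mesoderm and endoderm sectors on
sections 2–9 — is a reconstruction that reproduces the published
81-position design and the published section-9 coordinates; it is fully
overridable through the geometry config (JSON/YAML).

## Zipcode derivation

Two routes, chosen by data regime:

* **Clustering route** (sparse references): positions are clustered by
  k-means over the full expression matrix, 25 seeded restarts per
  candidate k, and k chosen by minimum BIC under a spherical-Gaussian
  model with shared variance (−2·logL + (k·d + 1)·ln n).  Per domain,
  one-vs-rest differential genes are called by Welch's t-test on
  log-space values with linear-scale fold change 2^Δmean; defaults
  p < 0.05, fold change > 1.5, top 50 per domain ranked by p (ties by
  fold change, then gene label).  P-values are uncorrected by default,
  matching the thresholds as printed; a Benjamini-Hochberg flag is
  available.
* **PC-loading route** (richer references): the 6000 most variable
  genes (ties by label) are decomposed by PCA and the 50 highest- and
  50 lowest-loading genes of each selected component are pooled
  (components 1–4 or 1–5 in the motivating application).

Both routes are deterministic given the seed and inputs.

## Mapping

For each cell, Spearman's rank correlation (average-tie ranks) against
every reference position over the zipcode intersection (≥ 3 genes
required) gives the SRCC profile; positions with constant zipcode
vectors are recorded as missing and excluded.  Assignment then follows
the version-2 rule set:

1. the germ layer is fixed by the global argmax-SRCC position and the
   remaining ranked positions are drawn from that layer;
2. with relative gap ΔSRCC = (SRCC₁ − SRCC₂)/SRCC₁ > 0.1 (the
   high-confidence gate) the argmax wins unsmoothed;
3. otherwise the top-3 (top-5 when the top-3 are dispersed — at least
   two of the three pairwise section gaps above 3, or three distinct
   sectors with angular separation beyond π/2; both thresholds
   configurable) are merged into the consensus point
   P₀ = argmin Σ SRCCᵢ·dist(x, xᵢ), the SRCC-weighted geometric
   median, and the cell is assigned to the nearest reference position
   (ties by higher SRCC, then lower section);
4. an assignment landing more than 3 sections from the argmax position
   is overridden by the argmax.

The published account of the dispersion trigger gives one worked
example (three positions spanning sections 4–11) but no formula; the
two-of-three-pairs reading is the weakest rule consistent with that
example and is therefore the default.  The geometric median is solved
by Weiszfeld iteration from the weighted centroid (tolerance 1e-9,
≤ 500 iterations) with the Vardi-Zhang correction at anchor
coincidences.  Only positive-SRCC anchors participate (a negative
weight makes the objective unbounded); if none is positive the argmax
is returned with a warning.  A zero or negative top SRCC leaves the
gate ratio undefined, in which case smoothing is applied.  Version 1 —
retained for comparison — is the same pipeline with the layer rule,
dispersion fallback and section override disabled.

## Within-position placement

*Uniform fill* draws i.i.d. uniform points over the region volume
(area-weighted radius inversion; exact, no rejection).  *Gradient sort*
keeps the point multiset and reassigns cells so a supplied per-cell
value is monotone along x, y, z, the radial or the angular axis; the
sort is stable, so equal values leave the assignment unchanged.

The *Optimal Spatial Distribution* embeds the cells mapped to one
position: Euclidean distances over an input gene set (by default the
100 top PC-loading genes of the cells' own PCA, scored by
explained-variance-weighted absolute loading over up to 5 components)
are rescaled so the largest equals the region's maximum interior chord,
then coordinates minimize the raw stress Σᵢⱼ(‖xᵢ−xⱼ‖ − dᵢⱼ)² subject to
region membership.  The rescaled matrix (not the raw one) is the
stress target — the rescaling exists precisely to fit the distances
into the region.  The stress is non-convex, so the solver is
multi-start: a classical-MDS (Torgerson) initialization centred in the
region, a chord-aligned initialization that spreads cells along the
region's longest segment in leading-MDS order, and seeded uniform
restarts (10 starts total by default), each refined by projected
gradient descent with backtracking line search and per-iterate
cylindrical clamping (radius, wedge angle, z); the best in-region
stress is kept.  The maximum chord of an annular wedge is computed
analytically (the larger of the outer-corner chord, the radial span
and the cross-corner chord — a full diameter once the wedge spans
≥ π — combined in quadrature with the z-span).  Transcriptomically
identical cells are co-located at the region centroid and jittered by
1e-6 of the chord for rendering.  Stress is invariant to rigid motions
of the whole configuration, so tests compare stress values, never raw
coordinates.

## Lineage tracing

Populations are summarized by the arithmetic mean of their cells'
log2 expression over a stated gene set (typically the differential
genes of the stage pair, derived with the same test as the zipcodes).
Between adjacent stages, each population's candidate partners are its
minimum-distance partner plus any whose distance is within 10%
relative variation of that minimum ((d_max − d_min)/d_min < 0.10); an
edge is kept when the candidacy is mutual.  Evaluating mutuality on
candidate sets (not strict argmins) is what lets a parent keep both
children of a bifurcation; a strict mode restricts candidates to exact
argmins.  A zero minimum admits only exact ties (the limit of the
ratio rule).  Edge display weights are log2 of the distance, floored
at machine epsilon and flagged when floored.  Single cells are chained
by plain minimum distance with no mutuality or expansion.

## Annotation

A query cell inherits the label of the maximum-Pearson-correlation
resident cell at its inferred position, over the position's cell-type
differential genes (one-vs-rest, same test and thresholds as the
zipcodes).  All correlation is computed in log2 space, consistent with
the log2(FPKM + 1) pre-processing convention.  With a single resident
type no within-position contrast exists; the full gene set is used and
the result flagged.  Ties in the maximum correlation resolve toward
the more frequent resident type, then lexicographically.

## Verification metrics

For cells of known origin, a Gaussian kernel centred on each true
source coordinate (σ default 1 section length) defines the expected
per-address mapping mass; the observed assignment histogram is
compared to the summed expectation by Pearson correlation.  Exact
assignment is additionally scored by macro F1 over the labels present
in truth or predictions, and the SRCC profiles by one-vs-rest AUROC
per address (macro-averaged over addresses with both positive and
negative examples) — the per-address construction is one of several
consistent readings of the published protocol and is labelled as such.
The microscopy step that located pipetted cells in the original bench
protocol is replaced by the synthetic truth address as the kernel
centre.

## Synthetic data: what it emulates and what it does not

`make_reference` builds a domain-structured atlas on any geometry:
positions fall into spatially contiguous proximal-distal bands
(domains), each with a block of planted marker genes elevated by a
fixed log2 effect; rows add i.i.d. Gaussian noise.  Defaults — 200
genes, 6 domains × 12 markers, effect 2.0 (4-fold), reference noise
sd 0.8, marker baseline 2.0 — are sized so the planted rank structure,
not baseline spread, determines inter-position correlations: marker
genes share a common baseline, and the noise-to-effect ratio keeps
same-domain position pairs well below the ΔSRCC gate while leaving
the markers trivially recoverable by the differential test.
`make_cells` draws cells as source rows plus Gaussian log-space noise
(default sd 0.5) with optional Bernoulli dropout.  `make_lineage_series`
grows a branching tree whose child profiles displace their parent by
orthogonal steps of norm 5 (noise sd 0.4, 30 cells per population);
these defaults keep the population-profile distance error well under
the 10% variation window, so the window's behaviour reflects the rule
rather than sampling noise.  Noise is additive Gaussian in log space
(an optional count-level route can be emulated by exponentiating);
count-level negative-binomial sampling, batch effects, doublets and
realistic dropout-expression dependence are *not* modelled, so passing
tests demonstrate algorithmic correctness and calibrated behaviour
under the stated noise model, not performance on real scRNA-seq.

## Problem sizes used in the test and acceptance suites

Property suites run on the bundled 81-position model or a compact
40-position variant: 200 noiseless cells for exact-recovery checks, 50
random triples for the smoothing oracle, 20 seeded replicates each for
the embedding (24 cells × 30 genes, 4 optimizer restarts), lineage
recovery and marker-recovery suites.  These sizes were chosen as the
smallest at which the tested properties are statistically unambiguous.

## Known limitations

* The geometry covers annular/wedge topologies (and discs at poles);
  arbitrary meshes and image-registered anatomy are out of scope.
* Mapping is a point assignment, not a posterior over positions; the
  SRCC profile is exposed for callers who want soft assignments.
* The constrained stress minimization is non-convex; with few restarts
  the embedding can land in local minima (mirror configurations are
  inherently unidentifiable — only distances are constrained).
* The published sector schemes for stages other than the bundled
  reconstruction must be supplied by the user as geometry configs.
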