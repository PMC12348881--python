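# Methods

`nichequant` quantifies 3D scaffold co-cultures of leukemic B cells,
autologous T cells and bone marrow stromal cells (BMSCs) from multi-channel
confocal z-stacks, and infers candidate tumor-stroma communication channels
from differential-expression (DE) gene lists cross-referenced against a
curated protein-protein interaction (PPI) table. This note records the
models, the parameters that matter, and the design choices made where more
than one reasonable implementation existed.

## Scaffold segmentation

The stromal scaffold is segmented from the combined structural channels
(phalloidin / CD90 / nuclear stain) by a fixed pipeline:

1. voxelwise maximum of per-channel min-max-rescaled volumes;
2. 3D median filter, cubic window of radius 1 voxel in x, y and z;
3. contrast enhancement: linear rescale to 8 bit saturating 0.35% of voxels
   at each intensity tail (the common Fiji "enhance contrast" behavior);
4. fixed threshold, foreground iff value > T with T = 16 on the 8-bit scale
   (strict comparison; the threshold is applied after 8-bit conversion);
5. morphological closing (ball radius 1) followed by removal of 26-connected
   components below `min_object_voxels` (default 64; a component of exactly
   the minimum size is kept).

All neighborhood filters use reflect padding so thin stacks do not darken at
the borders. The 3D variance filter (population variance over the cubic
window, used to texture-enhance nuclei) is computed as `E[x^2] - E[x]^2` on a
mean-shifted copy to limit cancellation error, and clipped at zero.

A caveat worth knowing: a radius-1 median filter erodes structures whose
cross-section is only a few voxels wide. The synthetic filaments are
therefore rendered ~8 voxels thick (about 1.3 nucleus diameters, a realistic
caliber for a spread stromal process); on such structures the pipeline
recovers the planted mask with Jaccard ≈ 0.97.

## Nuclei instance segmentation

The quantification stages consume an integer label volume and do not care
where it came from; externally produced masks (e.g. from a trained
learning-based segmenter) are read with `read_labels`, which relabels to
contiguous ids and reports the mapping. The built-in segmenter is a
deterministic classical pipeline honoring the expected nucleus diameter
(default 6.2 voxels):

Gaussian smoothing (sigma 1 voxel) → foreground threshold (Otsu by default)
→ seed detection as local maxima of the smoothed intensity with minimum
separation 0.7 × diameter → seeded watershed → size filter keeping instances
between 20% and 500% of the sphere volume implied by the diameter.

Seeding and flooding operate on the smoothed *intensity* rather than on the
Euclidean distance transform of the foreground mask. For blob-like nuclei
the two are equivalent when nuclei are isolated, but when two nuclei touch,
the thresholded silhouette merges into one convex-ish blob whose distance
transform can carry a single maximum, while the intensity field still has
one maximum per nucleus; the intensity landscape therefore splits touching
pairs reliably. A `watershed_on="distance"` option retains the classic
distance-transform variant. Seed ties are resolved deterministically
(larger landscape value first, then array order); repeated runs are
bit-identical.

On synthetic stacks at the default signal-to-noise ratio the segmenter
recovers planted cell counts within ±2% and matches ≥98% of planted
centroids within 2 voxels.

## Marker phenotyping

Per mask and marker, the mean voxel intensity is computed; within each stack
the mask means of a marker are divided by their sum (so scaled values sum to
one) and natural-log transformed. Scaling is per stack, matching the
per-z-stack acquisition: any uniform linear gain applied to a stack cancels
exactly, which is verified by a property test. The log base is irrelevant to
percentile thresholds (monotone) and is fixed to e. Zero means are replaced
by half the smallest positive scaled value of that stack and marker before
the log; a marker that is zero on every mask of a stack yields undefined
(NaN) values and those cells classify as negative.

Norm-log distributions are pooled across the stacks of an experiment and
percentile thresholds are taken with the linear-interpolation definition
(numpy's default): 40th percentile for CD19, 95th for CD3. The asymmetry
mirrors the skewed mask population of the imaged co-culture: the nuclear
stain segments *every* nucleus — dominated by malignant B cells, with rare
T cells and a substantial marker-negative remainder (stromal and other
mononuclear nuclei) — so the 40th/95th percentiles fall into the gaps of the
bimodal CD19/CD3 distributions when B cells make up ~60% and T cells ~5% of
masks. Positivity is strict (value > threshold; ties are negative); each
mask gets exactly one class among CD19pos, CD3pos, double_pos, negative.

An important structural property of percentile thresholds: the fraction of
masks classified positive is pinned near (100 − p)% regardless of the true
composition. Fixed 40/95 percentiles are therefore only accurate when the
composition is near 60%/5%; the generator's defaults are set to exactly that
regime, and the thresholds' percentiles are configurable for other data.

## Co-localization

Double-positive masks are always co-localized. In the default
`double_pos_or_adjacent` mode (the quantification used for the imaging
figures), every CD19+ mask whose label region lies within one voxel of a
CD3+ mask region — Chebyshev distance ≤ 2 between voxel sets, i.e. regions
touching after dilating one by a 3×3×3 element — is flagged together with
its partner. The strict `double_pos_only` mode matches the narrower
methods-text definition; the adjacent mode is always a superset.

## Apoptosis

Per stack, the apoptotic fraction is |CD19+ ∧ caspase-3+| / |CD19+|; stacks
with no CD19+ cells are excluded with a warning. Condition means are
unweighted across the 3-4 stacks of a condition and reported as a ratio to a
control condition (defined as 0 when both means are zero). Caspase
positivity was counted manually in the original workflow, so the automated
rule is a package choice: by default the pooled CASP3 norm-log values are
split at the Otsu point, accepted only if the two modes are ≥ 0.7 apart on
the log scale (≈ two-fold intensity); unimodal data yields no positives.
This prevalence-free rule recovers planted apoptotic fractions of 0.1-0.5
exactly, which a fixed percentile rule cannot (it would pin the positive
fraction near its percentile). A percentile rule remains available via
`CaspaseRule(method="percentile")`.

## Crosstalk inference

Inputs: a PPI edge table (HIPPIE v2.3 native tab dialect, with gene symbols
extracted from the uniprot-style `SYMBOL_HUMAN` identifier columns, or a
generic 3-column TSV), the core-vs-periphery B-cell DE table, and the
per-cluster BMSC DE table. Edges are canonicalized (uppercase, unordered
pairs collapsed keeping maximum confidence, self-edges preserved); no
confidence cutoff is applied by default (`min_confidence = 0`).

A B-cell gene is "DE" iff adjusted p < 0.05. A BMSC gene qualifies iff it is
DE in at least one cluster contrast *and* expressed in ≥ 10% of cells in at
least one cluster (inclusive boundary); the qualifying clusters are carried
on the record. Each edge is then classified: `B_BMSC` when one partner is a
B-cell DE gene and the other a qualifying BMSC gene (a gene present in both
sets produces one record per orientation, flagged `dual_membership`);
`B_B` when both partners are B-cell DE genes; `self_ligand` for self-edges
qualifying on either side. The methods-strict subset (B_BMSC only) is
selectable with `b_bmsc_only=True`. Output order is deterministic (class,
then gene pair). Symbol matching is exact after uppercasing — no alias or
ortholog resolution.

Condition-exclusive cluster detection tallies, per cluster, the cells from
each experimental condition; exclusivity is the largest per-condition share
and clusters at ≥ 0.95 are flagged with their dominant condition — the
signature of a stromal state arising only after tumor contact.

## Synthetic data generator

The generator emulates the statistical structure every downstream stage
assumes, so the full pipeline is testable without any deposited data.

* **Nuclei** are Gaussian blobs whose full width at half maximum equals the
  nominal diameter (6.2 voxels); labels are spheres of radius d/2 around
  each center (overlaps resolved by nearest center). Coordinates are
  0-based (z, y, x), voxels isotropic.
* **Composition** (defaults): 120 B cells, 10 T cells and 70 marker-negative
  nuclei per stack — B = 60% and T = 5% of masks, the skewed regime the
  asymmetric 40/95 thresholds are designed for. The implied lymphocyte B:T
  ratio (12:1) is at the top of, and slightly above, the ~10:1 seeding ratio
  of the co-culture; the composition of *detected masks* is what matters for
  threshold placement.
* **Placement** by rejection sampling: minimum center distance 1.2 × d
  within the population; non-partner B-T pairs are kept ≥ d + 5 voxels apart
  so that planted adjacency is unambiguous. A fraction `frac_coloc`
  (default 0.6) of T cells is placed at center distance d + 1 from a B cell
  and nudged until the rasterized regions sit within a 1-voxel surface gap;
  pairs are recorded mutually in the ground truth. Infeasible requests raise
  a `PackingError` naming the approximately achievable maximum.
* **Markers**: CD19 on B cells, CD3 on T cells, caspase-3 on the planted
  apoptotic fraction of B cells (`frac_apoptotic_b`, default 0.1), CD90 on a
  connected random filament network (never labeled as a cell). Signal
  amplitude is `marker_snr` × background (defaults 8 and 100 counts on the
  16-bit scale — free parameters, as real acquisitions vary); a
  `bleed_through` fraction (default 0.05) of CD19/CD3 leaks into the other
  channel; noise is Poisson by default (Gaussian and noise-free available).
* **Omics bundles**: gene symbols are partitioned into disjoint roles
  (B-cell DE, qualifying BMSC, significant-but-under-10%-expressed BMSC,
  null); planted edges cycle through the three interaction classes, and
  decoy edges are built so exact cross-referencing must reject them (no DE
  partner; stromal partner under 10% everywhere; self-edges of
  non-qualifying genes).

Identical parameters (including the seed) give byte-identical outputs.

What the generator does *not* emulate: optics (no point-spread function or
anisotropy), autofluorescence, nucleus shape/texture variation, per-cell
marker intensity variation beyond shot noise, segmentation-grade stromal
nuclei crowding, or realistic single-cell count matrices (only DE summary
tables). Passing recovery tests therefore demonstrates the correctness of
the quantification logic under the stated statistical structure, not
robustness to every artifact of real confocal data — for real data the
external-mask route and the configurable percentiles are the intended entry
points.

## Problem sizes and numerical choices

Tests and the acceptance script run on synthetic stacks of 64×128×128
voxels with 200 cells (segmentation recovery additionally on 128×256×256
with 100 cells), 3-4 stacks per condition and 50 toy omics bundles — sizes
at which every planted structure is comfortably resolved. Degenerate inputs
are defined, not errors: constant volumes enhance to all-zero 8-bit,
no-foreground volumes segment to empty label volumes, zero-signal markers
classify as negative. All component operations use 26-connectivity;
thresholds and classification comparisons are strict everywhere, so ties
fall to background/negative deterministically.
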