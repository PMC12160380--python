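# Methods

This note documents the models and procedures implemented in
`pelletmorph`, the defaults they use, and what the synthetic-data
generators do and do not emulate.

## 2D segmentation

The segmentation operates on the red channel, where fungal hyphae contrast
well against a dark background and most impurities are weak. The stages
and their rationale:

1. **Opening-by-reconstruction** — erosion with a disk of radius
   `open_se_px` (default 10 px) followed by morphological reconstruction by
   dilation under the original image. This removes bright objects smaller
   than the disk while, unlike a plain opening, exactly preserving the
   contours of surviving structures. **Closing-by-reconstruction** (dilation
   with a disk of radius `close_se_px`, default 5 px, then reconstruction
   by erosion) fills dark holes of that scale. Reconstruction is
   8-connected, the common 2D default. The structuring element is a disk
   and the parameter is its radius; both are exposed in the API.
2. **Markers and mask** — markers are the regional grey-level maxima
   (8-connected plateaus with no brighter neighbour) of the filtered image,
   restricted to the pellet mask. The mask is obtained by thresholding;
   the default operator is Otsu's method, with a quantile mode available.
   Otsu was chosen because a quantile of the non-zero intensities is biased
   by the (unknown) pellet area fraction, whereas the bimodal
   background/pellet histogram of these images is exactly Otsu's use case.
3. **Watershed** — the Euclidean distance transform of the mask is negated
   and flooded from the marker components. Every masked pixel is assigned
   to a basin (k markers → k labels); ridge pixels are resolved by the
   flooding order of the priority queue, which is deterministic for fixed
   input.
4. **Post-filter** — labels touching any image border are removed, then
   labels with area-equivalent diameter outside 100–3000 µm (defaults)
   are removed; smaller objects are unlikely to be pellets, larger ones
   unlikely to be single pellets.

Each replicate flask is imaged twice and the two record sets are pooled
under their sub-sample ids (`run_replicate`); running the deterministic
algorithm twice on one image would be a no-op, so the two passes are
interpreted as two aliquots. Pellets that defeat the automatic pipeline
can be supplied as `source="manual"` rows in the records CSV; no
interactive tooling is provided.

## Population statistics

- **Median / IQR.** The median represents a population robustly across
  differently shaped unimodal distributions; the IQR (75th − 25th
  percentile) measures intra-flask heterogeneity. Percentiles use linear
  interpolation between order statistics.
- **Exclusion rule.** Populations with fewer than 30 analysed pellets are
  flagged as poorly grown and excluded from population characteristics.
- **q0 histograms and OVL.** Number-density histograms are computed on a
  fixed grid of 80 half-open classes ([0, 50), …, [3950, 4000) µm).
  Diameters ≥ 4000 µm cannot occur downstream of the 3000 µm filter but
  manual records might exceed it; they are rejected with a logged count.
  The overlap coefficient of two normalised histograms,
  OVL = Σ min(f_A, f_B), is 0 for disjoint and 1 for identical
  distributions and is invariant to population size at fixed shape. Any
  replicate pair involving a population with fewer than 30 pellets scores
  0 — the population-validity reading of the exclusion rule. Replicate
  variation is the mean over off-diagonal pairs.
- **Modality.** Histogram plotting may use any bin width, but the OVL grid
  is fixed at 50 µm. The unimodal/multimodal call smooths the q0 density
  with a 3-bin moving average and counts peaks with prominence above 10%
  of the smoothed maximum; two or more peaks flag multimodality. This
  operationalises what is otherwise a visual judgement, so it is reported
  as a flag and never silently enforced.

## Regression

Each shake-flask replicate enters as an independent observation (a
deliberate simplification that ignores intra-flask pseudo-replication).
Rows failing the 30-pellet rule or flagged multimodal are excluded.
Pellet diameter, spore concentration and shaking frequency are
ln-transformed (diameters are right-skewed; the transforms linearise the
relationships and even the residual spread); talc stays on its natural
scale and baffling is a 0/1 indicator.

The fit is ordinary least squares with t-based two-sided p values and
adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1). A constant response has
zero total sum of squares; R² is defined as 0 there. Diagnostics are
emitted as data: residual-vs-fitted pairs, QQ pairs, a heteroscedasticity
score (Pearson correlation of |residual| with fitted value — a numeric
stand-in for the visual funnel-shape check) and a probability-plot
correlation as the normality statistic; thresholds are reported, never
auto-enforced. VIF_j = 1/(1 − R²_j) from regressing predictor j on the
others (with intercept); values above 10 flag multicollinearity, perfect
collinearity is reported as infinite. Backward elimination removes the
largest-p predictor above α = 0.05, refits, and repeats, keeping a trace.

The reduced two-predictor model back-transforms to
PD = exp(b0 + bA·ln A + bT·T) with defaults (15.863, −1.7769, −0.10856).
Predictions outside 150–1200 µm are flagged: agreement between predicted
and observed diameters degrades above ~1200 µm.

## 3D internal architecture

Volumes are labelled voxel grids (0 void, 1 hyphae, 2 spore, 3 talc) with
isotropic voxel size. "Solid" means hyphae + talc by default; whether
spores count as solid is configurable. Embedded talc is deliberately not
separated from hyphae — it contributes to the density relevant for
diffusion limitation — and a talc-inclusion flag travels with skeleton
metrics, which may be slightly overestimated under high talc.

- **Mass centre**: unweighted centroid of solid voxels (the volumes are
  binarized structures; there are no grey values to weight by).
- **Radial profile**: solid fraction in an inner sphere of 50 µm and
  successive 25 µm shells about the mass centre, extending to the furthest
  solid voxel; voxels are binned by their centre coordinate, so the
  shell-wise solid counts sum exactly to the total solid count. Across a
  batch, profiles are aggregated as per-shell mean ± SD over pellets.
- **Spore cores**: DBSCAN over spore-voxel coordinates. The neighbourhood
  radius eps defaults to 4× the voxel size (four nearest-neighbour
  spacings inside a dense core) and should be reviewed per dataset; it
  must stay below the core separation. `min_samples` defaults to 10;
  clusters with fewer than 100 member spores are counted as noise, so
  every reported core has ≥ 100 spores.
- **Classes**: one core → I, several → II. The fusion flag III is a
  heuristic (fusion is, strictly, a developmental-history statement): a
  pellet is flagged when ≥ 2 cores are found and the *core-spread ratio*
  — minimum pairwise core distance divided by the 90th-percentile radial
  extent of the solid — exceeds 0.85. In a multi-core pellet the cores sit
  inside one common envelope (ratio ≲ 0.75 under the growth model below);
  in a fusion of mature pellets each core carries its own envelope (ratio
  ≳ 0.9). A max/median radial-extent asymmetry score is computed and
  reported as evidence but is not used for the decision: for sparse
  hyphal structures it tracks the radial density profile rather than
  shape, and it fails to separate the classes. Pellets whose mass centre
  is solid-dense (fraction ≳ 0.2) are consistent with a single central
  core, sparse centres (< 0.1) with multiple off-centre cores; this
  consistency note travels in the evidence bundle. No spore cluster →
  unclassifiable, reported as an error.
- **Skeletons**: a geometric graph input is measured exactly (edge lengths,
  degree-1 tips, degree-≥3 branch points; "branches" here means branch
  points). Voxel input is thinned to a medial axis, skeleton voxels are
  linked to 26-neighbours, each component is reduced to its Euclidean
  minimum spanning tree (removing chord edges and, rarely, true cycles),
  and leaf spurs shorter than 3 voxels are pruned before counting. On
  synthetic pellets this recovers total length within ~6% and tip counts
  within ~10%; digitization of oblique lines biases length slightly
  upward.
- The module assumes one pellet per volume; multi-component solids are
  flagged (`n_solid_components`) rather than re-segmented — cropping of
  multi-pellet holders is upstream of this package.

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested.

- **Diameter populations** are lognormal mixtures: a component with median
  m and spread s draws m·exp(s·Z). Lognormal matches the right-skew of
  observed diameter distributions and the ln-transform used for modelling.
  Default spread 0.25 (a typical unimodal flask); multimodal populations
  use several well-separated components.
- **Micrographs** render pellets as radially shaded discs (centre 255,
  edge 100 on a background of 8 with σ = 2 Gaussian noise) with a
  low-amplitude sinusoidal boundary roughness (default 0.03) so marker
  detection is non-trivially exercised; the roughness amplitude is a free
  knob, not calibrated to real boundary texture ("hairy" peripheries).
  Requested fractions of touching pairs (centres at 95% of the radius sum)
  and border-clipped pellets are realised during shelf packing; noise
  speckles are strictly smaller than the opening element. The study runner
  calibrates pixel size per condition (median diameter / 40 px, clamped to
  2.5–12 µm/px), as one would choose magnification at the microscope.
- **3D pellets** grow hyphae from each spore core by discrete off-lattice
  segments (default 5 µm) with per-step branching probability (0.08),
  radial bias (0.6) and directional noise, from 12 initial tips per core,
  for 40 steps. Growth into another core's territory terminates the tip,
  reproducing the observation that growth towards other spore cores is
  reduced or absent — this is also what empties the mass centre of
  multi-core pellets and produces the negative correlation between core
  count and central solid fraction. Cores are ≥ 100 spores (default 150)
  in blobs of 12 µm radius; talc is sprinkled into void voxels inside the
  occupied sphere at the requested solid fraction. Fusion constructs
  (Class III) are two mature single-core pellets grown without mutual
  inhibition at 1.45 nominal radii separation. The geometric skeleton is
  recorded before voxelization, so ground truth is exact. Hyphae are
  rasterized at single-voxel calibre; consequently synthetic solid
  fractions at the centre (~0.01) are far below the ~0.2 of real
  single-core pellets, whose hyphae are several µm thick. Tests on these
  volumes therefore validate geometry recovery and orderings, not absolute
  density levels.
- **Regression tables** draw ln(median ED) from the prediction equation
  plus Normal(0, noise_sd_ln) noise; default noise 0.1 ln-units (≈10%
  replicate variation). Optional spore and baffle terms (default 0) allow
  full-model studies.

What passing tests show, and what they do not: the synthetic scenes have
no uneven illumination, no out-of-focus blur, no dispersed mycelium, no
overlap of more than two pellets, and simplified optics; the 3D volumes
have no reconstruction artefacts and thin hyphae. Results on this data
establish the correctness of the algorithms, not instrument-level accuracy
on real micrographs or tomograms.

## Numerical and design choices

- All randomness flows through explicit `numpy.random.Generator` seeds; a
  fixed seed reproduces images, volumes and tables bit-identically. Study
  runs derive per-sample streams from one root seed.
- Test and acceptance problem sizes (50 scenes × 20 pellets at 10 µm/px;
  500–1000 regression repetitions at n = 24; 50 volumes at 2 µm voxels
  with 10 growth steps for core-recovery checks) were chosen so the whole
  suite runs in a few minutes on one CPU while keeping Monte-Carlo
  standard errors below about one percentage point.
- Ties in the watershed are resolved by deterministic flooding order;
  degenerate inputs (empty images, constant images, empty label grids,
  empty volumes) return empty results or raise typed errors as documented
  on each function.
- The geometric-fidelity check for voxel skeletons uses a sparse,
  well-separated test pellet (10 µm segments, branch probability 0.03,
  8 tips) so that digitization, not branch merging, dominates the
  comparison.

## Known limitations

- The fusion (Class III) heuristic is calibrated on the synthetic growth
  model; on real tomograms the 0.85 core-spread threshold should be
  reviewed against manually classified examples.
- The OVL zero rule reads "fewer than 30 data points" as a property of
  each population in the pair; an alternative reading (30 points in the
  overlap region) would score sparse-overlap pairs differently.
- Replicates are modelled as independent observations in the regression;
  a mixed-effects treatment is out of scope.
- Skeleton metrics on voxel input inherit the biases of thinning +
  spanning-tree reduction (slight length overestimation on oblique lines,
  cycle breaking); the geometric-graph route is exact and preferred when
  ground truth graphs exist.
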