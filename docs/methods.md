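# Methods

## The problem

Immunofluorescent array tomography (IF-AT) images ribbons of ultrathin
(70 nm) resin sections at ~0.1 µm lateral pixel pitch, with one grayscale
stack per antibody channel (here: synapsin, PSD-95, VGluT1, VGluT2, GAD,
gephyrin, glutamine synthetase (GS), DAPI).  A synapse appears as a small
cluster of *puncta*: presynaptic markers colocalized with each other,
juxtaposed against a postsynaptic punctum, optionally with an astrocytic
GS punctum beside the pair ("tripartite" synapse).  `synquery` detects and
quantifies synapses of user-declared types in such volumes, without
training data: the user writes a *query* — the required markers, each
marker's subclass (pre/post/astro), its minimum lateral footprint
(default 2 px × 2 px = 0.2 µm × 0.2 µm) and its minimum span in
consecutive sections — and the pipeline turns the query into a per-voxel
probability map, thresholds it, and reports densities per µm³ of neuropil.

## Probability model

Each channel's background is modeled as a Gaussian whose location and
scale are estimated from the data — per section by default, since staining
efficiency varies between sections, and robustly (median and scaled MAD)
so the sparse bright foreground does not inflate the scale (plain moments
and whole-volume scope are selectable).  Foreground probability is
p = Φ((I − µ)/σ): monotone in intensity, bounded in [0, 1], and exactly
0.5 on average over background voxels.  With σ = 0 the rule degenerates to
a hard threshold p = 1[I > µ].

## Query evaluation

Three operators compose a query map; each maps [0,1] volumes to [0,1]
volumes and is monotone in its inputs:

1. **Punctum evidence.**  Lateral: the joint probability that the
   marker's whole minimum footprint is foreground — the product of the
   per-pixel foreground probabilities over the `min_xy` window (border
   windows edge-replicated).  The product, not the arithmetic window mean,
   is used because calibrated background probabilities are uniform on
   [0,1]: four independent background pixels *average* above 0.9 with
   probability ~10⁻³ — enough to scatter false puncta in proportion to
   imaged volume — while their product exceeds 0.9 only ~5·10⁻⁶ of the
   time.  (The arithmetic mean is available via
   `QueryParams(lateral_mode="mean")` for comparison.)  Axial: for a span
   requirement of *m* sections, the evidence at depth z is the maximum
   over the windows of *m* consecutive sections containing z of the
   product of the windowed per-section values.
2. **Within-subclass colocalization.**  Markers of one subclass must
   occupy the same 3-D space; each punctum map is max-dilated laterally by
   `r_coloc` (default 1 px) before the voxelwise product, so puncta that
   share only a border still colocalize.
3. **Across-subclass adjacency.**  q = pre · maxN(post) · maxN(astro),
   where maxN is the maximum over ±`a_xy` px laterally and ±`a_z` sections
   (defaults 2 px, 1 section; lateral and axial scales are separate
   because the grid is anisotropic).  Zero offset is allowed — juxtaposed
   puncta may share a small proportion of pixels.

Adding a marker or raising any span requirement multiplies by additional
values ≤ 1 (or maximizes products over fewer windows), so requirements are
anti-monotone: they can never raise a voxel's probability or the
downstream detection count.

The standard ten-query catalog covers glutamatergic (overall, VGluT1,
VGluT2, VGluT1/VGluT2) and GABAergic synapses, each bipartite and
tripartite.  Two markers carry a two-section span floor regardless of the
query's span setting: VGluT2, whose antibody produces abundant
single-section speckle background, and GS, because peripheral astrocytic
processes are extended structures and a single-section GS requirement
would let isolated background sections fake astrocytic contacts.

## Detection

Query maps are thresholded at 0.9 (configurable) and supra-threshold
voxels grouped into 26-connected 3-D components, one detection per
component.  At realistic densities two synapses' supra-threshold regions
can touch; such components are split by a watershed on the per-section
2-D Euclidean distance transform, seeded by connected plateaus of its
local maxima (a 3-D transform is capped by the stack faces — the stack is
only ~2 µm deep — and loses the lateral structure).  Components with one
seed are identical to plain labeling; splitting is on by default and can
be disabled.  Centroids are reported in pixels and voxel-center µm;
ordering is deterministic by centroid.

Size classes use query subtraction, not per-detection measurement: the
query is run at span requirements 1, 2 and 3, giving counts N₁ ≥ N₂ ≥ N₃,
and small = N₁−N₂, medium = N₂−N₃, large = N₃, all = N₁ — so the classes
sum exactly.  The same subtraction over a single channel's punctum maps
gives single-marker punctum densities, and varying only the postsynaptic
marker's span floor gives the distribution of postsynaptic punctum sizes
among detected synapses.

## Neuropil volume

Densities are per µm³ of neuropil: total imaged volume minus DAPI-stained
nuclei.  The DAPI channel is converted to foreground probability and
thresholded at 0.6; the binary map is cleaned per section by opening and
closing with a 2 px disk and hole filling, then 3-D components under 200
voxels are removed.  Opening precedes closing because at t = 0.6 roughly
40% of pure-background pixels pass (p is uniform under the background
model); opening erases that salt noise while solid nuclei survive.  The
mask is invariant to uniform intensity offsets (the background is
re-estimated).  An exactly constant DAPI channel is degenerate: a positive
constant is treated as saturated (all nuclei, with a warning), zero as
blank.

## Statistics

Cohorts are compared cell-by-cell over (layer, query, size class):
group means and SDs, percent difference 100·(KO−WT)/WT, and a two-tailed
unpaired Student's (pooled-variance) t-test, the conventional choice for
the 3-4 animals per genotype these experiments use; Welch's variant and
Benjamini–Hochberg adjustment are options, both off by default.  Cells
with under two samples on a side are reported missing, never imputed.
Astrocyte-association fractions are tripartite density over the matching
bipartite density (clipped to [0,1] with a warning); the E/I ratio is
glutamatergic over GABAergic density.  Embedded-tissue densities convert
to unprocessed tissue by (1−l)³ for linear shrinkage l (23% linear ↔ 54%
volumetric; 1.94/µm³ embedded ↔ 0.9/µm³ unprocessed).

Colocalization uses the van Steensel shift-correlation: Pearson r between
two raw-intensity channels, pooled over sections in a 40 µm × 26 µm ROI,
as one channel is shifted laterally ±2 µm in 1 px steps along one axis
(synapses are randomly oriented, so one axis suffices).  r(d) compares
A(x) with B(x+d).  Significance compares r(0) to the empirical null of
correlations at shifts ≥ 1 µm, two-sided about the null median, with the
add-one rank rule.  Colocalized markers peak at zero shift and decay;
adjacent-but-non-overlapping markers peak at their offset distance;
exclusive markers are anti-correlated at zero.

## Synthetic volumes

The generator emulates the acquisition: calibrated multi-channel stacks
with four disjoint synapse types (VGluT1, VGluT2, dual VGluT1/2,
GABAergic).  Defaults represent adult mouse somatosensory cortex as such
experiments report it: type densities 1.30 / 0.20 / 0.12 / 0.30 per µm³
of neuropil (total ≈ 1.9, inhibitory fraction ≈ 16%), astrocyte
association 0.72 for excitatory and 0.29 for inhibitory synapses,
log-normal punctum spans (median 2 sections, σ_log = 0.5, rounded and
floored at 1), cleft offsets 0.15–0.25 µm, punctum radii 0.1–0.3 µm
(GS: 0.08–0.15 µm — peripheral astrocytic processes are finer than
synaptic specializations), an optical blur of σ = 0.1 µm folded into the
rendered lateral width, punctum peaks 8 background SDs over a
Normal(100, 10) background, VGluT2 speckle at 1 single-section punctum
per µm³, and DAPI ellipsoid nuclei targeting 10% of the volume.  Puncta
are rendered as 2σ-truncated Gaussians, flat across their section span;
untruncated skirts are not part of a punctum and would create
artifactual low-level correlations between channels.  Synapse counts are
Poisson per type and size class; placement is uniform over the neuropil
with a 0.6 µm minimum centroid spacing (synaptic specializations cannot
interpenetrate) and a small border margin; all randomness flows from one
seeded generator, so output is bit-reproducible.

What the simulator does **not** model: section-to-section registration
errors and compression, intensity falloff with depth, antibody elution
artifacts, blood vessels, realistic nuclear texture, or correlated
marker amplitudes.  Passing tests therefore demonstrate the pipeline's
correctness under the generative model's geometry and noise — not
performance on real tissue, where registration and staining variability
dominate.

## Validation experiments and their problem sizes

The canonical experiments (`synquery.experiments`) fix desk-scale scenes
chosen for what each measures:

- **Detection accuracy**: 100×100 px × 30 sections at a density giving
  ~50 synapses; type-specific queries matched greedily one-to-one to
  eligible ground truth within 0.3 µm (≈ synapse scale).  Sparse scenes
  make per-synapse bookkeeping unambiguous.
- **Additivity identity** (glut = VGluT1 + VGluT2 − VGluT1/2): 30×30 µm ×
  30 sections at 0.15× the full density.  At full crowding the synthetic
  blob geometry (puncta up to ~0.6 µm across at 0.6 µm minimum spacing)
  lets a synapse borrow a neighbor's markers through the adjacency
  window, which contaminates per-type counts with a geometry artifact
  rather than testing the bookkeeping identity.
- **Astrocyte-association recovery**: mean over three 30×30 µm samples at
  0.08× density, using the VGluT1 bipartite/tripartite pair.  Mirrors
  per-animal averaging; low GS density keeps chance adjacency to
  unrelated astrocytic puncta from inflating the fraction.
- **Nuclei recovery**: one 20×20 µm volume; the estimated nuclear volume
  fraction is compared to the 10% target.
- **Knockout sign recovery**: twenty replicate cohorts of 3 WT + 4 KO
  samples (21×21 µm, GABAergic synapses only — the effect under test is
  −15% on large inhibitory synapses), scoring the sign of the detected
  large-inhibitory density difference.  Sample volume (~930 µm³) is sized
  so Poisson counting noise leaves ~2σ of sign power per cohort.
- **Adjacent-pair shift profile**: a constructed two-channel field of
  1200 punctum pairs offset 0.3–0.4 µm in random directions; the
  correlation profile must rise from zero shift to a peak at the offset
  distance (0.3–0.4 µm) and fall beyond it.

## Numerical notes and limitations

- Joint window evidence uses a log-space uniform filter with a 1e-30
  floor; an exact zero anywhere in the window forces exact zero evidence.
- Threshold monotonicity of detection counts holds over the operating
  range (up to the 0.9 default); exactly at saturation a supra-threshold
  region can pinch into two cores as the threshold rises, adding one
  count — intrinsic to any component-counting detector.
- Size-class subtraction guards its anti-monotonicity with a hard
  assertion; a violation would indicate an operator bug.
- Ground-truth and detection CSVs round-trip floats exactly
  (`%.17g` on write, `float_precision="round_trip"` on read).
- Tripartite fractions measured as density ratios carry two opposing
  small biases on synthetic data — chance adjacency to unrelated GS
  puncta (up) and bipartite false positives diluting the denominator
  (down); both grow with density, which is why parameter-recovery
  experiments run sparse.
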