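# Methods

This note documents the models and procedures implemented in
`podoquant`, the assumptions behind the synthetic-data generators, the
parameters that matter, and the numerical choices made where the design
was genuinely open.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Focal-contact segmentation and morphometry

Focal adhesions appear in vinculin/talin/paxillin immunofluorescence as
bright, roughly elliptical plaques (~0.5–3 µm²) on a diffuse cellular
background.  The pipeline has five stages.

**Adaptive threshold.**  A pixel is a candidate if it exceeds the local
mean plus `local_k` local standard deviations in a `window`×`window`
neighborhood (defaults 31 px, k = 0.5).  The local statistics are
computed with uniform filters in O(n).  The window is sized to roughly
twice the diameter of a large adhesion so the local background estimate
is not dominated by the plaque itself.  k controls the area/false-positive
trade-off: at realistic plaque densities (~10–20 % of the cell area
covered), the plaques themselves inflate the local standard deviation,
so a k near 1 systematically erodes measured areas (≈ −20 % in our
synthetic sweeps); k = 0.5 recovers planted areas within ~5 % across
SNR 5–20 while the two downstream gates absorb the extra false
foreground.

**Boundary-gradient gate.**  Components are kept only if the mean Sobel
gradient magnitude on their boundary exceeds the `gradient_quantile` of
the whole scene's gradient distribution (default 0.9) and their area
lies in [`min_area_um2`, `max_area_um2`] (defaults 0.1–20 µm²).  The
quantile gate expresses "adhesions have sharp edges relative to this
scene"; a quantile much below 0.9 sits inside the noise floor of
sparsely covered scenes and admits small noise clumps.

**Center/periphery specificity filter.**  Adhesions are center-bright;
out-of-focus blobs and diffuse background are not.  For each component
the center is the innermost `center_fraction` (default 25 %) of pixels
by internal distance transform; the periphery is a ring of
`periphery_width` px (default 3) outside the component, excluding
neighboring components.  Components with center/periphery mean-intensity
ratio below `cp_ratio_min` (ρ, default 1.2) are removed.  Components
whose ring is unusable (image border, fully adjacent contacts) are
retained with a warning rather than silently dropped.

**Separation of touching contacts.**  Within each component the internal
distance transform is lightly smoothed (σ = 0.8 px) and its h-maxima
(h = `split_depth` × max distance, default 0.4, floored at 0.5 px) seed
a watershed on the negated distance.  The smoothing and floor exist
because sub-pixel bumps on the distance ridge of a rasterized ellipse
otherwise split single elongated contacts.  Splitting conserves the
total foreground pixel count exactly; children smaller than the minimum
area are merged back into their largest sibling.  The operation is
idempotent on its own output.

**Measurement and localization.**  Area is pixel count × pixel size²;
axes and orientation come from second central moments
(`skimage.regionprops`); both mean and integrated intensity are
reported because conventions differ between laboratories.  With a
seeded cell segmentation, each contact receives the cell label under
its centroid and a radial position: distance from the cell centroid to
the contact centroid divided by the distance from the cell centroid to
the cell boundary along the same ray, clipped to [0, 1].  Contacts on
background are flagged and retained.

## Filtration-slit density

FSD — slit-diaphragm length per glomerular capillary area, µm⁻¹ — is
the standard morphometric readout of foot-process architecture in
super-resolution kidney imaging; foot-process effacement lowers it.
The measurement operates on a 2D projection of the slit channel:

1. **Segmentation**: light Gaussian smoothing (0.8 px) followed by Otsu
   (or a fixed threshold).  The smoothing suppresses shot-noise pixels
   that would otherwise contaminate both skeleton and envelope.
2. **Length**: morphological thinning to a 1-px skeleton, then a chain
   metric that counts 1 per orthogonal and √2 per diagonal neighbor
   pair, × pixel size.  Plain pixel counting would underestimate
   diagonal curves by up to 29 %.  The (1, √2) metric is exact on
   axis-aligned and 45° lines, and overestimates smoothly curved paths
   by an orientation-averaged factor of ≈ 1.055 (the classical
   chain-code bound; it reaches +8 % at 22.5°).  No skeleton pruning is
   applied by default.
3. **Capillary area**: an explicit ROI polygon when provided (the usual
   semi-automatic practice), else the envelope of the slit mask —
   Euclidean closing at `closing_radius_um` (default 1 µm, large enough
   to bridge foot-process-scale gaps) followed by hole filling.
4. **FSD** = length / area.

In end-to-end synthetic sweeps the chain-metric length overestimate and
the envelope's mild area overestimate act in the same direction on
numerator and denominator, keeping the recovered FSD within ±5 % of the
planted density across 2–6 µm⁻¹ at SNR 10.  An isolated digitized
circle, by contrast, exposes the raw +5.5 % metric factor — a known
property of all (1, √2) chain estimators, not a defect of a particular
thinning algorithm.

## Cell-level quantifications

**Seeded segmentation.**  The foreground is a global threshold (Otsu by
default) on the smoothed channel; user seeds grow geodesically
(watershed on a constant elevation restricted to the foreground) until
the seeded labels partition it.  Seeds falling on background are
reported by name.

**Nucleus detection.**  A single-scale, scale-normalized
Laplacian-of-Gaussian response at σ = blob_scale/√2, peak-picked with
non-maximum suppression at the blob scale and an absolute response
threshold, then refined to subpixel precision by a response-weighted
centroid over the full positive LoG lobe (~0.1 px accuracy at SNR ≥ 20
in the synthetic benchmark).  Two nuclei closer than the blob scale
merge into one detection; detection count is monotone non-increasing in
the threshold.  This classical detector deliberately replaces
trained-network detectors: it needs no weights, is fully deterministic,
and is adequate for well-separated stained nuclei.

**Track linking.**  Greedy nearest-neighbor assignment frame to frame
under a maximum displacement (default 30 µm), with gap closing up to
`max_frame_gap` missed frames (default 1).  Mean speed is total path
length over total duration (µm/min); net displacement is also emitted
because "migration distance" conventions vary.  Greedy linking recovers
exact identities when inter-object spacing exceeds twice the true step
size; it does not attempt globally optimal (LAP-style) assignment or
mitosis handling.

**Filopodia.**  The cell body is the morphological opening of the cell
mask at `body_opening_radius_um` (default 2 µm — larger than any
filopodium is wide, smaller than the cell body); protrusions are the
mask minus the body.  Each skeletonized protrusion component touching
the body is one filopodium; its length is the geodesic distance (1/√2
chain weights × pixel size) from the base (skeleton pixel nearest the
body) to the farthest tip, computed by Dijkstra on the skeleton
adjacency graph.  Filopodia shorter than `min_length_um` (default 1 µm)
are discarded.

**Adhesion loss** is the percent change in adherent-cell count,
100·(n_condition − n_reference)/n_reference.

## Statistical post-processing

Two groups are compared with a two-sided unpaired t test (pooled
variance by default; Welch optional).  More than two groups: one-way
ANOVA is reported together with all pairwise t tests adjusted by the
Benjamini–Hochberg step-up procedure across the pairs; the adjusted
pairwise rate, not the ANOVA gate, is what the package's type-I
simulations control (≤ 7 % empirical at nominal 5 % under the null).
`bh_adjust` returns adjusted values in input order, monotone and
clipped to 1.

The Pfaffl ratio E_t^ΔCt,t / E_ref^ΔCt,ref (ΔCt = Ct(control) −
Ct(sample)) generalizes the 2^ΔΔCt rule to measured amplification
efficiencies, which must lie in [1, 2.2].

The stretch membrane is modeled as a spherical cap: a circular membrane
of radius a deflected at its center by h gains relative area
ΔA/A = (h/a)², and the mean linear strain is s = √(1 + ΔA/A) − 1 (the
isotropic square root of the area stretch; s ≈ ΔA/2A for small
stretches).  The area↔strain conversion is model-independent; the
deflection→area step requires the membrane radius, which is left as a
required input because apparatus geometries differ.

The volcano filter classifies records as up (FC ≥ fc_min and
p ≤ p_max), down (FC ≤ 1/fc_min and p ≤ p_max, the reciprocal making
the rule symmetric on the log scale) or ns; both thresholds are
inclusive.  Fold changes may be supplied linear or log2.

## Synthetic-data generators

The generators emulate the statistical structure each pipeline assumes —
not photorealism.  All are deterministic given a seed; all planted
quantities are stored in µm-based units.  Noise is Poisson
(signal-dependent, unit gain) followed by additive Gaussian noise;
SNR is defined as rendered peak amplitude over Gaussian sd.

*Focal-contact scenes* (defaults: 512² px at 0.1 µm/px, 200 contacts,
lognormal areas with mean 1.32 µm² and CV 0.35 — control-condition
adhesion morphometry — axis ratios 1.5–3, center/periphery amplitude
ratio 3, SNR 10).  Each contact is a generalized Gaussian on the
ellipse's normalized radius with exponent 6: a flat-topped plaque
whose rim sits at peak/ratio above background, giving the
center-bright contrast the specificity filter relies on and making the
planted area insensitive to the exact threshold level.  Contacts are
placed without overlap inside an irregular cell-shaped background blob;
an optional fraction is planted as touching pairs.

*Slit scenes* (defaults: 0.025 µm/px — super-resolution scale — disc
capillary of ≈ 100 µm², line width 1 px, blur σ 0.8 px, SNR 10).
Smoothed random-walk polylines are packed inside the capillary with a
minimum inter-curve exclusion of 3 px (~0.075 µm, about a foot-process
width) until the rendered polyline length reaches target FSD × area;
the truth length is measured on the rendered (integer-vertex) polyline,
so it describes exactly what is in the image, and satisfies
|L/A − target| ≤ 2 % by construction.  Start points are sampled
preferentially far from existing curves, the way foot processes tile
the capillary surface evenly; walkers slide along obstacles so curves
run parallel to neighbors, like interdigitating foot processes.
Densities are achievable up to roughly half the parallel-line bound of
the exclusion spacing; unreachable targets raise.

*Filopodia scenes*: a convex disc body plus straight, ≤ 3-px-wide
radial protrusions of specified lengths at angularly separated
positions, so the planted geodesic length is exact.

*Nuclei time-lapses*: Gaussian spots moving with per-frame displacement
drift + N(0, step_sd²·I) in µm, default frame interval 20 min.
Placement leaves headroom for the full deterministic drift; random-walk
excursions are clipped at the field border and the ground truth is
computed from the realized (post-clip) trajectories, so truth always
describes what was rendered.

*Proteome tables*: exactly n_up rows pass both up-regulation
thresholds, exactly n_down pass both down-regulation thresholds, and
every remaining row strictly fails at least one criterion.

**What passing tests do and do not show.**  The generators use
isotropic Gaussian optics, uniform backgrounds, non-overlapping objects
and stationary noise.  Real immunofluorescence adds uneven
illumination, out-of-focus structure, autofluorescence, and genuinely
ambiguous adhesion boundaries; real SIM data add reconstruction
artifacts and 3D geometry that a 2D projection flattens.  Recovery on
these scenes therefore validates the algorithmic chain (segmentation
→ measurement → statistics) against known truth, not the biological
accuracy of any particular acquisition.

## Problem sizes and reproducibility

The acceptance script regenerates every reported number from scratch at
modest problem sizes chosen for a single CPU: 10 focal-contact scenes
of 200 contacts, 3 slit scenes per density group, 5 paired filopodia
replicates, one drift time-lapse, and a planted 2000-protein table.
The test suite uses the same generators at equal or smaller sizes, plus
1000-replicate null simulations for the type-I checks.  Every random
choice flows from an explicit seed; identical seeds give bit-identical
scenes and tables.

## Known limitations

- The (1, √2) chain metric overestimates smoothly curved skeleton
  length by up to ~5.5 % on average (exactly the digitized-circle
  factor); end-to-end FSD stays within ±5 % only because the envelope
  denominator behaves consistently.
- The capillary envelope is a closing of the slit pattern; for very
  sparse patterns it can undershoot the true capillary by a few
  percent.  An explicit ROI polygon avoids this entirely.
- Greedy linking can swap identities when objects approach within the
  maximum displacement of each other between frames.
- Filopodium lengths carry a one-to-two-pixel uncertainty at the base
  junction (thinning is not exactly grid-symmetric there).
- The semi-automatic operations (cell seeds, capillary ROI) take file
  input, not interactive clicks, by design.
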