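# podoquant

Quantitative image analysis for podocyte biology.

Podocytes are the terminally differentiated epithelial cells whose
interdigitating foot processes form the kidney's filtration slits.
Studying how they sense and withstand mechanical stretch requires a set
of quantitative readouts that are usually scattered across ad-hoc
scripts and interactive tools: focal-adhesion morphometry from
immunofluorescence, filtration-slit density from super-resolution
images, cell spreading, migration and filopodia measurements from
time-lapse and phase data, and the small statistical toolbox that turns
those measurements into group comparisons.  `podoquant` implements these
pipelines as one tested, scriptable package, together with synthetic
scene generators that carry exact ground truth, so every pipeline can be
validated end to end.

## What it computes

**Focal-contact morphometry** (`podoquant.fa_morphometry`).  Candidate
adhesions are segmented by an adaptive local threshold
(pixel > local mean + *k*·local sd in a square window), retained only if
the mean gradient magnitude on their boundary exceeds a quantile of the
scene gradient distribution and their area falls inside physical gates.
A specificity filter compares each candidate's center intensity (the
innermost 25 % of pixels by distance transform) with a surrounding
3-px ring and removes candidates whose center/periphery ratio falls
below ρ.  Slightly connected contacts are separated by a watershed on
the internal distance transform seeded at h-maxima.  Each contact is
reported with area (µm²), axis lengths, eccentricity, orientation, mean
/ max / integrated fluorescence, and its normalized radial position
inside a seeded cell segmentation.

**Filtration-slit density** (`podoquant.slit_density`).  FSD is the
total slit-diaphragm length per glomerular capillary area,

    FSD = L_slit / A_capillary   [µm⁻¹],

measured by thresholding the slit channel, thinning it to a one-pixel
skeleton, summing orthogonal (1) and diagonal (√2) steps × pixel size,
and dividing by the capillary area (an explicit ROI polygon, or the
closed and hole-filled envelope of the slit mask).

**Cell dynamics** (`podoquant.cell_dynamics`).  Seeded (semi-automatic)
cell segmentation; spreading-area time series; scale-space (LoG) nucleus
detection with subpixel refinement; adhesion-loss percentages; greedy
nearest-neighbor track linking with gap closing and mean speed in
µm/min; filopodia detection by morphological opening of the cell mask
with geodesic skeleton lengths.

**Statistics** (`podoquant.stats`).  Unpaired two-sided t tests (pooled
or Welch), one-way ANOVA with Benjamini–Hochberg-adjusted pairwise
tests, the Pfaffl efficiency-corrected qPCR ratio
E_t^ΔCt,t / E_ref^ΔCt,ref, the spherical-cap membrane strain model
(ΔA/A = (h/a)², s = √(1+ΔA/A) − 1), volcano-threshold filtering of
differential-abundance tables (up ⇔ FC ≥ 1.5 and p ≤ 0.05, down ⇔
FC ≤ 1/1.5 and p ≤ 0.05, thresholds inclusive), and intensity-in-mask
summaries.

**Synthetic scenes** (`podoquant.simulate`).  Deterministic, seeded
generators for every pipeline: elliptical center-bright focal contacts
on a cell-shaped background, meandering slit curves of known total
length packed inside a capillary mask, cells with thin protrusions of
known geodesic length, drifting/diffusing Gaussian-spot nuclei, and
differential-abundance tables with exactly planted regulation.  Each
generator returns a `GroundTruth` record sufficient to score any
pipeline output without re-deriving anything from pixels.

## Worked example

```python
import numpy as np
from podoquant import (FaSceneSpec, synth_fa_scene, quantify_focal_contacts,
                       membrane_strain, synth_proteome_table, volcano_filter)

# focal-adhesion morphometry on a synthetic control scene
scene, truth = synth_fa_scene(FaSceneSpec(seed=1, n_fa=200, snr=10.0))
contacts = quantify_focal_contacts(scene.channel("fa"), scene.pixel_size)
print(f"planted contacts : {len(truth.objects)}  (true mean area "
      f"{truth.objects['area_um2'].mean():.2f} um^2)")
print(f"detected contacts: {len(contacts)}  (measured mean area "
      f"{contacts['area_um2'].mean():.2f} um^2)")

# stretch geometry of a 6 mm center deflection on an 18.09 mm membrane
g = membrane_strain(cap_height_mm=6.0, membrane_radius_mm=18.09)
print(f"6 mm deflection  : area +{100*g.area_increase:.1f} %, "
      f"linear strain {100*g.linear_strain:.1f} %")

# volcano filter on a planted differential-abundance table
table, _ = synth_proteome_table(n_proteins=2000, n_up=71, n_down=105, seed=1)
n_up, n_down, _ = volcano_filter(table.data, fc_min=1.5, p_max=0.05)
print(f"volcano filter   : {n_up} up-, {n_down} down-regulated")
```

prints

```
planted contacts : 200  (true mean area 1.34 um^2)
detected contacts: 200  (measured mean area 1.30 um^2)
6 mm deflection  : area +11.0 %, linear strain 5.4 %
volcano filter   : 71 up-, 105 down-regulated
```

The detected contact count matches the planted count exactly and the
measured mean single-adhesion area recovers the planted mean within a
few percent; an 11 % membrane-area increase corresponds to ~5 % mean
linear cell strain; the volcano thresholds recover the planted
regulation counts exactly.

## Command line

A thin CLI chains the same pipelines over files:

```sh
podoquant simulate fa --seed 1 --out scenes/        # scene + ground truth
podoquant fa-quant scenes/fa.tif --out contacts.csv
podoquant fsd slits.tif --pixel-size 0.025 --out fsd.csv
podoquant track timelapse.tif --out tracks.csv
podoquant volcano-filter proteome.csv --fc-min 1.5 --p-max 0.05
podoquant strain --height 6 --radius 18.09
```

Every run writes a plain-text log with all parameters and the seed;
identical inputs and seeds reproduce identical outputs.

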