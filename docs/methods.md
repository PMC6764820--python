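# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user should know before trusting
or changing a result.

## Synthetic movies

`simulate.MovieConfig` holds both the acquisition geometry and the
biological truth. Geometry defaults follow volumetric light-sheet-style
acquisition: z-step 0.250 µm over a 25 µm range, 5.67 s between stacks,
0.25 µm xy pixels. Camera gain and background counts are free parameters
(they are instrument settings, not biology): background 100 counts,
chromatin contrast amplitude 300 counts, Poisson shot noise at gain 1
followed by Gaussian read noise of SD 2 counts, in that order (camera
physics convention).

Chromatin is rendered per nucleus as parameterized ellipsoids following
the mitotic phase schedule: a single oblate metaphase plate (short axis
along a per-nucleus random division axis in the imaging plane), two
prolate anaphase masses separating along that axis to 3 nucleus radii,
compact telophase / late-telophase spheres, and larger decondensed
interphase daughters. The recruitment channel equals
`background × f(phase)` inside the chromatin mask and `background`
outside; `f` is the ground-truth enrichment factor the pipelines must
recover. The default phase → f profile rises through anaphase to a
late-telophase maximum and partially decays in interphase, matching the
qualitative loading time course of initiator proteins on mitotic
chromosomes. The PSF is a separable Gaussian with anisotropic sigma
(z 0.2 µm > xy 0.12 µm, a light-sheet-scale optics proxy). Random streams
are split per nucleus from a master `SeedSequence`, so identical
(config, seed) pairs are bit-identical and placement is stable under
profile edits.

Two presets encode the study conditions used throughout the tests:

* `embryo_movie_config` — a field of 10 synchronously dividing nuclei
  (radius 3 µm) with cytoplasm filling the field of view, as in a
  syncytial blastoderm. The rendered field (48 × 60 µm, 16 z-planes of
  0.4 µm) is smaller and more coarsely sampled in z than the full
  acquisition geometry so a movie renders in seconds, while preserving
  the optics scale (PSF ≪ body size) that controls measurement bias.
* `s2_movie_config` — one mitotic cell on a dark field. The GFP channel
  is dark (camera offset, 2 counts) outside a 8 µm cell cylinder,
  cytosolic (100 counts) inside it, × f on chromatin; chromatin bodies
  span the (thin, 6 µm) z-range, as mitotic chromosomes do in a rounded
  cell. Both choices matter: the dark surround is what the pipeline's
  below-threshold background estimate measures, and the z-spanning
  chromatin is what makes a sum projection preserve the enrichment
  factor rather than dilute it with out-of-plane cytosol.

Not emulated: photobleaching, chromatic aberration, chromosome texture,
autofluorescence gradients, nucleus-to-nucleus variability of f, cell
movement other than uniform drift. Passing recovery tests therefore show
that the measurement chain is unbiased under ideal optics and noise — not
that segmentation survives textured or crowded real data.

Droplet fields are non-overlapping disks (radius 1–2 µm by default, the
scale of the condensates measured in vitro) with a DNA channel defining
droplets and a partner channel enriched inside by a configured factor.
Titrations evaluate the Hill model exactly plus Gaussian noise. Random
sequences are i.i.d. draws over the 20-letter protein or 4-letter DNA
alphabet with optional per-symbol weights.

## Volumetric segmentation

Median (3 voxels/axis) then Gaussian (1 voxel) filtering with reflective
boundaries; kernel sizes are config values since no standard exists. The
locally adaptive threshold marks a voxel foreground when it exceeds the
local mean over an odd block by more than `offset`; this sign convention
makes a constant volume all-background and foreground monotone
non-increasing in `offset`. Border clearing defaults to the x/y borders
only — z truncation is physical, not a segmentation error. Connectivity
is fixed at 26 (3D) / 8 (2D).

The standard analysis settings for embryo-style movies
(`traces.EMBRYO_ANALYSIS`) use a block of ~2× the nucleus diameter
((9, 41, 41) voxels), offset = 40% of the chromatin contrast amplitude
(120 counts), and a minimum object size of 80 voxels. The offset choice
places the mask boundary at the blurred body edge: much lower and the
mask swallows the PSF halo (diluting the in-mask mean), much higher and
the mask erodes to the body core. At these settings the end-to-end
pipeline recovers configured enrichment factors f ∈ {1.5, 2.5, 4.0}
within 3% (noise on or off) and f = 1 as 1.01; the residual bias is the
PSF edge effect, which grows toward (σ/r)-scale as bodies shrink.

## Tracking

Frame-to-frame linking minimizes total Euclidean centroid displacement
with a gating distance `max_disp` (a required analysis parameter; the
embryo preset uses 4 µm ≈ one body radius per 5.67 s frame). Gating uses
the standard square reduction: dummy nodes at cost `max_disp` for every
real object, forbidden (> max_disp) pairs set to a large sentinel. The
objective actually minimized — matched distances plus `max_disp` per
unmatched object — is therefore explicit and is what the exhaustive
oracle in the tests enumerates. Ties are resolved deterministically by
`scipy.optimize.linear_sum_assignment`'s row-major order. There is no gap
closing and no lineage logic: anaphase splitting appears as a second
track starting at the split, which is the desired behavior for
per-chromatin-mass traces.

## Fold-enrichment traces

Intensities are measured on raw voxels (filtering is for detection only;
quantification on filtered data would be biased). Background is the
median intensity outside a 2-voxel dilation of the union object mask,
per frame and per channel — median for robustness to stray bright
objects, dilation to keep PSF-blurred rims out of the background pool;
an empty mask degenerates to the whole-volume median, a mask covering
≥ 90% of the volume is an error. F(t) is invariant to global intensity
rescaling by construction.

Peak alignment smooths the recruitment-channel fold series with a
3-frame moving average (edge-padded; window is config-visible) and takes
the earliest argmax; flat traces warn and peak at frame 0. Cohort
dispersion statistics use the sample SD (n−1), since reported "±" values
are cohort dispersions.

## Projection pipeline

Sum projection over z, Gaussian blur of radius 1 px, scalar background
subtraction clipped at 0, in that order. "Auto-threshold" is the
isodata/intermeans iterative global threshold (the common default in
general-purpose imaging software), with minimum-intra-class-variance
(Otsu) selectable; for well-separated bimodal images both land in the
inter-mode gap and give identical masks. The reference frame defaults to
frame 0 (metaphase by acquisition design). When not given explicitly,
per-channel background is the mean of pixels below the auto threshold of
that channel's first projected frame — with a single-cell field this is
the dark surround. The ROI mean is a plain arithmetic mean (no
histone-channel weighting). On the S2 preset the pipeline recovers a
configured telophase enrichment of 2.5 within 5% and the uniform-GFP
null as 1.00 ± 0.01; the residual bias is again the blurred-rim effect.

## Droplet quantitation

Droplet ROIs: same auto-threshold engine, 8-connected components,
minimum area 4 px (suppresses shot-noise singletons). The partition
ratio excludes a 2-px dilated guard band around droplets from the
"outside" pool so PSF bleed cannot bias the denominator. Depletion and
pellet-enrichment are pure band-intensity arithmetic (densitometry
itself is out of scope; any source of band intensities works); D is
dimensionless and exposure-invariant. Phase diagrams require a full
rectangular (protein, salt) grid with no duplicates; the droplet-count
cutoff defining "phase separation observed" is an explicit parameter
(default 1) because no standard value exists.

## Sequence analytics

Coordinates are 1-based inclusive in sequence space (images are
0-based). The IDR is the longest contiguous run of disorder scores
strictly above the cutoff (default 0.5), earliest run on ties; disorder
scores are consumed from TSV, never recomputed. FCR counts D/E/K/R only
(the standard definition), while the "charged" composition class
includes H; both are reported because both conventions are in use.
Positive/negative fractions count K/R and D/E respectively (H excluded;
with the default pKa table H is < 10% protonated above pH ~7, so either
convention is computable from the composition profile).

pI is the bisection root (|Q| < 1e-4) of a Henderson–Hasselbalch net
charge over D, E, C, Y, H, K, R and the two termini with a
Bjellqvist-style pKa table (N-term 7.50, C-term 3.55, D 4.05, E 4.45,
C 9.00, Y 10.00, H 5.98, K 10.00, R 12.00), swappable per call. Published
pI tools differ by a few tenths of a pH unit depending on their table;
agreement within ±0.3 is the realistic expectation, which is also the
tolerance used against literature values.

Compositional complexity uses the multinomial (Wootton–Federhen) form
K = log(L!/Πnᵢ!)/(L·log N) with N = 20 and natural logs, evaluated in a
20-residue window via log-gamma and assigned to the window's central
residue; edge residues carry no score (no standard edge rule exists,
and inventing one would bias disordered/ordered summaries near termini).
K = 0 exactly for homopolymers and < 1 always.

CDK scanning reports all overlapping occurrences: minimal sites are
[S/T]P pairs, full sites additionally require K/R three residues after
the S/T ([S/T]PX[K/R]); interval restriction is by the S/T position.

## Binding fits

Hill and 4PL fits are least squares (lmfit/Levenberg–Marquardt) started
from 7 log-spaced Kd/IC50 seeds spanning the positive concentration
range, keeping the best χ²; this removes the usual local-minimum
sensitivity without user tuning. The Hill coefficient can float
(default) or be fixed at 1 — both modes exist because published
anisotropy fits often do not say which they used. The competition fit
reports the fitted IC50 directly as the apparent inhibition constant;
a Cheng–Prusoff-style correction (IC50 / (1 + [probe]/Kd)) is an
explicit option rather than a silent default, since the underlying
binding model is rarely stated. Standard curves are ordinary least
squares with inverse prediction; predictions outside the standards'
amount range set an extrapolation flag and warn.

With 10-point curves and Gaussian noise at 5% of the dynamic range, the
median Kd over 200 replicates is within ~4% of truth (floating n);
noiseless data are recovered to ~1e-9 relative error.

## Problem sizes

The test and acceptance workloads are deliberately desk-scale: embryo
movies of 10 nuclei at 160 × 200 × 16 voxels × 40 frames (~20 s each to
render and quantify), S2 movies of 128 × 128 × 6 voxels × 8 frames,
droplet fields of 20 droplets at 320², 200-replicate fit ensembles, and
1000-instance assignment oracles. These sizes were chosen so the full
validation chain reruns in about a minute while keeping every
bias-controlling ratio (PSF vs body size, noise vs contrast, droplet
radius vs guard band) at the scale of the real experiments.

## Known limitations

* Touching nuclei are not watershed-split; the tracker treats a merged
  mask as one object.
* The projection pipeline's background estimate assumes the cell does
  not fill the field; a full-field cell needs an explicit background.
* The pI model ignores charge-charge interactions and terminal-residue
  pKa adjustments; differences of ±0.3 against other tools are normal.
* The acidic extreme of the pI scale (< ~3) is extrapolation: most
  published tools clamp there, this one does not.
* Hill and 4PL fits assume independent homoscedastic errors; replicate
  SDs, if present, are not yet used as weights.
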