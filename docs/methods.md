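# Methods

This note records the models, parameter choices and numerical
conventions behind `caftrack`, and what the synthetic-data validation
does and does not demonstrate.

## Detection

Tracked cells are modeled as isotropic bright blobs on a dark
background. The detector computes the scale-normalized
Laplacian-of-Gaussian response `-σ² ∇²(G_σ * I)` with
`σ = (d / pixel_size) / (2√2)` for an expected diameter `d`: a disk of
radius `r = d/2` maximizes the scale-normalized response at
`σ = r/√2`, which is the standard blob-scale relation and matches how
blob detectors are configured by object diameter. scipy's
`gaussian_laplace` is used with reflect padding; because the truncated
discrete kernel does not sum exactly to zero, the kernel-sum times the
image is subtracted so the filter is exactly zero-DC (a constant image
yields a zero response, and adding an offset changes nothing).

Spots are strict 8-connected local maxima with response ("quality")
above `quality_min`; the threshold is applied before proximity
suppression so that lowering it can only add spots. Maxima closer than
`d/2` px to a stronger one, or within `d/2` px of the border, are
discarded. Positions are integer pixels by default; an optional
quadratic sub-pixel refinement exists but the contact rule operates at
≥ 1 px scale, so it stays off. Defaults: `diameter_um = 8`,
`quality_min = 1`. Quality units scale with image intensity, so the
synthetic tests calibrate blob amplitudes relative to the threshold
rather than assuming absolute units.

## Tracking

Frame-to-frame linking is a linear assignment problem with squared
Euclidean distance costs and a hard cap (`link_max_um = 36`,
boundary inclusive). "Minimal total cost among capped partial
matchings" alone is degenerate (the empty matching costs zero), so the
matching is defined as: maximal number of links admissible under the
cap, then minimal total squared distance — implemented with the usual
big-M augmented square cost matrix and verified against exhaustive
enumeration on random instances. Inputs are sorted by (frame, x, y)
so results are deterministic.

Gap closing joins a tracklet end to a later tracklet start when
1 ≤ skipped frames ≤ `gap_max_frames` (5) and the end-to-start
distance is ≤ `gap_max_um` (12). Candidates are applied greedily by
ascending distance rather than as a global assignment: at the cell
densities of these movies candidate joins rarely compete, and the
greedy rule is deterministic and easy to audit. Tracks never split or
merge (the cells do not divide on the analysis timescale; contact is
inferred downstream, not by track fusion).

Per-track statistics: path length (sum of consecutive observed steps,
a closed gap contributing its straight-line step), net displacement
(start to end), confinement ratio net/path (0 for a zero path), and
duration `(last − first + 1) × Δt`.

## Stromal segmentation

The stromal (fibroblast) area has low absolute contrast but high
texture, so it is segmented by local contrast
`C = sqrt(G_σ(I²) − G_σ(I)²) / (G_σ(I) + δ)` with `σ = 4` px and
threshold `ε = 0.08`, followed by hole filling and removal of
components below `min_object_px = 64`. The stabilizer
`δ = 1e-6 × mean(I)` scales with the image, making `C` (and hence the
mask) exactly invariant to a global intensity gain.

Windowed local contrast systematically overshoots a texture boundary:
outside a mean-matched textured region the contrast decays as
`C_in √Φ(−r/σ)` (Φ the normal CDF) with distance r, so thresholding at
ε extends the foreground by `r* = −σ Φ⁻¹((ε/C_in)²)` (~2–3 px at the
defaults). The mask is therefore eroded by `r*`, with `C_in` estimated
as the median foreground contrast — a self-calibrating boundary-spill
correction playing the role of the halo correction in phase-contrast
segmentation tools. It is first-order (exact for a straight,
mean-matched boundary) and can be disabled
(`spill_correction: false`). Fluorescence-marker area uses plain Otsu
or fixed thresholding (foreground strictly above the threshold).

## Contact rule and episodes

A cell is in contact when the Euclidean distance from its center to
the nearest stromal-foreground pixel is ≤ `contact_radius_um` (4 µm,
half the detection diameter), ties counting as contact. Distances are
computed from the exact Euclidean distance transform's
nearest-foreground index at the spot's grid cell. Episodes are maximal
runs of consecutive in-contact frames; runs shorter than
`min_episode_frames = 2` are discarded and `duration = n_frames × Δt`
(so the minimal 2-frame contact at 5-min sampling is 10 min — the
convention forces `n × Δt` rather than `(n−1) × Δt`). Frames skipped
by gap closing carry no flag and break runs; optional bridging of
short non-contact gaps exists (`bridge_max_frames`) but defaults to
off, strict runs being the conservative reading. Condition comparisons
use the Wilcoxon rank-sum on pooled per-episode durations (exact by
full enumeration when both n ≤ 8, with average ranks for ties;
tie-corrected normal approximation otherwise) or an unpaired
two-tailed t-test; per-track aggregation is available as an option.

## Spatial density and puncta

Fields are classed CAF-rich/poor against the within-experiment median
marker-area fraction; strictly greater than the median is rich, ties
are poor (a deterministic reading of "median as threshold"). A region
is a whole field by default. Counting is automated spot detection
(centers inside the region mask); density is cells per 10⁶ px.

Cell labeling for puncta counting: Otsu nuclei → connected components
(≥ `min_nucleus_px = 20`), cytoplasm foreground by Otsu, each
foreground pixel assigned to the label of its nearest nucleus pixel
(exact EDT nearest-index partition). Puncta are detected with the same
LoG machinery at `punctum_diameter_um = 0.8` and kept when their
response exceeds `quality_rel = 0.25` of the image's maximal response —
a per-image relative threshold, so counts are invariant to global
gain. A punctum belongs to the cell whose label contains its center;
puncta outside all labels are dropped, never double-counted. The
relative threshold assumes puncta dominate the small-scale response;
in an image containing only noise it can report a few false puncta
(an all-zero channel reports none).

## Synthetic data: what it emulates, and what not

`generate_movie` renders a 512×512 px field at 1 µm/px, 5 min/frame,
90 frames, 40 cells — one frame interval and movie length chosen to
match 7–8 h co-culture imaging. Cells are Gaussian blobs
(σ = d/(2√2), amplitude 150 over background 10, read noise σ = 1.5, so
detection quality ≈ 75 against a threshold of 1: the high-SNR regime
of these movies). Motility is a two-state random walk: free steps
σ = 6 µm/frame per axis and arrested steps σ = 0.5 µm/frame (invented
defaults — the source imaging does not quantify Treg speeds), arrest
entry allowed only inside the contact zone (true mask dilated by the
4 µm cell radius — the same rule the analysis applies, so recovery is
well-posed) with per-frame probability `p_on`, exit with `p_off`.
Conditions: antigen `p_on = 0.6, p_off = 0.05`; control
`p_on = 0.1, p_off = 0.5`. Transition uniforms and step normals are
drawn every frame regardless of state, so different rates consume
identical random streams (monotone coupling for the rate-monotonicity
property). Boundaries reflect, and cell centers keep a soft minimal
separation of one cell diameter (8 µm): lymphocyte bodies cannot
interpenetrate, and separations below the detector's two-blob
resolution limit (2σ ≈ 5.7 px) would create merge dropouts no real
movie shows.

The stromal channel holds a static speckle texture (uniform ±28 about
the background level 100, contrast ≈ 0.16 ≈ 2ε) inside the true mask —
mean-matched so only local contrast, not intensity, distinguishes it,
which is the regime the local-contrast segmenter exists for. The
default mask is 20 non-overlapping 30 µm-radius patches (~22% field
coverage), sized to a spread fibroblast cluster and matching the
surface coverage implied by seeding a few thousand fibroblasts in a
1 cm² chamber well. Not emulated: realistic PSF/camera noise, phase
halos, cell division, mask deformation over time, shape changes,
uneven illumination. Passing the recovery tests therefore shows the
pipeline recovers truth under the model's own assumptions (blob-like
cells, textured static stroma, two-state motility) — not performance
on real microscope data.

`generate_if_field` derives the marker region by thresholding a
smoothed Gaussian random field at the quantile matching the requested
area fraction (exact to histogram resolution) and places nuclei
(8 µm blobs at 0.5 µm/px) well inside / outside it with 1.5-diameter
separation, raising an overcrowding error when placement fails.
`generate_puncta_image` renders, at 0.2 µm/px, a smooth-edged
cytoplasm disk (edge smoothing 2 px keeps the disk edge from exciting
the small-scale punctum filter), a central nucleus blob, and 0.8 µm
puncta placed inside the cell radius with two-diameter separation.

## Validation sizes and runtimes

The test suite validates matching against brute force on 1000 random
≤ 6-spot frame pairs, episode extraction against run-length encoding
on 10⁴ random timelines, and LoG peak locations against dense
convolution on 20 blobs. Ground-truth recovery and condition-direction
checks use 40-cell, 90-frame movies — one per condition for recovery
(episode F1 and mean-duration agreement), five seeded replicates per
condition, pooled, for the direction statistics (episodes pooled
across replicates exactly as contact violins pool episodes across
videos; trajectory statistics restricted to tracks spanning at least
half the movie, since border-crossing fragments otherwise dominate and
dilute whole-trajectory contrasts). These sizes keep the full suite at
a few minutes on one CPU while leaving dozens of tracks and hundreds
of episodes per comparison.

## Known limitations

- Identity swaps between two cells that approach within the linking
  radius can merge contact episodes of different cells (observed at a
  few percent of episodes in the validation movies); a motion-model
  (Kalman) tracker would reduce this but is out of scope.
- The spill correction is calibrated for mean-matched texture
  boundaries; textures much brighter or darker than their surround
  will still be over- or under-segmented near edges.
- Integer-pixel localization makes the contact decision a tie at
  exactly the contact radius; sub-pixel refinement changes borderline
  frames.
- The exact rank-sum enumeration is limited to n ≤ 8 per group
  (C(16,8) labelings); larger samples use the tie-corrected normal
  approximation.
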