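# Methods

This note documents the models behind each stage of the pipeline, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real microscopy data.

## Synthetic scenes

The simulator emulates spinning-disk live imaging of lysosomes on an ER
network. Its defaults encode the fibroblast acquisition geometry: 120 nm
pixels (63× objective), one frame per second for one minute (`n_frames=60`),
a 256×256 px field (≈31×31 μm — a cell-sized crop chosen for desk-scale
runtime). Round lysosomes are 0.5 μm discs; tubular lysosomes are capsules
(rectangle + semicircular caps) of default length 3.0 μm and width 0.3 μm.
The capsule length/width were chosen so the three-way tubular criterion is
met by construction with margin: at 120 nm pixels, rasterization inflates
the area of thin objects by up to one pixel row, which pushes the
circularity of a 0.5 μm-wide capsule right onto the 0.5 cutoff depending on
sub-pixel placement; a 0.3 μm tubule (a realistic width for ER-associated
lysosome tubules, below the ~0.5 μm round-lysosome diameter) classifies
robustly at any placement.

The ER is the edge set of a Voronoi diagram of uniformly sampled seed points
(`er_density` seeds per μm², default 0.04), rendered as ridges with a
Gaussian cross-section of half-width 25 nm (a 50 nm tubule) floored at half
a pixel; the sampling window is padded so boundary cells still produce
ridges. A fraction `contact_fraction` of lysosomes is seeded directly on ER
edges (uniform by edge length). Motion is a mixture of stationary jitter
(σ = 20 nm), diffusion (D = 0.01 μm²/s) and directed runs (0.5 μm/s by
default; directed tubules orient along their motion). Directed directions
are resampled up to 200 times so the full run fits inside the field —
otherwise reflection at the boundary would shorten the realized path and
bias programmed-speed recovery; reflection remains as a last-resort
fallback. Rendering is analytic (anti-aliased signed distance), followed by
a Gaussian PSF (σ = 1 px ≈ the diffraction-limited spot at this pixel size)
and additive Gaussian noise. Photon (Poisson) noise, photobleaching,
3-D defocus and realistic PSF side lobes are deliberately out of scope: the
generator exists to stress detectors and geometry, not to fool a human.

Axon scenes are straight 80 μm segments (soma at coordinate 0) sampled
every 500 ms for 30 s, with class counts allocated from the programmed
(anterograde, retrograde, stationary) fractions by largest remainder so the
truth composition is exact; default fractions (0.3, 0.3, 0.4) and 1 μm/s
run speeds are typical of axonal lysosome transport. Start positions are
drawn so a full run never leaves the axon; configurations whose run length
cannot fit raise immediately.

Determinism: every stochastic choice flows from one `numpy` Generator
seeded by the config, so identical configs are bit-identical.

## Detection and morphometry

Spots are binarized on the negated Laplacian-of-Gaussian response at a
characteristic scale (default 2 px); the threshold is `mean + k·SD` of the
response (k = 3 by default). These detector parameters are configuration,
not constants: there is no canonical setting for a spot detector, so the
defaults are this package's own and are surfaced in every API and CLI. Components below 4 px are removed; connectivity is fixed at 8 so
one-pixel-wide tubules do not fragment.

Region properties come from `skimage.measure.regionprops` (the direct
analogue of the MATLAB `regionprops` this analysis style is built on):
sub-pixel centroids, moments-of-inertia ellipse axes and eccentricity, and
the Crofton 4-direction perimeter. Crofton was chosen because the naive
boundary-pixel count biases disc circularity far below 1, which would
distort a cutoff at 0.5; with Crofton a rasterized r = 10 px disc measures
within [0.85, 1.1]. Single-pixel regions get eccentricity 0 by the moments
convention, and a degenerate zero perimeter falls back to the equal-area
disc perimeter so circularity stays defined and positive.

The tubular rule is the conjunction `circularity < 0.5 ∧ eccentricity >
0.9 ∧ axis_ratio > 4`. The axis-ratio criterion is stated in the field as a
width/length ratio; read literally that ratio is < 1 for any elongated
object and could never exceed 4, so it is implemented as major/minor on the
fitted-ellipse axes (bounding-box sides would be orientation-dependent).
Both the interpretation and the thresholds are configurable. The tubulation
index is `clamp((d − d_KO)/(d_WT − d_KO), 0, 1)` with same-experiment
control means; equal control means raise rather than return a silent NaN.
Per-experiment summarization (superplot convention) averages per-cell
values within each independent experiment; downstream statistics should
consume those means only.

## Contacts

The area-overlap readout labels lysosome particles and intersects each with
the ER mask; contact is called above a 30% overlap fraction. The threshold
itself is justified by the 1-D apparent-overlap calculator: each rendered
edge extends one pixel beyond the true object edge, so two objects with a
true edge gap `g` overlap by `max(0, 2p − g)` at pixel size `p`, and the
apparent diameter is the true diameter + 2p. The default geometry (500 nm
lysosome, 10 nm gap, 120 nm pixels) yields 230 nm on 740 nm ≈ 31%, rounded
to the 30% working threshold. Both computations are kept: the area fraction
is the measurement, the 1-D argument is the threshold derivation.

The flip control rotates the lysosome mask 90° about the image centre
(pad-to-square, rotate, crop) while the ER stays fixed — a spatial
randomization that preserves both marginal patterns while destroying their
co-localization. Membrane proximity computes the Euclidean distance
transform of the ER boundary and scores each lysosome's boundary pixels
against a cutoff (default 30 nm — an EM-resolution criterion; a warning is
emitted when the cutoff is below one pixel, as on confocal masks it then
only distinguishes touching from non-touching). `is_near` uses an
any-boundary-point rule; the boundary-fraction metric covers the
what-fraction-of-membrane reading. Spot colocalization classifies each spot
by membership of its (optionally dilated) footprint in each mask —
`mask_a_only / mask_b_only / both / neither`.

## Tracking

Linking is frame-to-frame minimum-cost assignment (scipy's Hungarian
solver) on squared displacements, with links beyond `max_disp` forbidden via
a cost larger than any admissible total — this makes the solver maximize
the number of links first and minimize cost among those, matching the
exhaustive oracle the tests enumerate. The default bound is the size of one
tubular lysosome, 2.4 μm (20 px at 120 nm). Unmatched detections start new
tracks; `memory_frames` (default 0, i.e. no gap closing) lets a track
survive missed detections. Every detection belongs to exactly one track by
construction. Assignment ties are resolved deterministically by the solver;
with continuous positions exact ties have measure zero.

Per-track metrics: total traveled path length (sum of inter-frame
displacements — not net displacement, since total distance traveled is the
quantity of interest), duration, mean speed, `fast` (mean speed > 0.3 μm/s)
and `motile` (path > 1.2 μm over the acquisition; the motility window is
the full acquisition, one minute at one frame per second, rather than a
sliding window). Shape-transition events report mean instantaneous speeds
in a window (default 3 steps) on each side of a class change; the step
crossing the change counts toward the *after* side, and events without a
full window are dropped with a warning.

## Axonal dynamics

Kymographs sample each frame along the axon polyline at 1 px arclength
steps with linear interpolation, taking the maximum across `line_width_px`
samples along the local normal; columns run soma → distal, so a rightward
slope is anterograde. Direction classification uses signed net axial
displacement with a stationary band of ±1.2 μm per acquisition — the
fibroblast motility bound reused as the least arbitrary stand-in for a
by-eye kymograph criterion, and configurable. Reversing the path flips the
sign of every net displacement, so anterograde and retrograde swap exactly
while stationary counts are unchanged (a tested invariant). The axial
distribution statistic is the fraction of lysosomes within 50% of the
farthest lysosome's distance from the axon start.

## Screen

Train/test splits take `ceil(test_fraction · n)` test images per class
(default 15%; 742 and 735 images per class give 112 and 111 test images),
with membership determined by a seeded permutation. The classifier is a
pluggable interface; the built-in backend extracts 10 per-image morphometry
features (particle and tubule densities, tubular fraction,
circularity/eccentricity summaries, axis ratio capped at 50 to tame
degenerate thin objects, area statistics) and fits a standardized logistic
regression. Flip augmentation is available but off by default here: these
features are flip-invariant, so flipping only duplicates rows; the flag
exists for image-level backends (e.g. a CNN) plugged in through the same
interface. A deep transfer-learning backend is intentionally not bundled —
the screen logic, not the network, is the defined computation, and the
interface accepts any object with `fit`/`predict_ko_probability`.

Conditions are scored by the arithmetic mean knockout probability over
their images and by the tubulation index of their mean tubule density.
Gates derive from the positive-control siRNA scores: the default
`minimal_effect` rule gates at the weakest control (minimum control
probability, maximum control index), so a hit is "at least as effective as
the least effective positive control" on both readouts; the stricter
`all_controls` rule (maximum probability, minimum index) is available
behind a flag because an at-least-as-effective-as-controls criterion
admits both readings. Hits are
the intersection of the two single-readout pass sets, sorted by condition
id.

## What the tests show — and do not

All recovery claims (detection counts, ≥95% tubular classification recall
and precision, 5%/15% speed recovery at zero noise/SNR 5, exact transport
fractions, flip-control ordering) are established on synthetic scenes with
known truth, at the problem sizes stated in the tests (single-cell fields,
≤20 objects, ≤60 frames; linking verified against an exhaustive oracle on
≤4 particles × 5 frames over 100 random instances). Synthetic capsules and
discs are cleaner than real organelles: no out-of-focus light, no intensity
heterogeneity, no touching organelles, no photobleaching. Passing therefore
demonstrates correctness of the computations and their conventions, not
segmentation performance on real images — detector parameters in
particular should be re-tuned per dataset. No per-gene reference score
table ships with the package, so the screen suite validates the
scoring/gating machinery on constructed and simulated conditions rather
than on any real screen's hit list.
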