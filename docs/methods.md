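# Methods

This note records the models, parameter choices and numerical decisions
behind cardiomorph, and what the synthetic validation does and does not
demonstrate.

## The beating-heart phantom

Each chamber is an axis-aligned ellipsoid whose **axial (z) semi-axis** is
modulated sinusoidally,

    c(t) = c̄ (1 + α sin(2πt/T + φ)),   V(t) = (4/3) π a b c̄ (1 + α sin(2πt/T + φ)),

so chamber volume is sinusoidal with a closed form. With EDV = V̄(1+α) and
ESV = V̄(1−α) this implies EF = 200α/(1+α) percent exactly — the oracle used
throughout the tests. The two chambers contract in counter-phase
(φ_A − φ_V = π, as atrial emptying fills the ventricle); φ_A = +π/2 and
φ_V = −π/2 place both extrema exactly on sampled phases when one cycle is
sampled at N = 20 evenly spaced frames, so voxel-counted EDV/ESV are not
biased by phase discretization.

The default 4-dpf recipe is calibrated so that (i) the cycle-mean total
lumen is ≈9.5 × 10⁵ μm³ and (ii) atrial stroke volume is ≈3.6 × 10⁵ μm³:

| parameter | atrium | ventricle |
|---|---|---|
| mean semi-axes (z, y, x), μm | 35.2, 50, 57 | 36.5, 55, 63 |
| α | 3/7 (EF 60%) | 1/4 (EF 40%) |
| trabeculation | none | 4 μm amplitude, 8 lobes |

Chamber centers sit 130 μm apart along y in a 192 × 320 × 320 μm field
(96 × 160 × 160 voxels at the 2 μm acquisition pitch; 48 × 80 × 80 at the
4 μm fast profile). An 8 μm-radius cylindrical canal joins the centers, so
the lumen is always one 26-connected component — the precondition for the
morphological chamber split. Presets for 2/3/5 dpf scale all semi-axes by
0.75/0.90/1.05 and the trabeculation amplitude by 0/0.5/1.25; these growth
factors are the package's own invention (real per-day chamber dimensions
are not established), so cross-day trends computed on phantoms are
illustrative only.

**Trabeculation** — the spongy ridges on the inner ventricular wall from
~3 dpf — is modeled as a multiplicative radial perturbation of the implicit
surface, ρ ≤ 1 + ε sin(Lθ) with ε = amplitude / geometric-mean radius and
θ the azimuth. Averaging (1+ε sin Lθ)³ over angle gives an exact volume
inflation factor 1 + 3ε²/2 (≈1% at 4 dpf); because the factor is the same
at every phase, EF is untouched. The closed-form oracle exposes
`include_trabeculation` for tests that need voxel-exact expectations.

**Voxelization** labels a voxel by its center (no partial volumes); at 2 μm
pitch the voxel-counted volume of a default chamber is within ~0.5% of the
closed form and converges as the pitch shrinks.

**Rendering**: bright shell of 8 μm wall thickness around the lumen
(myocardium), dark lumen and background (0.04 of shell intensity),
attenuation exp(−z/300 μm) emulating imaging depth loss, Gaussian PSF blur
of 1 voxel, additive Gaussian noise of σ = 0.08 shell intensities, 8-bit
output. No refraction, scattering, or intra-stack motion is simulated.

**Training slices** emulate a hand-segmented corpus: 128 × 128 slices at
the 4 μm fast pitch, each with a random phase, a random axial position
spanning the entire heart (including pole slices that show only a
myocardial cap and slices just outside it — a real training set covers
every slice of the stack), ±10% isotropic size jitter and ±10 μm in-plane
displacement. Slices whose truth mask is empty are scored Dice = 1 against
an empty prediction and 0 against any stray pixel, which is the dominant
source of held-out score variance.

## U-net and training

Classic encoder–decoder with skip connections: per level two 3 × 3
convolutions + ReLU, then 2 × 2 max pooling; channels double and spatial
size halves per level (asserted programmatically via `level_ledger()`);
the expansive path mirrors with 2 × 2 stride-2 transposed convolutions and
concatenation of same-level encoder features; a 1 × 1 convolution +
sigmoid head emits per-pixel lumen probability, binarized at τ = 0.5.
Convolutions use same padding so the output mask matches the input size.
The full-scale configuration is 512 × 512 input, depth 4, 64 base features;
the desk-scale default is 128 × 128, depth 3, 8 base features, which one
CPU core trains in minutes.

Training: binary cross-entropy on logits, Adam (lr 10⁻³, batch 8), seeded
shuffling, 80/20 train/validation split (|train| = round(0.8 n), clamped so
neither side is empty). lr and batch size are package defaults — only the
loss and optimizer are inherited choices. The network layers are
implemented directly in NumPy (channels-last; each 3 × 3 convolution runs
as nine BLAS matmuls over the padded grid with shifted accumulation, and
its backward pass as the exact transpose of that scheme), with gradients
verified against float64 numerical differentiation.

At inference the network is fully convolutional: any slice with sides
divisible by 2^depth is accepted. `predict_padded` reflect-pads slices by
24 px before prediction so hearts touching the frame edge keep the
background context seen in training, then crops back.

Mask preparation utilities mirror a manual-segmentation workflow: Gaussian
smoothing of hand masks with a 2.0 μm kernel (σ = 2.0 μm / pixel pitch,
re-binarized at 0.5 — removes single-pixel specks, moves large boundaries
less than a pixel), and contour interpolation between sparse hand-segmented
z-slices by linear interpolation of signed distance transforms.

## Cardiac period estimation

The period is the first peak of the autocorrelation of a 1-D trace (e.g.
summed lumen area per frame). Two numerical choices matter:

1. **Window-normalized autocorrelation.** The plain finite-window estimator
   of a sinusoid carries an additive edge term ~sin(ωk)/(ω(n−k)) that
   shifts the correlation peak by ≈1/(ω²(n−k)) samples — ~3 samples
   (0.33 ms) for a 250 ms beat sampled at 0.1 ms for 20 cycles, larger than
   the ±0.3 ms phase-lock window itself. The trace is therefore
   Hann-windowed and the raw correlation divided by the window's own
   autocorrelation, which suppresses the edge term; the pure-tone error
   drops to ~10⁻⁵ ms.
2. **Fundamental selection.** A periodic trace correlates equally at T, 2T,
   3T…, so the raw argmax under noise may land on a multiple. Lags whose
   correlation comes within 10% (of the in-range dynamic range) of the
   maximum are clustered into contiguous runs and the first run wins — the
   smallest-period tie-break, implemented robustly.

The peak is refined to sub-sample precision with a least-squares parabola
over ±2.5% of the period (wider than three points to average correlation
noise; still well inside one lobe, so unbiased). Beat-to-beat regularity:
the correlation peak nearest each multiple k·T̂ is located the same way and
the residual is the worst |lag_k − k·T̂|; the recording is flagged
phase-locked iff residual ≤ δ, default δ = 0.3 ms. Whether that window
should bound the period error or inter-slice phase mismatch is an open
modeling choice; the period-residual reading is implemented. The full
slice-wise retrospective gating used to assemble 4D stacks from free-running
acquisitions is out of scope; `bin_phases` assumes a known/estimated period.

## Chamber splitting

Erode the lumen with a radius-1 ball (the 6-connected cross) until the
26-connected component count reaches 2 (26-connectivity avoids spurious
early fracture across diagonal necks); keep the two largest seeds; dilate
each by the same number of steps; intersect with the original mask. Voxels
claimed by both seeds or by neither are assigned by geodesic distance
within the mask — simultaneous ring-growing of both labels constrained to
the lumen, with same-ring ties going to the larger seed — so label support
equals the input mask exactly and labels never jump across background.
A mask that erodes to nothing (no neck: e.g. a solid sphere), or exceeds 50
iterations, raises `UnsplittableMaskError`.

Identity: per frame, "larger is ventricle" by default, or a user-supplied
ventricle-centroid hint. Across a cine the split is recomputed per frame
(whether the original workflow split once and propagated is unknown; per
frame is the conservative choice), positional labels are kept consistent by
nearest-centroid matching to frame 0, and the size rule is applied to the
**cycle-mean** track volumes: the atrium at peak filling can transiently
exceed the ventricle — in the default phantom it does — so a frame-0 size
comparison would misname the chambers whenever the cine starts there.

## Mechanics and validation

Volumes are voxel counts × voxel volume; EDV/ESV are the extrema over the
one binned cycle (ties to the earliest phase), not per-beat averages — the
synchronized cine holds exactly one canonical cycle. Dice of two empty
masks is defined as 1 (the formula's 0/0 case) and logged when triggered;
the evaluator reports Dice both per 2D slice and per 3D frame, since
either convention appears in practice.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that the implementation is internally correct
(voxel volumes converge to closed forms, the split conserves and localizes
to the canal, the network learns the phantom's appearance to a held-out
per-slice Dice above 0.95 under the standard protocol — with a heavy lower
tail from tiny polar cross-sections, while per-3D-frame Dice is ≈0.97 —
EF is recovered to within a point from masks, and the full pipeline
reproduces truth-mask EF to within ~0.5 points at the fast profile). They do not demonstrate performance on real LSFM data: the
phantom's geometry is smooth and axis-aligned, its noise is Gaussian and
stationary, there is no motion blur, no scattering, no inter-individual
variability, and the trained network has only ever seen the phantom's own
appearance model. Cross-day (2–5 dpf) trends use invented growth factors
and are illustrative only.

## Problem sizes

The default test and acceptance profile uses the 4 μm fast phantom
(48 × 80 × 80 voxels), 200 training slices at 128 × 128, the reduced
network (depth 3, 8 base features) and 40 training epochs; the 2 μm
acquisition-pitch phantom is used wherever volumes are compared against
printed calibration values. The full-scale network (512 × 512, depth 4,
64 base features) is constructible and shape-verified but not trained in
the test suite.
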