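# Methods

This note documents the models, conventions and numerical choices behind
`edgecooc`, in the order the pipeline applies them.

## Log-Gabor dictionary

Each filter is defined in the frequency domain as the product of a radial
and an angular term,

    K(f, a) = exp(−log²(f/f₀) / 2β²) · exp(−wrap(a − a₀)² / 2γ²),

with `f₀` the scale's center frequency, `β` the log-frequency width, `a₀`
the orientation of the edge's frequency energy (perpendicular to the edge
itself) and `γ` the angular width.  The radial term is identically zero at
`f = 0`, so the dictionary carries no DC component and constant images
produce no response.  The angular Gaussian is one-sided (centered at `a₀`
only, not at `a₀ + π`), which makes the spatial kernels complex quadrature
pairs: the real part is the even-symmetric (line) receptive field, the
imaginary part the odd-symmetric (step-edge) one.  Every kernel is
normalized to unit energy (Σ|K|² = 1 over frequency bins).

Defaults (all configurable through `FilterParams` / the `filterbank`
config section):

| parameter | default | meaning |
|---|---|---|
| `n_orientations` | 8 | edge orientations evenly spaced over [0, π) |
| `n_scales` | 5 | octave-like scale levels |
| `base_frequency` | 0.25 cy/px | finest-scale peak frequency |
| `scale_ratio` | 2 | ratio of successive center frequencies (octaves) |
| `bandwidth_freq` | 0.4 | log-frequency Gaussian width (≈1.5 octaves) |
| `bandwidth_theta` | π/16 rad | angular Gaussian width |
| `dtype` | complex128 | `complex64` roughly halves analysis time |

These are standard V1-like values; the cortical literature constrains
them only loosely, so they are explicit package defaults rather than
measured quantities.  Images are mean-subtracted before analysis
(the zero-DC dictionary cannot represent the mean) and filtering is
performed by frequency-domain products, i.e. with circular boundary
conditions.

## Matching pursuit

The linear coefficient stack C(s, o, x, y) — inner products of the image
with every atom — is over-complete, so the edge list is obtained greedily:
repeatedly select the atom with the largest |coefficient|, subtract its
projection from the residual, and re-derive the coefficients of the new
residual.  Ties are broken toward the lowest (scale, orientation, y, x)
in lexicographic order, making extraction fully deterministic.

Because atoms are quadrature pairs with one-sided spectra, the even and
odd parts are orthogonal with equal energy ½; the projection subtracted
for a complex coefficient `c` is `2·Re(c·atom)` and removes exactly
`2|c|²` of residual energy.  Amplitudes are recorded as `√2·|c|` so that

    E_initial = Σ amplitudeₖ² + E_residual

holds to machine precision (the test suite enforces 1e−4 relative; in
practice the gap is ~1e−10).  The residual is maintained as a spectrum
and updated analytically per selection — this *is* the exact full
recomputation, organized to cost one stacked inverse FFT per iteration.
Extraction stops at the edge budget (default 2048) or when the residual
energy falls to the target fraction of the initial energy (default 5%),
whichever comes first; exhausting the budget without reaching the target
sets a `target_not_reached` flag rather than raising.

Amplitudes decrease along the selection order up to the small
fluctuations that non-orthogonal atoms permit; residual energy, in
contrast, decreases strictly at every step.

## Pair geometry and folding conventions

For an edge pair (A, B): `d` is the center distance (absolute pixels by
default; optionally in units of the pair's geometric-mean wavelength,
which makes the statistics scale-invariant), `θ = θ_B − θ_A` folded to
[−π/2, π/2), `σ` the log₂ scale ratio, and `ψ` the symmetrized relative
angle.  Edges are unoriented (orientation modulo π), and the half-angle
of a modulo-π quantity is only defined modulo π/2; the naive
`fold(φ) − fold(θ)/2` therefore lands on the wrong branch for tangent
separations beyond 90°.  `edgecooc` instead folds the two chord angles
separately before averaging:

    a = fold(θ_A − chord),  b = fold(θ_B − chord),  ψ = fold(−(a + b)/2),

which is exactly zero for edges tangent to a common circle at *any*
separation, exactly ±π/2 for parallel offset edges, exactly invariant
under swapping A and B, and agrees with φ − θ/2 modulo π/2.  Coincident
centers (d = 0) take φ = ψ = 0 by convention and are flagged.

## Co-occurrence histograms and chevron maps

Histograms accumulate over all unordered pairs of edges inside a central
circular mask (default radius 0.45 × min(image side); border edges are
discarded to avoid boundary artifacts).  Default binning: 6 log-spaced
`d` bins on [2 px, mask radius], 12 × 12 angular bins on [−π/2, π/2)²,
5 `σ` bins on [−2, 2] octaves (values beyond the range are clipped into
the end bins; pairs outside the `d` range are dropped and counted
separately, keeping `p` a proper distribution over the binned domain).
Pairs are weighted by the product of the two edge amplitudes (an
`"uniform"` mode is available; the mode is stored in the metadata).

Each pair enters symmetrically under the two choices of reference edge:
half its weight at (d, ψ, θ, σ) and half at (d, ψ, −θ, −σ).  This makes
the histogram exactly independent of edge ordering and exactly invariant
under global translations and rotations (and, with scale-normalized
distance, global rescalings).  A consequence worth knowing: a single
generic pair occupies two mirror cells at half weight each.

The chevron map is the (ψ, θ) marginal; ratio maps divide two chevron
maps cell-wise after adding a small ε (default 1e−6) to every cell and
renormalizing, so empty reference cells cannot divide by zero.  Note that
0 lies on a bin *edge* of the 12-bin angular grids, so "the collinear
cell" in practice is the 2 × 2 central block, and exactly-collinear
fixtures concentrate in its (ψ ≥ 0, θ ≥ 0) member.

## Divergences and the factorization test

KL divergence smooths both arguments additively (default pseudo-count
ε = 1/(n_bins × n_pairs)) and renormalizes; Jensen–Shannon needs no
smoothing (its mixture covers both supports) and is bounded by ln 2, with
√JS a metric.  All divergences are reported in nats.

The factorization test compares the joint 4-D table against the product
of its four 1-D marginals and against `p(d, σ)·p(ψ, θ)`.  The pair
factorization nests the full product, so its KL gap is never larger
(the difference equals I(d; σ) + I(ψ; θ) ≥ 0); a small pair gap licenses
analyzing the angular structure separately from the distance/scale
structure, which is what the chevron map does.

d′ between two groups of scores uses the pooled-SD two-sample convention
`(m₁ − m₂) / s_pooled`.  The false-alarm analysis computes, per image,
`Δ = KL(h_image ‖ h̄_A) − KL(h_image ‖ h̄_B)` against the two class-mean
histograms; Δ is antisymmetric under swapping class roles, and group
separations are summarized by d′.

## Classification

Per-image feature vectors are L1-normalized histograms: FO (12
orientation bins), CM (144 chevron cells), SO (the full 4-D table,
C-order flattened with the axis order recorded).  The classifier is a
linear-kernel SVM; rows are L2-normalized before the kernel because
probability vectors spread over thousands of cells have vanishing dot
products, which would otherwise leave a fixed C swamped by regularization
at fine binnings.  The default C = 10 puts the SVM in the regime where it
reliably fits its training folds at these feature dimensionalities; an
underfitting C skews near-chance predictions toward a single class
(predictions ~68% one-sided and train accuracy ~64% at C = 1 on the null
benchmark), which biases the F1 statistic well below the 50% chance
level.  C is configurable.  Performance is measured over 20
stratified 80/20 train/test resamples (fresh split per resample, seeds
derived from one master seed) and reported as F1 in percent.

F1 is computed per class as 2TP/(2TP + FP + FN) and macro-averaged over
the two class roles by default: the synthetic benchmarks have no
canonical "positive" class, and the macro average is symmetric under
relabeling — near chance, a single-class F1 is dominated by the
degenerate all-positive solution (F1 = 2/3) and fluctuates several-fold
more across permutation nulls.  When one class is the designated
detection target, `positive_label=` restores the single-class score.

The noise-degradation condition adds white Gaussian noise with power
`signal_power / snr` (default `snr = 1`, i.e. noise power equal to image
power — the "SNR halved" condition with the clean image as its own
reference); as `snr → ∞` the image is returned unchanged.

## Synthetic fixtures

Images are sums of unit-energy log-Gabor strokes (odd-symmetric polarity)
laid along chains of constant curvature: each contour draws a curvature κ
from N(mean, sd) with random sign, and strokes sit *exactly* on the
resulting arc with tangent orientations, spaced 0.75 wavelengths apart,
so within-chain pair geometry is exactly collinear (κ = 0) or exactly
co-circular (κ ≠ 0).  Amplitudes get log-normal jitter; strokes leaving
the frame are clipped (count logged).  An optional 1/f-amplitude random
background adds natural-image-like clutter at a chosen RMS relative to
the strokes.  Because strokes come from the same atom family the coder
uses, planted parameters are recoverable near-exactly on clean
backgrounds, which the recovery tests exploit.

Benchmark study conditions (fixed in `edgecooc.bench`): classification
benchmarks use 96 × 96 images, a 4-scale/8-orientation single-precision
bank (the default fifth scale is coarser than a 96 px frame usefully
supports), 256 edges/image, 100 images per class, 6 contours × 10
strokes at the 8 px wavelength, background 0.2 relative RMS; curvature
(mean, sd) is (0.02, 0.01) for the chance-control class, (0, 0.002) for
the straight class and (0.05, 0.015) — radius ≈ 20 px — for the curved
class.  The residual benchmark uses a 256 × 256 image with 30 planted
bank atoms over a 0.2-RMS 1/f background and the default 2048-edge /
5%-residual budget.  These sizes keep a full benchmark to a few minutes
on one core while leaving the reported statistics stable.

What the fixtures do *not* emulate: photometric structure of real scenes
(occlusion, shading, texture), broadband edge spectra (strokes live at
one scale), and the long-tailed amplitude statistics of natural images.
Passing benchmarks therefore demonstrate that the pipeline measures and
discriminates contour-curvature statistics correctly — not that any
particular natural-image category is separable at a given F1.

## Known limitations

* Circular boundary conditions wrap filter responses; the circular mask
  removes most boundary pairs but extraction itself sees wrapped edges.
* Matching pursuit is the plain greedy variant (no orthogonalization);
  coefficient magnitudes are only approximately monotone.
* The orientation grid quantizes extracted θ to π/n_orientations; tests
  that compare extracted against planted angular statistics use a
  24-orientation bank to keep quantization below the bin width.
* d′ conventions differ across the literature; the pooled-SD two-sample
  form is used here.
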