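# edgecooc

Sparse oriented-edge extraction and **second-order edge co-occurrence
statistics** for image categorization.

Natural images are not random collections of edges: oriented elements tend
to align along lines and smooth curves, and the *statistics* of how edge
pairs co-occur — the empirical "association field" — differ systematically
between scene categories.  Scenes dominated by man-made structure carry an
excess of collinear configurations; scenes containing animals carry more
curved, co-circular and converging configurations.  `edgecooc` implements
the full measurement pipeline needed to quantify and exploit this:

1. **Log-Gabor dictionary** (`edgecooc.filterbank`) — an over-complete bank
   of quadrature band-pass filters over scales × orientations, modeling
   V1 simple-cell receptive fields (zero DC response, Gaussian profile on
   the log-frequency axis).
2. **Matching pursuit** (`edgecooc.sparse`) — greedy sparse coding that
   converts an image into a discrete list of edges (position, orientation
   θ, scale, amplitude), run until a target residual energy (default 5%)
   or an edge budget is reached.  Energy bookkeeping is exact:
   `initial = Σ amplitude² + residual`.
3. **Association field** (`edgecooc.geometry`, `edgecooc.cooccurrence`) —
   the 4-D histogram `p(d, ψ, θ, σ)` over all unordered pairs of edges
   inside a circular mask, where `d` is center distance, `θ` the relative
   orientation, `σ` the log₂ scale ratio, and `ψ` the *symmetrized
   relative angle* (ψ = φ − θ/2 with φ the azimuth of one edge seen from
   the other, folded so that ψ = 0 exactly characterizes edges tangent to
   a common circle).  Marginalizing over `(d, σ)` gives the **chevron
   map** `p(ψ, θ)`; ratios of chevron maps visualize class contrasts.
4. **Divergences** (`edgecooc.divergence`) — Kullback–Leibler and
   Jensen–Shannon divergences between histograms, a factorization test
   (is `p(d, σ)·p(ψ, θ)` a good approximation of the joint?), and the
   pooled-SD d′ separation of per-image KL affinities to two class means.
5. **Categorization** (`edgecooc.classify`) — linear-SVM classification of
   per-image feature vectors: FO (first-order orientation histogram), CM
   (chevron map) or SO (full 4-D histogram), scored by F1 over 20
   stratified train/test resamples (50% = chance), with a halved-SNR
   noise-degradation condition.
6. **Synthetic fixtures** (`edgecooc.synthetic`) — labeled image classes
   made of log-Gabor stroke chains with controlled contour curvature (the
   class contrast), with planted ground truth, so every stage is testable
   without any external image database.

See `docs/methods.md` for the model details, parameter defaults, and the
design decisions behind the conventions.

## Worked example

```python
import numpy as np
from edgecooc import (FilterParams, build_filterbank, extract_edges,
                      cooccurrence_histogram, chevron_map)
from edgecooc.synthetic import FixtureSpec, generate_contour_image

# one synthetic image: 6 curved contours (radius ~20 px) on a 1/f background
spec = FixtureSpec(image_shape=(96, 96), n_contours=6, n_strokes_per_contour=10,
                   stroke_scale_index=1, curvature_mean=0.05, curvature_sd=0.015,
                   background_amplitude=0.2, seed=5)
image, truth = generate_contour_image(spec)

bank = build_filterbank(FilterParams(n_scales=4, image_shape=(96, 96)))
edges, residual = extract_edges(image, bank, n_edges=256, residual_target=0.05)
print(f"{len(edges)} edges, residual energy {100*edges.residual_fraction:.1f}%")

h = cooccurrence_histogram(edges)          # p(d, psi, theta, sigma)
cm = chevron_map(h)                        # p(psi, theta), 12 x 12
centre = cm.values[5:7, 5:7].sum()
print(f"histogram over {h.n_pairs} pairs; central (collinear) block mass {centre:.3f}")
```

Output:

```
85 edges, residual energy 5.0%
histogram over 1650 pairs; central (collinear) block mass 0.028
```

The extraction hits the 5% residual-energy criterion after 85 edges
(well inside the 256-edge budget) and the 4-D histogram accumulates 1650
masked edge pairs.  For a *curved* image like this one, the central
collinear block holds only ~3% of the angular probability mass — on a
straight-contour image the same block dominates, which is exactly the
contrast the SVM exploits and the chevron ratio map displays.

A command-line pipeline wraps the same stages:

```sh
edgecooc synth    --out data --preset straight-vs-curved --n-per-class 20
edgecooc extract  --in data --out edges
edgecooc stats    --in edges --out hists
edgecooc classify --in hists --manifest data/manifest.csv --mode SO --out report.json
# after splitting the histogram files into per-class directories:
edgecooc compare  --in hists_curved --ref hists_straight --out cmp
```

`classify` prints the mean and spread of the 20 resampled F1 scores;
`compare` writes the KL/JS divergence report, the factorization gaps, the
chevron ratio map (CSV + rendered PNG), and the per-image KL-affinity d′
between the two sets.

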