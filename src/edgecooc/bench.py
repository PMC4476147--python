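"""Reference benchmarks on the synthetic fixtures.

These functions tie the whole pipeline together under fixed, documented
study conditions and are shared by the test suite and the reproduction
script.  Problem sizes are desk-scale: the residual benchmark runs one
256 x 256 image through the full default edge budget, while the
classification benchmarks use 96 x 96 images with a 256-edge budget and
100 images per class, which keeps a full benchmark to a few minutes on a
single core while leaving the statistics stable (the F1 spread across
resamples is what the benchmark measures).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .classify import ClassificationResult, add_noise, crossval_f1, features_from_stats, make_features
from .cooccurrence import Binning, cooccurrence_histogram, default_binning
from .filterbank import FilterBank, FilterParams, build_filterbank
from .geometry import pairwise_geometry
from .sparse import EdgeElement, EdgeList, extract_edges, residual_energy
from .synthetic import FixtureSpec, generate_arrays, planted_atom_image

__all__ = [
    "residual_benchmark",
    "classification_benchmark",
    "cocircular_psi_max",
    "bench_bank",
    "BENCH_SHAPE",
    "CHANCE_SPEC",
    "STRAIGHT_SPEC",
    "CURVED_SPEC",
]

# -- study conditions for the classification benchmarks ---------------------
BENCH_SHAPE: Tuple[int, int] = (96, 96)
_BENCH_FIXTURE = dict(
    image_shape=BENCH_SHAPE,
    n_contours=6,
    n_strokes_per_contour=10,
    stroke_scale_index=1,  # 8-pixel wavelength at base frequency 0.25
    amplitude_jitter=0.3,
    background_amplitude=0.2,
)
# statistically identical classes (chance-level control)
CHANCE_SPEC = FixtureSpec(curvature_mean=0.02, curvature_sd=0.01, **_BENCH_FIXTURE)
# separable benchmark: straight contours vs arcs of radius ~20 px
STRAIGHT_SPEC = FixtureSpec(curvature_mean=0.0, curvature_sd=0.002, **_BENCH_FIXTURE)
CURVED_SPEC = FixtureSpec(curvature_mean=0.05, curvature_sd=0.015, **_BENCH_FIXTURE)


def bench_bank(image_shape: Tuple[int, int] = BENCH_SHAPE) -> FilterBank:
    """Bank used by the classification benchmarks: default V1-like
    parameters, 4 scales (the coarsest default scale is wider than a
    96-pixel frame usefully supports), single precision for speed."""
    return build_filterbank(
        FilterParams(n_scales=4, image_shape=image_shape, dtype="complex64")
    )


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2 ** 31))


def residual_benchmark(
    seed: int = 42,
    image_shape: Tuple[int, int] = (256, 256),
    n_atoms: int = 30,
    background_amplitude: float = 0.2,
    n_edges: int = 2048,
    residual_target: float = 0.05,
) -> Dict[str, float]:
    """Greedy-coding quality control on a natural-like synthetic image.

    Plants ``n_atoms`` bank-matched strokes on a 1/f background, runs
    matching pursuit with the default budget, and measures the residual
    energy fraction by explicit reconstruction.  Returns the residual as a
    percentage of the initial (mean-subtracted) image energy.
    """
    bank = build_filterbank(FilterParams(image_shape=image_shape, dtype="complex64"))
    image, _truth = planted_atom_image(
        bank, n_atoms=n_atoms, seed=seed, background_amplitude=background_amplitude
    )
    edges, _res = extract_edges(
        image, bank, n_edges=n_edges, residual_target=residual_target, source_id=f"resbench-{seed}"
    )
    measured = residual_energy(image, edges, bank)
    return {
        "residual_pct": 100.0 * measured,
        "residual_pct_tracked": 100.0 * edges.residual_fraction,
        "n_edges_used": float(len(edges)),
        "target_not_reached": float(edges.target_not_reached),
    }


def _so_features(
    images: List[np.ndarray],
    bank: FilterBank,
    binning: Binning,
    n_edges: int,
    noise_snr: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    rows = []
    for i, img in enumerate(images):
        if noise_snr is not None:
            img = add_noise(img, snr=noise_snr, seed=_derive_seed(seed, 1000 + i))
        edges, _ = extract_edges(img, bank, n_edges=n_edges, residual_target=0.01)
        h = cooccurrence_histogram(edges, binning=binning)
        rows.append(make_features(features_from_stats(h), "SO").values)
    return np.asarray(rows)


def classification_benchmark(
    kind: str = "separable",
    seed: int = 7,
    n_per_class: int = 100,
    n_edges: int = 256,
    noise_snr: Optional[float] = None,
    n_resamples: int = 20,
) -> ClassificationResult:
    """SVM cross-validation on a synthetic two-class benchmark (SO features).

    ``kind = "chance"`` draws both classes from the same fixture spec
    (different seeds), so any mean F1 away from 50% reflects classifier
    bias; ``kind = "separable"`` contrasts straight against curved
    contours.  20 stratified 80/20 resamples by default.
    """
    if kind == "chance":
        class_specs = {"classA": CHANCE_SPEC, "classB": CHANCE_SPEC}
    elif kind == "separable":
        class_specs = {"straight": STRAIGHT_SPEC, "curved": CURVED_SPEC}
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")

    data = generate_arrays(class_specs, n_per_class, seed=_derive_seed(seed, 1))
    labels = [label for label, _, _ in data]
    images = [img for _, img, _ in data]
    bank = bench_bank()
    mask_radius = 0.45 * min(BENCH_SHAPE)
    binning = default_binning(mask_radius)
    X = _so_features(images, bank, binning, n_edges, noise_snr=noise_snr, seed=seed)
    return crossval_f1(
        X, labels, n_resamples=n_resamples, seed=_derive_seed(seed, 2), mode="SO"
    )


def ratio_benchmark(
    seed: int = 7,
    n_per_class: int = 20,
    n_edges: int = 256,
) -> Dict[str, object]:
    """Class-contrast chevron ratio map: curved vs straight fixtures.

    Extracts edges from both classes, averages the per-image 4-D
    histograms within each class, and forms the chevron ratio map
    (curved / straight).  Returns the map together with the designated
    cells: the central 2x2 collinear block around (psi, theta) = (0, 0)
    (0 lies on a bin edge) and the co-circular band (central psi rows,
    theta well away from 0).  Curved contours should enrich the
    co-circular band and deplete the collinear block.
    """
    from dataclasses import replace as _rep

    data = generate_arrays(
        {"straight": STRAIGHT_SPEC, "curved": CURVED_SPEC}, n_per_class,
        seed=_derive_seed(seed, 3),
    )
    bank = bench_bank()
    binning = default_binning(0.45 * min(BENCH_SHAPE))
    tables: Dict[str, list] = {"straight": [], "curved": []}
    for label, img, _ in data:
        edges, _r = extract_edges(img, bank, n_edges=n_edges, residual_target=0.01)
        tables[label].append(cooccurrence_histogram(edges, binning=binning).table)

    def as_hist(label: str):
        mean = np.mean(tables[label], axis=0)
        return CoocHistogram(
            table=mean, binning=binning, n_pairs=1, normalized=False,
        ).normalize()

    from .cooccurrence import CoocHistogram, ratio_map

    rm = ratio_map(as_hist("curved"), as_hist("straight"))
    i0, j0 = rm.cell(-1e-9, -1e-9)
    i1, j1 = rm.cell(+1e-9, +1e-9)
    collinear = rm.values[i0 : i1 + 1, j0 : j1 + 1]
    cocircular = np.concatenate(
        [rm.values[i0 : i1 + 1, : j0 - 1].ravel(), rm.values[i0 : i1 + 1, j1 + 2 :].ravel()]
    )
    return {
        "ratio_map": rm,
        "collinear_cells": collinear,
        "cocircular_cells": cocircular,
        "collinear_mean": float(collinear.mean()),
        "cocircular_median": float(np.median(cocircular)),
    }


def cocircular_psi_max(
    radius: float = 50.0,
    separations_deg: Optional[np.ndarray] = None,
) -> float:
    """Max |psi| over edge pairs tangent to a common circle.

    Tangent pairs are constructed analytically at polar-angle separations
    of 10..170 degrees by default; the symmetrized relative angle psi is
    identically zero for such pairs, so this measures the numerical error
    of the geometry conventions.
    """
    if separations_deg is None:
        separations_deg = np.arange(10.0, 171.0, 10.0)
    worst = 0.0
    for beta_deg in separations_deg:
        beta = np.deg2rad(float(beta_deg))
        a = EdgeElement(x=radius, y=0.0, theta=np.pi / 2 % np.pi, scale_index=0, amplitude=1.0)
        b = EdgeElement(
            x=radius * np.cos(beta),
            y=radius * np.sin(beta),
            theta=(np.pi / 2 + beta) % np.pi,
            scale_index=0,
            amplitude=1.0,
        )
        g = pairwise_geometry(a, b)
        worst = max(worst, abs(g.psi))
    return worst
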