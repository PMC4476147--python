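"""Synthetic labeled image classes with controlled contour curvature.

Generates grayscale images made of smooth contours rendered as chains of
oriented log-Gabor strokes, with the planted stroke parameters returned as
ground truth.  Because the strokes are drawn from the same atom family the
sparse-coding stage uses, matching pursuit can recover them near-exactly,
which makes parameter-recovery and statistics-convergence tests sharp.

Curvature is the control knob that separates classes: near-zero curvature
yields straight contours whose pairwise geometry concentrates at the
collinear cell (psi = 0, theta = 0), while high curvature yields circular
arcs whose pair geometry is co-circular (psi close to 0 across many
relative orientations theta).  This emulates the documented contrast
between image categories dominated by long straight lines and categories
with curved, converging contours.

An optional 1/f-spectrum background adds natural-image-like clutter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.fft as _fft

from .filterbank import FilterBank, FilterParams, _loggabor_spectrum, build_filterbank
from .sparse import EdgeList, default_mask_radius, write_edge_csv

__all__ = [
    "FixtureSpec",
    "render_strokes",
    "one_over_f_background",
    "generate_contour_image",
    "planted_atom_image",
    "generate_arrays",
    "generate_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image class.

    Curvature is in 1/pixels (inverse radius of the osculating circle);
    each contour draws a curvature magnitude from N(curvature_mean,
    curvature_sd) (negated with probability 1/2) and keeps it constant
    along the chain, so high-curvature contours lie on circles.
    ``background_amplitude`` is the RMS of the 1/f background relative to
    the RMS of the rendered strokes (0 disables it).  Same spec + seed
    always produces bit-identical images.
    """

    image_shape: Tuple[int, int] = (256, 256)
    n_contours: int = 8
    curvature_mean: float = 0.02
    curvature_sd: float = 0.01
    n_strokes_per_contour: int = 12
    stroke_scale_index: int = 2
    stroke_spacing: Optional[float] = None  # pixels; default 0.75 * wavelength
    stroke_amplitude: float = 1.0
    amplitude_jitter: float = 0.3
    background_amplitude: float = 0.0
    seed: int = 0

    def filter_params(self, **overrides) -> FilterParams:
        return FilterParams(image_shape=self.image_shape, **overrides)


def render_strokes(
    params: FilterParams,
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    scale_index: np.ndarray,
    amplitude: np.ndarray,
    phase: np.ndarray,
) -> np.ndarray:
    """Render oriented strokes as unit-energy log-Gabor atoms.

    Unlike the bank (which quantizes orientation into channels), strokes
    may take any continuous orientation and sub-pixel position; each is
    synthesized directly in the frequency domain.
    """
    h, w = params.image_shape
    fy = _fft.fftfreq(h)[:, None]
    fx = _fft.fftfreq(w)[None, :]
    fgrid = np.hypot(fx, fy)
    angle = np.arctan2(fy, fx)
    freqs = params.center_frequencies
    rootn = np.sqrt(h * w)
    acc = np.zeros((h, w), dtype=complex)
    for k in range(len(x)):
        spec = _loggabor_spectrum(
            fgrid, angle, freqs[int(scale_index[k])], float(theta[k]),
            params.bandwidth_freq, params.bandwidth_theta,
        )
        spec = spec / np.sqrt(np.sum(spec * spec))
        ramp = np.exp(-2j * np.pi * (fx * x[k] + fy * y[k]))
        c = (amplitude[k] / np.sqrt(2.0)) * np.exp(1j * phase[k])
        acc += c * rootn * spec * ramp
    return 2.0 * np.real(_fft.ifft2(acc))


def one_over_f_background(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS random field with a 1/f amplitude spectrum (zero mean)."""
    h, w = shape
    white = rng.standard_normal((h, w))
    spectrum = _fft.fft2(white)
    f = np.hypot(_fft.fftfreq(w)[None, :], _fft.fftfreq(h)[:, None])
    shaping = np.zeros_like(f)
    shaping[f > 0] = 1.0 / f[f > 0]
    bg = np.real(_fft.ifft2(spectrum * shaping))
    return bg / bg.std()


def _truth(spec_shape, xs, ys, ths, scs, amps, phs, source_id: str) -> EdgeList:
    order = np.argsort(-np.asarray(amps), kind="stable")
    return EdgeList(
        x=np.asarray(xs, dtype=float)[order],
        y=np.asarray(ys, dtype=float)[order],
        theta=np.asarray(ths, dtype=float)[order] % np.pi,
        scale_index=np.asarray(scs, dtype=int)[order],
        amplitude=np.asarray(amps, dtype=float)[order],
        phase=np.asarray(phs, dtype=float)[order],
        image_shape=tuple(spec_shape),
        mask_radius=default_mask_radius(spec_shape),
        source_id=source_id,
        residual_fraction=float("nan"),
    )


def generate_contour_image(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    source_id: str = "",
) -> Tuple[np.ndarray, EdgeList]:
    """Draw one image of smooth stroke chains; return it with ground truth.

    Contours are chains of strokes laid along arcs of constant curvature:
    the tangent direction advances by curvature * spacing between
    successive strokes.  Strokes whose center leaves the frame (with a
    half-wavelength margin) are clipped and their count logged.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = spec.filter_params()
    h, w = spec.image_shape
    lam = 1.0 / params.center_frequencies[spec.stroke_scale_index]
    spacing = spec.stroke_spacing if spec.stroke_spacing is not None else 0.75 * lam
    margin = lam / 2.0

    xs: List[float] = []
    ys: List[float] = []
    ths: List[float] = []
    amps: List[float] = []
    n_clipped = 0
    for _ in range(spec.n_contours):
        kappa = rng.normal(spec.curvature_mean, spec.curvature_sd)
        kappa *= rng.choice([-1.0, 1.0])
        # start inside the central region so most of the chain stays visible
        r0 = 0.35 * min(h, w) * np.sqrt(rng.uniform())
        a0 = rng.uniform(0, 2 * np.pi)
        px = (w - 1) / 2.0 + r0 * np.cos(a0)
        py = (h - 1) / 2.0 + r0 * np.sin(a0)
        phi0 = rng.uniform(0, 2 * np.pi)
        k_arc = np.arange(spec.n_strokes_per_contour)
        if abs(kappa) < 1e-9:
            cx = px + k_arc * spacing * np.cos(phi0)
            cy = py + k_arc * spacing * np.sin(phi0)
            tangents = np.full(len(k_arc), phi0)
        else:
            # exact arc: strokes lie on a circle of radius 1/kappa, so
            # within-chain pairs are exactly co-circular
            ccx = px - np.sin(phi0) / kappa
            ccy = py + np.cos(phi0) / kappa
            tangents = phi0 + kappa * spacing * k_arc
            cx = ccx + np.sin(tangents) / kappa
            cy = ccy - np.cos(tangents) / kappa
        for sx, sy, sth in zip(cx, cy, tangents):
            if margin <= sx <= w - 1 - margin and margin <= sy <= h - 1 - margin:
                xs.append(float(sx))
                ys.append(float(sy))
                ths.append(float(sth % np.pi))
                amps.append(
                    spec.stroke_amplitude * float(np.exp(spec.amplitude_jitter * rng.standard_normal()))
                )
            else:
                n_clipped += 1
    if n_clipped:
        logger.debug("%s: clipped %d strokes leaving the frame", source_id or "contour image", n_clipped)

    n = len(xs)
    scs = np.full(n, spec.stroke_scale_index, dtype=int)
    phs = np.full(n, np.pi / 2)  # odd-symmetric (step-edge) polarity
    image = render_strokes(params, np.asarray(xs), np.asarray(ys), np.asarray(ths), scs,
                           np.asarray(amps), phs)
    if spec.background_amplitude > 0:
        stroke_rms = image.std() if n else 1.0
        image = image + spec.background_amplitude * stroke_rms * one_over_f_background(
            spec.image_shape, rng
        )
    truth = _truth(spec.image_shape, xs, ys, ths, scs, amps, phs, source_id)
    return image, truth


def planted_atom_image(
    bank: FilterBank,
    n_atoms: int = 30,
    seed: int = 42,
    background_amplitude: float = 0.2,
    min_separation: float = 0.0,
    scale_indices: Optional[Tuple[int, ...]] = None,
) -> Tuple[np.ndarray, EdgeList]:
    """Image made of atoms drawn from the bank itself, plus 1/f clutter.

    Atoms sit on integer positions at bank orientations, so the greedy
    coder can in principle recover them exactly; ``min_separation``
    (pixels) optionally enforces well-separated placements for recovery
    tests.  Amplitudes are distinct, uniform on [0.5, 1.5].
    """
    rng = np.random.default_rng(seed)
    params = bank.params
    h, w = params.image_shape
    scales = tuple(range(params.n_scales)) if scale_indices is None else scale_indices
    lo_x, hi_x = w // 8, w - w // 8
    lo_y, hi_y = h // 8, h - h // 8
    if min_separation > 0:
        # jittered grid: adjacent cells are one cell apart, so a jitter of
        # (cell - separation)/2 per coordinate guarantees the separation
        side = int(np.ceil(np.sqrt(n_atoms)))
        cell = min((hi_x - lo_x) / side, (hi_y - lo_y) / side)
        if cell <= min_separation:
            raise ValueError(
                f"cannot fit {n_atoms} atoms at separation {min_separation} "
                f"in a {h}x{w} frame"
            )
        jitter = (cell - min_separation) / 2.0
        cells = rng.permutation(side * side)[:n_atoms]
        gx = lo_x + cell * (cells % side + 0.5) + rng.uniform(-jitter, jitter, n_atoms)
        gy = lo_y + cell * (cells // side + 0.5) + rng.uniform(-jitter, jitter, n_atoms)
        px, py = np.round(gx).astype(int), np.round(gy).astype(int)
    else:
        px = rng.integers(lo_x, hi_x, n_atoms)
        py = rng.integers(lo_y, hi_y, n_atoms)
    xs, ys, ths, scs, amps, phs = [], [], [], [], [], []
    for x, y in zip(px, py):
        s = int(rng.choice(scales))
        o = int(rng.integers(params.n_orientations))
        xs.append(int(x))
        ys.append(int(y))
        scs.append(s)
        ths.append(params.orientations[o])
        amps.append(float(rng.uniform(0.5, 1.5)))
        phs.append(float(rng.uniform(0, 2 * np.pi)))
    image = render_strokes(
        params, np.asarray(xs, float), np.asarray(ys, float), np.asarray(ths),
        np.asarray(scs), np.asarray(amps), np.asarray(phs),
    )
    if background_amplitude > 0:
        image = image + background_amplitude * image.std() * one_over_f_background(
            params.image_shape, rng
        )
    truth = _truth(params.image_shape, xs, ys, ths, scs, amps, phs, f"planted-{seed}")
    return image, truth


def generate_arrays(
    class_specs: Dict[str, FixtureSpec],
    n_per_class: int,
    seed: int = 0,
) -> List[Tuple[str, np.ndarray, EdgeList]]:
    """In-memory labeled dataset: [(label, image, ground truth), ...].

    Per-image RNG streams are spawned deterministically from the master
    seed, so the dataset is reproducible as a whole and per image.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 class specs")
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(class_specs) * n_per_class)
    k = 0
    for label, spec in class_specs.items():
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            sid = f"{label}_{i:04d}"
            image, truth = generate_contour_image(spec, rng=rng, source_id=sid)
            out.append((label, image, truth))
    return out


def generate_dataset(
    class_specs: Dict[str, FixtureSpec],
    n_per_class: int,
    out_dir: str | Path,
    seed: int = 0,
) -> pd.DataFrame:
    """Write PNG images, ground-truth edge CSVs, and a manifest CSV.

    The manifest has columns (path, label, seed); image files are 16-bit
    grayscale PNGs rescaled per image to the full intensity range (the
    pipeline's statistics are invariant to that affine rescaling).
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, image, truth in generate_arrays(class_specs, n_per_class, seed):
        path = out_dir / f"{truth.source_id}.png"
        if path.exists():
            raise FileExistsError(f"output collision: {path}")
        lo, hi = image.min(), image.max()
        scaled = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
        write_edge_csv(truth, out_dir / f"{truth.source_id}.truth.csv")
        rows.append({"path": path.name, "label": label, "seed": seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
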