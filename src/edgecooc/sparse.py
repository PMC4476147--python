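"""Greedy sparse coding (matching pursuit) of images over the log-Gabor bank.

An image is turned into an ordered list of discrete edges.  At each
iteration the atom (scale, orientation, position) with the largest
coefficient magnitude is selected, its projection is subtracted from the
residual, and coefficients are re-derived from the updated residual.  The
residual spectrum is maintained in the frequency domain, so the per-step
coefficient recomputation is exact full filtering, not an approximation.

Because the atoms are quadrature pairs, the quantity subtracted for a
complex coefficient c is the projection onto the span of the even and odd
parts, 2*Re(conj(c) * atom), which removes 2|c|^2 of residual energy.  We
therefore record amplitude = sqrt(2)|c| so that the energy bookkeeping
"initial = sum(amplitude^2) + final residual" holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.fft as _fft

from .filterbank import FilterBank

__all__ = [
    "EdgeElement",
    "EdgeList",
    "extract_edges",
    "reconstruct_image",
    "residual_energy",
    "write_edge_csv",
    "read_edge_csv",
]

DEFAULT_N_EDGES = 2048
DEFAULT_RESIDUAL_TARGET = 0.05
DEFAULT_MASK_FRACTION = 0.45


@dataclass(frozen=True)
class EdgeElement:
    """One extracted edge: center position, orientation, scale, strength."""

    x: float
    y: float
    theta: float  # radians, modulo pi
    scale_index: int
    amplitude: float
    phase: float = 0.0  # radians; reconstruction only, ignored by statistics


@dataclass
class EdgeList:
    """All edges of one image, in greedy selection order.

    Array-of-columns layout; ``element(i)`` gives an :class:`EdgeElement`
    view of row i.  ``amplitude`` follows matching-pursuit selection order
    and is non-increasing up to the small fluctuations that atom
    non-orthogonality permits (an over-complete dictionary does not
    guarantee strict coefficient monotonicity; residual energy, however,
    decreases at every step).
    """

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    scale_index: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    image_shape: Tuple[int, int]
    mask_radius: float
    source_id: str = ""
    params_hash: str = ""
    residual_fraction: float = float("nan")
    target_not_reached: bool = False

    def __len__(self) -> int:
        return len(self.x)

    def element(self, i: int) -> EdgeElement:
        return EdgeElement(
            x=float(self.x[i]),
            y=float(self.y[i]),
            theta=float(self.theta[i]),
            scale_index=int(self.scale_index[i]),
            amplitude=float(self.amplitude[i]),
            phase=float(self.phase[i]),
        )

    def prefix(self, n: int) -> "EdgeList":
        """The first ``n`` edges (greedy order), metadata preserved."""
        return replace(
            self,
            x=self.x[:n],
            y=self.y[:n],
            theta=self.theta[:n],
            scale_index=self.scale_index[:n],
            amplitude=self.amplitude[:n],
            phase=self.phase[:n],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_id": self.source_id,
                "x": self.x,
                "y": self.y,
                "theta": self.theta,
                "scale_index": self.scale_index,
                "amplitude": self.amplitude,
                "phase": self.phase,
            }
        )

    @staticmethod
    def empty(image_shape: Tuple[int, int], mask_radius: float, source_id: str = "") -> "EdgeList":
        z = np.zeros(0)
        return EdgeList(
            x=z.copy(), y=z.copy(), theta=z.copy(),
            scale_index=np.zeros(0, dtype=int),
            amplitude=z.copy(), phase=z.copy(),
            image_shape=tuple(image_shape), mask_radius=mask_radius,
            source_id=source_id, residual_fraction=0.0,
        )


def default_mask_radius(image_shape: Tuple[int, int]) -> float:
    return DEFAULT_MASK_FRACTION * min(image_shape)


def extract_edges(
    image: np.ndarray,
    bank: FilterBank,
    n_edges: int = DEFAULT_N_EDGES,
    residual_target: float = DEFAULT_RESIDUAL_TARGET,
    source_id: str = "",
    mask_radius: Optional[float] = None,
    params_hash: str = "",
) -> Tuple[EdgeList, np.ndarray]:
    """Run matching pursuit on ``image``.

    Stops at ``n_edges`` selections or when the residual energy falls to
    ``residual_target`` times the initial energy, whichever happens first;
    if the target was not reached within the budget the returned list has
    ``target_not_reached = True``.  Returns (edge list, residual image).

    The image is mean-subtracted first (the zero-DC dictionary cannot and
    need not represent the mean); energies are measured on the
    mean-subtracted image.  Ties in the greedy arg-max are broken toward
    the lowest (scale, orientation, y, x) in lexicographic order.
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    if not (0.0 < residual_target < 1.0):
        raise ValueError("residual_target must lie in (0, 1)")
    image = np.asarray(image, dtype=float)
    if image.shape != bank.shape:
        raise ValueError(f"image shape {image.shape} != bank shape {bank.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")

    h, w = bank.shape
    npix = h * w
    rootn = np.sqrt(npix)
    if mask_radius is None:
        mask_radius = default_mask_radius(image.shape)

    work = image - image.mean()
    r_hat = _fft.fft2(work).astype(bank.kernels.dtype)
    e0 = float(np.sum(np.abs(r_hat) ** 2)) / npix
    if e0 <= 0.0:
        out = EdgeList.empty(image.shape, mask_radius, source_id)
        out.params_hash = params_hash
        return out, np.zeros_like(work)

    conj_k = np.conj(bank.kernels)
    fy = _fft.fftfreq(h)
    fx = _fft.fftfreq(w)

    xs, ys, ss, os_, amps, phases = [], [], [], [], [], []
    e_res = e0
    flagged = False
    for _ in range(n_edges):
        coeff = _fft.ifft2(r_hat[None, None] * conj_k, axes=(-2, -1))
        power = coeff.real ** 2 + coeff.imag ** 2
        flat = int(np.argmax(power))  # first max in C-order = lexicographic tie-break
        s, o, y, x = np.unravel_index(flat, power.shape)
        c = complex(coeff[s, o, y, x]) * rootn
        if abs(c) == 0.0:
            break
        ramp = np.exp(-2j * np.pi * fy * y)[:, None] * np.exp(-2j * np.pi * fx * x)[None, :]
        # spectrum of 2*Re(c * atom): one-sided term plus its Hermitian mirror
        update = rootn * ramp * (c * bank.kernels[s, o] + np.conj(c) * bank.kernels_mirror[s, o])
        r_hat -= update.astype(r_hat.dtype)

        xs.append(float(x)); ys.append(float(y))
        ss.append(int(s)); os_.append(int(o))
        amps.append(np.sqrt(2.0) * abs(c)); phases.append(float(np.angle(c)))

        e_res = float(np.sum(np.abs(r_hat) ** 2)) / npix
        if e_res <= residual_target * e0:
            break
    flagged = e_res > residual_target * e0

    theta = bank.params.orientations[np.asarray(os_, dtype=int)] if os_ else np.zeros(0)
    edges = EdgeList(
        x=np.asarray(xs), y=np.asarray(ys), theta=np.asarray(theta, dtype=float),
        scale_index=np.asarray(ss, dtype=int),
        amplitude=np.asarray(amps), phase=np.asarray(phases),
        image_shape=image.shape, mask_radius=float(mask_radius),
        source_id=source_id, params_hash=params_hash,
        residual_fraction=e_res / e0, target_not_reached=flagged,
    )
    residual = np.real(_fft.ifft2(r_hat.astype(np.complex128)))
    return edges, residual


def reconstruct_image(edges: EdgeList, bank: FilterBank) -> np.ndarray:
    """Sum of the selected atoms scaled by amplitude and phase.

    The reconstruction is accumulated in the frequency domain (one inverse
    transform total), which is exactly equivalent to summing shifted
    spatial atoms under circular boundary conditions.
    """
    h, w = bank.shape
    if len(edges) == 0:
        return np.zeros((h, w))
    if edges.scale_index.min() < 0 or edges.scale_index.max() >= bank.params.n_scales:
        raise ValueError("edge scale_index out of range for this bank")
    orientations = bank.params.orientations
    # map stored theta back to the nearest orientation channel
    o_idx = np.argmin(
        np.abs(np.angle(np.exp(2j * (edges.theta[:, None] - orientations[None, :])))), axis=1
    )
    fy = _fft.fftfreq(h)
    fx = _fft.fftfreq(w)
    rootn = np.sqrt(h * w)
    acc = np.zeros((h, w), dtype=np.complex128)
    coeffs = (edges.amplitude / np.sqrt(2.0)) * np.exp(1j * edges.phase)
    for i in range(len(edges)):
        ramp = (
            np.exp(-2j * np.pi * fy * edges.y[i])[:, None]
            * np.exp(-2j * np.pi * fx * edges.x[i])[None, :]
        )
        acc += coeffs[i] * rootn * bank.kernels[edges.scale_index[i], o_idx[i]] * ramp
    return 2.0 * np.real(_fft.ifft2(acc))


def residual_energy(image: np.ndarray, edges: EdgeList, bank: FilterBank) -> float:
    """energy(image - reconstruction) / energy(image), on the
    mean-subtracted image; 0 for a zero-energy image."""
    image = np.asarray(image, dtype=float)
    work = image - image.mean()
    e0 = float(np.sum(work ** 2))
    if e0 <= 0.0:
        return 0.0
    recon = reconstruct_image(edges, bank)
    return float(np.sum((work - recon) ** 2)) / e0


# ---------------------------------------------------------------------------
# Interchange format: CSV of edges + JSON sidecar with image geometry
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["source_id", "x", "y", "theta", "scale_index", "amplitude", "phase"]


def write_edge_csv(edges: EdgeList, path: str | Path) -> None:
    """Write edges as CSV plus a ``<path>.json`` sidecar of metadata."""
    path = Path(path)
    edges.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "image_shape": list(edges.image_shape),
        "mask_radius": edges.mask_radius,
        "params_hash": edges.params_hash,
        "residual_fraction": None if np.isnan(edges.residual_fraction) else edges.residual_fraction,
        "target_not_reached": bool(edges.target_not_reached),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_edge_csv(path: str | Path) -> EdgeList:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != CSV_COLUMNS:
        raise ValueError(f"unexpected edge CSV header in {path}: {list(df.columns)}")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    rf = meta.get("residual_fraction")
    return EdgeList(
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        theta=df["theta"].to_numpy(dtype=float),
        scale_index=df["scale_index"].to_numpy(dtype=int),
        amplitude=df["amplitude"].to_numpy(dtype=float),
        phase=df["phase"].to_numpy(dtype=float),
        image_shape=tuple(meta["image_shape"]),
        mask_radius=float(meta["mask_radius"]),
        source_id=str(df["source_id"].iloc[0]) if len(df) else "",
        params_hash=meta.get("params_hash", ""),
        residual_fraction=float("nan") if rf is None else float(rf),
        target_not_reached=bool(meta.get("target_not_reached", False)),
    )
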