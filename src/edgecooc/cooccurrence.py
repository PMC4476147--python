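"""The association field: 4-D edge co-occurrence histograms and chevron maps.

The central object is the normalized histogram p(d, psi, theta, sigma)
accumulated over all unordered pairs of edges inside a central circular
mask (edges near the frame border are discarded to avoid boundary
artifacts).  Marginalizing over distance and scale ratio gives the 2-D
"chevron map" p(psi, theta) of angular configurations: the collinear cell
is (psi = 0, theta = 0), parallel configurations sit at |psi| = pi/2 on
the theta = 0 row, and co-circular configurations run along the psi = 0
column across theta.

Each unordered pair is accumulated symmetrically under the two choices of
reference edge — half its weight at (d, psi, theta, sigma) and half at
(d, psi, -theta, -sigma) — so the histogram is exactly independent of the
reference-edge choice.  Pairs are weighted by the product of the two edge
amplitudes by default (sparse coefficients carry magnitude information);
an unweighted mode is available and recorded in the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .geometry import fold_halfpi, pair_geometry_arrays
from .sparse import EdgeList

__all__ = [
    "Binning",
    "CoocHistogram",
    "ChevronMap",
    "default_binning",
    "cooccurrence_histogram",
    "chevron_map",
    "ratio_map",
    "first_order_histogram",
    "save_histogram",
    "load_histogram",
]

AXES = ("d", "psi", "theta", "sigma")


@dataclass(frozen=True)
class Binning:
    """Bin edges of the 4-D histogram.

    ``normalize_distance`` selects whether ``d`` is accumulated in absolute
    pixels or in units of the pair's geometric-mean wavelength; the latter
    makes the histogram invariant under joint rescaling of positions and
    scales.
    """

    d_edges: np.ndarray
    psi_edges: np.ndarray
    theta_edges: np.ndarray
    sigma_edges: np.ndarray
    normalize_distance: bool = False

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return (
            len(self.d_edges) - 1,
            len(self.psi_edges) - 1,
            len(self.theta_edges) - 1,
            len(self.sigma_edges) - 1,
        )

    def compatible(self, other: "Binning") -> bool:
        return (
            self.normalize_distance == other.normalize_distance
            and all(
                np.array_equal(getattr(self, f"{ax}_edges"), getattr(other, f"{ax}_edges"))
                for ax in AXES
            )
        )


def default_binning(
    mask_radius: float,
    n_d: int = 6,
    d_min: float = 2.0,
    n_psi: int = 12,
    n_theta: int = 12,
    n_sigma: int = 5,
    sigma_max: float = 2.0,
    normalize_distance: bool = False,
) -> Binning:
    """Default grid: 6 log-spaced distance bins on [2, mask_radius] px,
    12 x 12 angular bins on [-pi/2, pi/2), 5 scale-ratio bins on
    [-sigma_max, sigma_max] octaves."""
    if normalize_distance:
        d_edges = np.geomspace(0.5, 32.0, n_d + 1)
    else:
        d_edges = np.geomspace(d_min, mask_radius, n_d + 1)
    return Binning(
        d_edges=d_edges,
        psi_edges=np.linspace(-np.pi / 2, np.pi / 2, n_psi + 1),
        theta_edges=np.linspace(-np.pi / 2, np.pi / 2, n_theta + 1),
        sigma_edges=np.linspace(-sigma_max, sigma_max, n_sigma + 1),
        normalize_distance=normalize_distance,
    )


@dataclass
class CoocHistogram:
    """4-D table over (d, psi, theta, sigma) bins plus accumulation metadata."""

    table: np.ndarray
    binning: Binning
    weighting: str = "amplitude"
    n_pairs: int = 0
    n_dropped: int = 0
    normalized: bool = False
    mask_radius: float = float("nan")
    params_hash: str = ""

    def normalize(self) -> "CoocHistogram":
        total = self.table.sum()
        if total <= 0:
            raise ValueError("no pairs: cannot normalize an empty histogram")
        return replace(self, table=self.table / total, normalized=True)

    def marginal(self, axes: Tuple[str, ...]) -> np.ndarray:
        """Marginal over the named axes (normalized if the table is)."""
        keep = [AXES.index(a) for a in axes]
        drop = tuple(i for i in range(4) if i not in keep)
        out = self.table.sum(axis=drop)
        return np.moveaxis(out, np.argsort(np.argsort(keep)), range(len(keep)))


@dataclass
class ChevronMap:
    """2-D map over (psi, theta) cells; probability or ratio-vs-reference."""

    values: np.ndarray  # shape (n_psi, n_theta)
    psi_edges: np.ndarray
    theta_edges: np.ndarray
    mode: str = "probability"  # or "ratio"

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",")

    def cell(self, psi: float, theta: float) -> Tuple[int, int]:
        """Indices of the cell containing (psi, theta) after folding."""
        p = float(fold_halfpi(psi))
        t = float(fold_halfpi(theta))
        ip = min(np.searchsorted(self.psi_edges, p, side="right") - 1, len(self.psi_edges) - 2)
        it = min(np.searchsorted(self.theta_edges, t, side="right") - 1, len(self.theta_edges) - 2)
        return int(ip), int(it)


def _masked(edges: EdgeList, mask_radius: Optional[float]):
    h, w = edges.image_shape
    r = edges.mask_radius if mask_radius is None else mask_radius
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    keep = (edges.x - cx) ** 2 + (edges.y - cy) ** 2 <= r ** 2
    return keep, r


def cooccurrence_histogram(
    edges: EdgeList,
    binning: Optional[Binning] = None,
    weighting: str = "amplitude",
    mask_radius: Optional[float] = None,
    scale_ratio: float = 2.0,
    base_wavelength: float = 4.0,
    normalize: bool = True,
) -> CoocHistogram:
    """Accumulate the 4-D co-occurrence histogram of one edge list.

    Pairs whose distance falls outside the ``d`` bin range are dropped and
    counted in ``n_dropped``; scale-ratio values beyond the sigma range are
    clipped into the end bins.  Fewer than two masked edges yield an empty
    (all-zero) histogram with ``n_pairs = 0``.
    """
    if weighting not in ("amplitude", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    keep, r = _masked(edges, mask_radius)
    if binning is None:
        binning = default_binning(r)
    x, y = edges.x[keep], edges.y[keep]
    th, sc = edges.theta[keep], edges.scale_index[keep]
    amp = edges.amplitude[keep]

    empty = CoocHistogram(
        table=np.zeros(binning.shape), binning=binning, weighting=weighting,
        n_pairs=0, n_dropped=0, normalized=False, mask_radius=r,
        params_hash=edges.params_hash,
    )
    if len(x) < 2:
        return empty

    d, psi, theta_rel, sigma, i, j = pair_geometry_arrays(x, y, th, sc, scale_ratio)
    if binning.normalize_distance:
        lam = base_wavelength * scale_ratio ** sc.astype(float)
        d = d / np.sqrt(lam[i] * lam[j])
    w = amp[i] * amp[j] if weighting == "amplitude" else np.ones_like(d)

    in_range = (d >= binning.d_edges[0]) & (d <= binning.d_edges[-1])
    n_dropped = int(np.size(d) - np.count_nonzero(in_range))
    d, psi, theta_rel, sigma, w = (a[in_range] for a in (d, psi, theta_rel, sigma, w))
    if d.size == 0:
        return replace(empty, n_dropped=n_dropped)

    lo, hi = binning.sigma_edges[0], binning.sigma_edges[-1]
    sigma = np.clip(sigma, lo, hi)
    # symmetrize over the choice of reference edge: theta, sigma flip sign
    sample = np.concatenate(
        [
            np.stack([d, psi, theta_rel, sigma], axis=1),
            np.stack([d, psi, fold_halfpi(-theta_rel), np.clip(-sigma, lo, hi)], axis=1),
        ]
    )
    weights = np.concatenate([w, w]) / 2.0
    table, _ = np.histogramdd(
        sample,
        bins=[binning.d_edges, binning.psi_edges, binning.theta_edges, binning.sigma_edges],
        weights=weights,
    )
    out = CoocHistogram(
        table=table, binning=binning, weighting=weighting,
        n_pairs=int(d.size), n_dropped=n_dropped, normalized=False,
        mask_radius=r, params_hash=edges.params_hash,
    )
    return out.normalize() if normalize else out


def chevron_map(h: CoocHistogram) -> ChevronMap:
    """Marginal p(psi, theta) of the 4-D histogram."""
    if h.table.sum() <= 0:
        raise ValueError("no pairs: empty histogram has no chevron map")
    values = h.marginal(("psi", "theta"))
    values = values / values.sum()
    return ChevronMap(
        values=values, psi_edges=h.binning.psi_edges,
        theta_edges=h.binning.theta_edges, mode="probability",
    )


def ratio_map(h_test: CoocHistogram, h_ref: CoocHistogram, epsilon: float = 1e-6) -> ChevronMap:
    """Cell-wise ratio of two chevron marginals (test / reference).

    Both marginals are epsilon-smoothed and renormalized first, so the
    reference can never be zero; a value of 1 means identical prevalence.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not h_test.binning.compatible(h_ref.binning):
        raise ValueError("histograms were binned differently; refusing to form a ratio")
    a = chevron_map(h_test).values + epsilon
    b = chevron_map(h_ref).values + epsilon
    a /= a.sum()
    b /= b.sum()
    return ChevronMap(
        values=a / b, psi_edges=h_test.binning.psi_edges,
        theta_edges=h_test.binning.theta_edges, mode="ratio",
    )


def first_order_histogram(
    edges: EdgeList,
    n_bins: int = 12,
    weighting: str = "amplitude",
    mask_radius: Optional[float] = None,
) -> np.ndarray:
    """Normalized histogram of edge orientations over [0, pi)."""
    keep, _ = _masked(edges, mask_radius)
    if not np.any(keep):
        raise ValueError("no edges inside the mask")
    th = edges.theta[keep] % np.pi
    w = edges.amplitude[keep] if weighting == "amplitude" else None
    hist, _ = np.histogram(th, bins=np.linspace(0, np.pi, n_bins + 1), weights=w)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# HDF5 storage
# ---------------------------------------------------------------------------

def save_histogram(h: CoocHistogram, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("table", data=h.table, track_times=False)
        for ax in AXES:
            f.create_dataset(f"{ax}_edges", data=getattr(h.binning, f"{ax}_edges"), track_times=False)
        f.attrs.update(
            weighting=h.weighting, n_pairs=h.n_pairs, n_dropped=h.n_dropped,
            normalized=h.normalized, mask_radius=h.mask_radius,
            params_hash=h.params_hash,
            normalize_distance=h.binning.normalize_distance,
        )


def load_histogram(path: str | Path) -> CoocHistogram:
    import h5py

    with h5py.File(path, "r") as f:
        binning = Binning(
            d_edges=f["d_edges"][:], psi_edges=f["psi_edges"][:],
            theta_edges=f["theta_edges"][:], sigma_edges=f["sigma_edges"][:],
            normalize_distance=bool(f.attrs["normalize_distance"]),
        )
        return CoocHistogram(
            table=f["table"][:], binning=binning,
            weighting=str(f.attrs["weighting"]), n_pairs=int(f.attrs["n_pairs"]),
            n_dropped=int(f.attrs["n_dropped"]), normalized=bool(f.attrs["normalized"]),
            mask_radius=float(f.attrs["mask_radius"]),
            params_hash=str(f.attrs["params_hash"]),
        )
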