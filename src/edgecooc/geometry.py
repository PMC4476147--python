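"""Relative geometry of oriented edge pairs.

For a pair of edges A, B the second-order statistics use four variables:

* ``d``     — center-to-center distance (pixels, or in units of the pair's
              geometric-mean wavelength when scale-normalized);
* ``phi``   — azimuth of B's center seen from A, measured relative to A's
              orientation, folded modulo pi;
* ``theta`` — orientation difference theta_B - theta_A, folded modulo pi
              into [-pi/2, pi/2);
* ``psi``   — the symmetrized relative angle psi = phi - theta/2 (up to the
              modulo-pi folding of the half-angles), which is zero exactly
              when the two edges are tangent to a common circle and is
              invariant under swapping A and B;
* ``sigma`` — log2 of the scale ratio of B to A (octaves).

Edges are unoriented (orientation modulo pi), so all angular variables are
computed from folded representatives.  ``psi`` is computed from the angles
each edge makes with the chord joining the two centers, each folded to
[-pi/2, pi/2) *before* averaging: psi = -(a + b)/2 with a = theta_A -
chord, b = theta_B - chord.  This choice makes psi exactly zero for
circle-tangent pairs at any tangent-point separation, which the naive
"fold(phi) - fold(theta)/2" does not (the two agree modulo pi/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sparse import EdgeElement

__all__ = ["PairGeometry", "fold_halfpi", "pairwise_geometry", "pair_geometry_arrays"]


def fold_halfpi(x: np.ndarray | float):
    """Fold an angle (defined modulo pi) into [-pi/2, pi/2)."""
    return ((np.asarray(x) + np.pi / 2) % np.pi) - np.pi / 2


@dataclass(frozen=True)
class PairGeometry:
    d: float
    phi: float
    theta: float
    psi: float
    sigma: float
    degenerate: bool = False  # coincident centers: phi/psi conventional


def pairwise_geometry(a: EdgeElement, b: EdgeElement, scale_ratio: float = 2.0) -> PairGeometry:
    """Relative geometry of a single edge pair (scalar convenience path).

    ``sigma`` is expressed in octaves: (scale_index_B - scale_index_A) *
    log2(scale_ratio).  Coincident centers make the azimuth undefined; by
    convention phi = psi = 0 and the pair is flagged degenerate.
    """
    dx = b.x - a.x
    dy = b.y - a.y
    d = float(np.hypot(dx, dy))
    sigma = (b.scale_index - a.scale_index) * float(np.log2(scale_ratio))
    theta = float(fold_halfpi(b.theta - a.theta))
    if d == 0.0:
        return PairGeometry(d=0.0, phi=0.0, theta=theta, psi=0.0, sigma=sigma, degenerate=True)
    chord = float(np.arctan2(dy, dx))
    phi = float(fold_halfpi(chord - a.theta))
    fa = fold_halfpi(a.theta - chord)
    fb = fold_halfpi(b.theta - chord)
    psi = float(fold_halfpi(-(fa + fb) / 2.0))
    return PairGeometry(d=d, phi=phi, theta=theta, psi=psi, sigma=sigma)


def pair_geometry_arrays(
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    scale_index: np.ndarray,
    scale_ratio: float = 2.0,
):
    """Vectorized geometry over all unordered pairs of an edge set.

    Returns (d, psi, theta_rel, sigma, i, j) arrays over the m(m-1)/2
    pairs, ordered by the upper triangle of the pair matrix.  The pair
    ordering (i < j in input order) fixes the sign conventions; histogram
    accumulation symmetrizes over the swap, so the ordering has no effect
    on the statistics.
    """
    m = len(x)
    i, j = np.triu_indices(m, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    d = np.hypot(dx, dy)
    chord = np.arctan2(dy, dx)
    fa = fold_halfpi(theta[i] - chord)
    fb = fold_halfpi(theta[j] - chord)
    psi = fold_halfpi(-(fa + fb) / 2.0)
    theta_rel = fold_halfpi(theta[j] - theta[i])
    sigma = (scale_index[j] - scale_index[i]) * float(np.log2(scale_ratio))
    # coincident centers: conventional psi = 0
    psi = np.where(d == 0.0, 0.0, psi)
    return d, psi, theta_rel, sigma, i, j
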