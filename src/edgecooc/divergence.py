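"""Histogram divergences and the factorization / false-alarm analyses.

Divergences are in nats (natural log) by default.  Empirical co-occurrence
tables contain empty cells, so Kullback-Leibler comparisons add a small
epsilon to every cell of both arguments and renormalize before taking the
ratio; the Jensen-Shannon divergence needs no smoothing because its mixture
term covers the union of the supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .cooccurrence import CoocHistogram

__all__ = [
    "DivergenceReport",
    "FalseAlarmScore",
    "kl_divergence",
    "js_divergence",
    "divergence_report",
    "smoothing_epsilon",
    "factorization_gap",
    "dprime",
    "false_alarm_scores",
    "nats_to_bits",
]

LN2 = float(np.log(2.0))


def nats_to_bits(x: float) -> float:
    return x / LN2


def _as_prob(p: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("histogram has negative entries")
    p = p + epsilon
    total = p.sum()
    if total <= 0:
        raise ValueError("histogram sums to zero")
    return p / total


def smoothing_epsilon(h: CoocHistogram) -> float:
    """Default additive smoothing for an empirical table: one pseudo-count
    spread over all cells, 1 / (n_bins * n_pairs)."""
    n_bins = int(np.prod(h.table.shape))
    return 1.0 / (n_bins * max(h.n_pairs, 1))


def kl_divergence(p: np.ndarray, q: np.ndarray, epsilon: float = 1e-10) -> float:
    """KL(p || q) in nats after epsilon-smoothing and renormalizing both."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ps = _as_prob(p, epsilon).ravel()
    qs = _as_prob(q, epsilon).ravel()
    return float(np.sum(ps * np.log(ps / qs)))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats: 0.5 KL(p||m) + 0.5 KL(q||m),
    m = (p + q)/2.  Symmetric, bounded by ln 2; its square root is a
    metric on distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    ps = _as_prob(p).ravel()
    qs = _as_prob(q).ravel()
    m = 0.5 * (ps + qs)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(ps > 0, ps * np.log(ps / m), 0.0)
        b = np.where(qs > 0, qs * np.log(qs / m), 0.0)
    return float(min(0.5 * (a.sum() + b.sum()), LN2))


@dataclass(frozen=True)
class DivergenceReport:
    kl_ab: float
    kl_ba: float
    js: float
    epsilon: float

    def to_dict(self) -> Dict[str, float]:
        return {"kl_ab": self.kl_ab, "kl_ba": self.kl_ba, "js": self.js, "epsilon": self.epsilon}


def divergence_report(p: np.ndarray, q: np.ndarray, epsilon: float = 1e-10) -> DivergenceReport:
    return DivergenceReport(
        kl_ab=kl_divergence(p, q, epsilon),
        kl_ba=kl_divergence(q, p, epsilon),
        js=js_divergence(p, q),
        epsilon=epsilon,
    )


def factorization_gap(h: CoocHistogram, epsilon: float | None = None) -> Dict[str, float]:
    """How well the 4-D table factorizes.

    Compares the joint p(d, psi, theta, sigma) against (i) the product of
    its four 1-D marginals, and (ii) the product p(d, sigma) * p(psi,
    theta) of the two 2-D marginals.  The pair factorization nests the
    full one, so its KL gap is never larger; a small pair gap justifies
    analyzing the angular chevron map separately from the
    distance/scale marginal.
    """
    if h.table.sum() <= 0:
        raise ValueError("empty histogram")
    if epsilon is None:
        epsilon = smoothing_epsilon(h)
    joint = _as_prob(h.table)
    m = [joint.sum(axis=tuple(j for j in range(4) if j != i)) for i in range(4)]
    full_product = m[0][:, None, None, None] * m[1][None, :, None, None] \
        * m[2][None, None, :, None] * m[3][None, None, None, :]
    d_sigma = joint.sum(axis=(1, 2))      # (d, sigma)
    psi_theta = joint.sum(axis=(0, 3))    # (psi, theta)
    pair_product = d_sigma[:, None, None, :] * psi_theta[None, :, :, None]
    gap_full = kl_divergence(joint, full_product, epsilon)
    gap_pair = kl_divergence(joint, pair_product, epsilon)
    return {
        "kl_joint_vs_full_product": gap_full,
        "kl_joint_vs_pair_product": gap_pair,
        "closer_factorization": "pair" if gap_pair <= gap_full else "full",
    }


def dprime(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Standardized separation (mean1 - mean2) / pooled SD of two groups."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite scores")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: d-prime undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class FalseAlarmScore:
    """Per-image histogram affinities to two class-average histograms.

    ``delta[i] = KL(h_i || mean_A) - KL(h_i || mean_B)``: negative values
    mean image i sits closer to class A.  Swapping the class roles negates
    every delta.
    """

    deltas: np.ndarray
    epsilon: float

    def to_dict(self) -> Dict[str, object]:
        return {"deltas": self.deltas.tolist(), "epsilon": self.epsilon}


def false_alarm_scores(
    image_tables: Sequence[np.ndarray],
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    epsilon: float = 1e-10,
) -> FalseAlarmScore:
    deltas = np.array(
        [kl_divergence(t, mean_a, epsilon) - kl_divergence(t, mean_b, epsilon) for t in image_tables]
    )
    return FalseAlarmScore(deltas=deltas, epsilon=epsilon)
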