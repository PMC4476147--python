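"""Matching pursuit: recovery, energy accounting, determinism, I/O."""

import numpy as np
import pytest

from edgecooc import (
    EdgeList,
    extract_edges,
    read_edge_csv,
    reconstruct_image,
    residual_energy,
    write_edge_csv,
)
from edgecooc.synthetic import planted_atom_image


def one_atom_image(bank, s, o, x, y, amp=0.8, phase=0.4):
    c = (amp / np.sqrt(2.0)) * np.exp(1j * phase)
    return 2 * np.real(c * bank.atom(s, o, x, y))


def test_one_atom_recovered_exactly(small_bank):
    img = one_atom_image(small_bank, 2, 5, 22, 41, amp=0.8, phase=0.4)
    edges, residual = extract_edges(img, small_bank, n_edges=5)
    e = edges.element(0)
    assert (e.scale_index, e.x, e.y) == (2, 22.0, 41.0)
    assert e.theta == pytest.approx(small_bank.params.orientations[5])
    assert e.amplitude == pytest.approx(0.8, rel=1e-6)
    assert e.phase == pytest.approx(0.4, rel=1e-6)
    assert edges.residual_fraction < 1e-12
    assert residual_energy(img, edges.prefix(1), small_bank) < 1e-6


def test_residual_energy_trivial_cases(small_bank):
    img = one_atom_image(small_bank, 1, 0, 30, 30)
    empty = EdgeList.empty((64, 64), mask_radius=28.8)
    assert residual_energy(img, empty, small_bank) == pytest.approx(1.0)
    assert np.array_equal(reconstruct_image(empty, small_bank), np.zeros((64, 64)))


def test_zero_image_yields_empty_list(small_bank):
    edges, residual = extract_edges(np.zeros((64, 64)), small_bank, n_edges=10)
    assert len(edges) == 0
    assert edges.residual_fraction == 0.0
    assert not edges.target_not_reached
    assert np.all(residual == 0)


def test_residual_monotone_and_bookkeeping(small_bank, rng):
    image = rng.standard_normal((64, 64))
    edges, residual = extract_edges(image, small_bank, n_edges=60, residual_target=0.001)
    # greedy property: amplitudes non-increasing up to the slack that
    # non-orthogonal atoms allow (subtracting one atom can slightly raise
    # a neighbor's coefficient)
    assert np.all(np.diff(edges.amplitude) <= 0.1 * edges.amplitude[:-1])
    assert edges.amplitude[-1] < edges.amplitude[0]
    # residual strictly decreases along prefixes
    fracs = [residual_energy(image, edges.prefix(n), small_bank) for n in range(0, len(edges) + 1, 10)]
    assert all(b < a for a, b in zip(fracs, fracs[1:]))
    # energy bookkeeping: initial = sum(amp^2) + final residual
    work = image - image.mean()
    e0 = np.sum(work ** 2)
    gap = abs(np.sum(edges.amplitude ** 2) + np.sum(residual ** 2) - e0) / e0
    assert gap < 1e-4


def test_planted_atoms_recovered(medium_bank):
    """10 well-separated planted atoms are the first 10 selections, each
    within one pixel / one orientation channel / the exact scale."""
    image, truth = planted_atom_image(
        medium_bank, n_atoms=10, seed=11, background_amplitude=0.0,
        min_separation=23, scale_indices=(0, 1, 2),
    )
    edges, _ = extract_edges(image, medium_bank, n_edges=10, residual_target=1e-9)
    assert len(edges) == 10
    spacing = np.pi / medium_bank.params.n_orientations
    matched = 0
    for i in range(10):
        d = np.hypot(truth.x - edges.x[i], truth.y - edges.y[i])
        j = int(np.argmin(d))
        dth = np.abs(np.angle(np.exp(2j * (truth.theta[j] - edges.theta[i])))) / 2
        if d[j] <= 1.0 and dth <= spacing and truth.scale_index[j] == edges.scale_index[i]:
            matched += 1
    assert matched == 10


def test_extraction_deterministic(small_bank, rng):
    image = rng.standard_normal((64, 64))
    a, _ = extract_edges(image, small_bank, n_edges=30)
    b, _ = extract_edges(image, small_bank, n_edges=30)
    for field in ("x", "y", "theta", "scale_index", "amplitude", "phase"):
        assert np.array_equal(getattr(a, field), getattr(b, field))


def test_natural_like_image_reaches_five_percent_residual(medium_bank):
    """On a synthetic natural-like image (planted strokes + 1/f clutter)
    the default residual criterion is reachable and the reconstruction
    from the edge list alone matches to within that residual."""
    image, _ = planted_atom_image(medium_bank, n_atoms=20, seed=5, background_amplitude=0.2)
    edges, _ = extract_edges(image, medium_bank, n_edges=1024, residual_target=0.05)
    assert not edges.target_not_reached
    assert residual_energy(image, edges, medium_bank) <= 0.05 + 1e-9


def test_budget_exhaustion_is_flagged(small_bank, rng):
    image = rng.standard_normal((64, 64))
    edges, _ = extract_edges(image, small_bank, n_edges=3, residual_target=0.01)
    assert len(edges) == 3
    assert edges.target_not_reached


def test_edge_csv_roundtrip(tmp_path, small_bank, rng):
    image = rng.standard_normal((64, 64))
    edges, _ = extract_edges(image, small_bank, n_edges=17, source_id="img-7", params_hash="abc123")
    path = tmp_path / "edges.csv"
    write_edge_csv(edges, path)
    back = read_edge_csv(path)
    for field in ("x", "y", "theta", "scale_index", "amplitude", "phase"):
        assert np.array_equal(getattr(edges, field), getattr(back, field)), field
    assert back.image_shape == edges.image_shape
    assert back.mask_radius == edges.mask_radius
    assert back.source_id == "img-7"
    assert back.params_hash == "abc123"
    assert back.residual_fraction == pytest.approx(edges.residual_fraction)


def test_extract_validates_inputs(small_bank):
    with pytest.raises(ValueError, match="n_edges"):
        extract_edges(np.zeros((64, 64)), small_bank, n_edges=0)
    with pytest.raises(ValueError, match="residual_target"):
        extract_edges(np.zeros((64, 64)), small_bank, residual_target=1.5)
    with pytest.raises(ValueError, match="shape"):
        extract_edges(np.zeros((32, 32)), small_bank)
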