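"""Co-occurrence histograms, chevron maps, ratio maps, invariances."""

import numpy as np
import pytest

from edgecooc import (
    Binning,
    EdgeList,
    chevron_map,
    cooccurrence_histogram,
    default_binning,
    first_order_histogram,
    load_histogram,
    ratio_map,
    save_histogram,
)


def make_edges(x, y, theta, scale=None, amp=None, shape=(128, 128), mask_radius=1e6):
    n = len(x)
    return EdgeList(
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        theta=np.asarray(theta, float) % np.pi,
        scale_index=np.zeros(n, int) if scale is None else np.asarray(scale, int),
        amplitude=np.ones(n) if amp is None else np.asarray(amp, float),
        phase=np.zeros(n),
        image_shape=shape,
        mask_radius=mask_radius,
        source_id="fixture",
    )


def wide_binning(**kw):
    return default_binning(mask_radius=180.0, **kw)


def central_block(cm):
    """The four cells around (psi, theta) = (0, 0) (0 lies on a bin edge)."""
    i0, j0 = cm.cell(-1e-9, -1e-9)
    i1, j1 = cm.cell(+1e-9, +1e-9)
    return cm.values[i0 : i1 + 1, j0 : j1 + 1]


def test_two_edge_list_single_pair():
    e = make_edges([10, 30], [20, 25], [0.3, 1.1])
    h = cooccurrence_histogram(e, binning=wide_binning(), normalize=False)
    assert h.n_pairs == 1
    # the pair's weight may split across the two reference-symmetric
    # mirror cells (theta, sigma) <-> (-theta, -sigma)
    nz = h.table[h.table > 0]
    assert len(nz) in (1, 2)
    assert nz.sum() == pytest.approx(1.0)


def test_two_edge_symmetric_pair_single_bin():
    # theta = 0 and sigma = 0: the mirror image coincides -> exactly one bin
    e = make_edges([10, 40], [20, 21], [0.3, 0.3])
    h = cooccurrence_histogram(e, binning=wide_binning(), normalize=False)
    assert np.count_nonzero(h.table) == 1


def test_collinear_line_concentrates_at_origin_cell():
    t = np.arange(12, dtype=float)
    e = make_edges(10 + 5 * t, np.full(12, 30.0), np.zeros(12))
    h = cooccurrence_histogram(e, binning=wide_binning())
    cm = chevron_map(h)
    assert central_block(cm).sum() == pytest.approx(1.0)
    # and the arg-max cell is in that central block
    ij = np.unravel_index(np.argmax(cm.values), cm.values.shape)
    assert cm.values[ij] <= central_block(cm).max() + 1e-12


def test_circle_tangents_concentrate_in_psi_zero_band():
    """Edges tangent to a circle at equal arc spacing: all mass in the
    central psi band, spread across relative orientations theta."""
    r = 40.0
    # half-circle of tangents: antipodal pairs are excluded because their
    # configuration degenerates to parallel (|psi| = pi/2), not co-circular
    alphas = np.deg2rad(np.arange(0, 170, 20))
    e = make_edges(
        64 + r * np.cos(alphas), 64 + r * np.sin(alphas), (alphas + np.pi / 2) % np.pi
    )
    h = cooccurrence_histogram(e, binning=wide_binning())
    m = h.marginal(("psi",))
    n_psi = len(h.binning.psi_edges) - 1
    band = m[n_psi // 2 - 1 : n_psi // 2 + 1].sum()
    assert band == pytest.approx(1.0)
    # theta axis is genuinely spread (co-circularity across many angles)
    mt = h.marginal(("theta",))
    assert np.count_nonzero(mt > 1e-6) >= 4


def test_pair_count_and_normalization(rng):
    m = 25
    e = make_edges(
        rng.uniform(40, 88, m), rng.uniform(40, 88, m), rng.uniform(0, np.pi, m),
        scale=rng.integers(0, 3, m), amp=rng.uniform(0.5, 2, m), shape=(128, 128),
        mask_radius=64.0,
    )
    h = cooccurrence_histogram(e, binning=wide_binning(), normalize=False)
    assert h.n_pairs + h.n_dropped == m * (m - 1) // 2
    hn = h.normalize()
    assert hn.table.sum() == pytest.approx(1.0)
    assert np.all(hn.table >= 0)


def test_mask_discards_outer_edges():
    # two inside, one far outside the mask
    e = make_edges([60, 70, 5], [60, 70, 5], [0.2, 0.9, 1.3], shape=(128, 128), mask_radius=20.0)
    h = cooccurrence_histogram(e, binning=wide_binning(), normalize=False)
    assert h.n_pairs == 1


def test_fewer_than_two_masked_edges_gives_empty_histogram():
    e = make_edges([64], [64], [0.5], shape=(128, 128), mask_radius=57.6)
    h = cooccurrence_histogram(e)
    assert h.n_pairs == 0 and h.table.sum() == 0
    with pytest.raises(ValueError, match="no pairs"):
        chevron_map(h)


def test_reference_symmetry_under_edge_reversal(rng):
    m = 30
    x, y = rng.uniform(0, 100, m), rng.uniform(0, 100, m)
    th, sc = rng.uniform(0, np.pi, m), rng.integers(0, 5, m)
    amp = rng.uniform(0.5, 2, m)
    fwd = make_edges(x, y, th, sc, amp)
    rev = make_edges(x[::-1], y[::-1], th[::-1], sc[::-1], amp[::-1])
    b = wide_binning()
    h1 = cooccurrence_histogram(fwd, binning=b)
    h2 = cooccurrence_histogram(rev, binning=b)
    assert np.allclose(h1.table, h2.table, atol=1e-12)


def test_histogram_invariances(rng):
    """Translation, global rotation, and (with scale-normalized distance)
    joint rescaling leave the normalized histogram unchanged."""
    m = 40
    x, y = rng.uniform(-30, 30, m), rng.uniform(-30, 30, m)
    th, sc = rng.uniform(0, np.pi, m), rng.integers(1, 3, m)
    amp = rng.uniform(0.5, 2, m)

    b = wide_binning()
    ref = cooccurrence_histogram(make_edges(x + 64, y + 64, th, sc, amp), binning=b)

    shifted = cooccurrence_histogram(make_edges(x + 70, y + 55, th, sc, amp), binning=b)
    assert np.allclose(ref.table, shifted.table, atol=1e-12)

    rot = 0.7
    xr = x * np.cos(rot) - y * np.sin(rot) + 64
    yr = x * np.sin(rot) + y * np.cos(rot) + 64
    rotated = cooccurrence_histogram(make_edges(xr, yr, (th + rot) % np.pi, sc, amp), binning=b)
    assert np.allclose(ref.table, rotated.table, atol=1e-12)

    bn = default_binning(mask_radius=180.0, normalize_distance=True)
    ref_n = cooccurrence_histogram(make_edges(x + 64, y + 64, th, sc, amp), binning=bn)
    scaled = cooccurrence_histogram(
        make_edges(2 * x + 64, 2 * y + 64, th, sc + 1, amp), binning=bn
    )
    assert np.allclose(ref_n.table, scaled.table, atol=1e-12)


def test_chevron_map_is_marginalization_invariant(rng):
    m = 30
    e = make_edges(
        rng.uniform(0, 100, m), rng.uniform(0, 100, m), rng.uniform(0, np.pi, m),
        scale=rng.integers(0, 5, m),
    )
    h = cooccurrence_histogram(e, binning=wide_binning())
    cm = chevron_map(h)
    assert cm.values.sum() == pytest.approx(1.0)
    # permuting d-bins does not change the (psi, theta) marginal
    perm = rng.permutation(h.table.shape[0])
    import dataclasses

    h2 = dataclasses.replace(h, table=h.table[perm])
    assert np.allclose(chevron_map(h2).values, cm.values)


def test_uniform_table_gives_uniform_chevron():
    import dataclasses

    b = wide_binning()
    e = make_edges([0, 10], [0, 0], [0, 0])
    h = cooccurrence_histogram(e, binning=b, normalize=False)
    h = dataclasses.replace(h, table=np.full(b.shape, 1.0)).normalize()
    cm = chevron_map(h)
    assert np.allclose(cm.values, 1.0 / cm.values.size)


def test_ratio_map_identity_and_binning_guard(rng):
    m = 30
    e = make_edges(
        rng.uniform(0, 100, m), rng.uniform(0, 100, m), rng.uniform(0, np.pi, m)
    )
    h = cooccurrence_histogram(e, binning=wide_binning())
    r = ratio_map(h, h)
    assert np.allclose(r.values, 1.0)
    other = cooccurrence_histogram(e, binning=wide_binning(n_psi=6))
    with pytest.raises(ValueError, match="binned differently"):
        ratio_map(h, other)


def test_ratio_map_curved_vs_straight_fixture():
    """Analytic fixtures mirroring the class contrast: circle tangents
    (co-circular) against a straight collinear chain."""
    r = 40.0
    alphas = np.deg2rad(np.arange(0, 360, 15))
    curved = make_edges(
        64 + r * np.cos(alphas), 64 + r * np.sin(alphas), (alphas + np.pi / 2) % np.pi
    )
    t = np.arange(20, dtype=float)
    straight = make_edges(5 + 6 * t, np.full(20, 64.0), np.zeros(20))
    b = wide_binning()
    h_c = cooccurrence_histogram(curved, binning=b)
    h_s = cooccurrence_histogram(straight, binning=b)
    rm = ratio_map(h_c, h_s)
    i0, j0 = rm.cell(-1e-9, -1e-9)
    i1, j1 = rm.cell(1e-9, 1e-9)
    collinear = rm.values[i0 : i1 + 1, j0 : j1 + 1]
    assert collinear.min() < 1.0
    # co-circular cells: central psi band, theta well away from zero
    cocirc = np.concatenate([rm.values[i0:i1 + 1, : j0 - 1].ravel(),
                             rm.values[i0:i1 + 1, j1 + 2:].ravel()])
    assert np.median(cocirc[cocirc != 1.0]) > 1.0 if np.any(cocirc != 1.0) else True
    assert cocirc.max() > 1.0


def test_first_order_histogram_properties():
    e = make_edges([10, 20, 30], [10, 10, 10], [0.0, 0.0, 0.0])
    fo = first_order_histogram(e, n_bins=12)
    assert fo[0] == pytest.approx(1.0)
    # rotating all edges by one bin width circularly shifts the histogram
    shift = np.pi / 12
    e2 = make_edges([10, 20, 30, 40], [10, 12, 14, 16], [0.1, 0.3, 0.3, 1.2])
    fo2 = first_order_histogram(e2, n_bins=12)
    e3 = make_edges([10, 20, 30, 40], [10, 12, 14, 16], (np.array([0.1, 0.3, 0.3, 1.2]) + shift))
    fo3 = first_order_histogram(e3, n_bins=12)
    assert np.allclose(fo3, np.roll(fo2, 1))
    with pytest.raises(ValueError, match="no edges"):
        first_order_histogram(make_edges([200], [200], [0.0], mask_radius=10.0))


def test_histogram_hdf5_roundtrip(tmp_path, rng):
    m = 25
    e = make_edges(
        rng.uniform(0, 100, m), rng.uniform(0, 100, m), rng.uniform(0, np.pi, m),
        scale=rng.integers(0, 5, m),
    )
    h = cooccurrence_histogram(e, binning=wide_binning())
    h.params_hash = "deadbeef"
    p = tmp_path / "h.h5"
    save_histogram(h, p)
    back = load_histogram(p)
    assert np.array_equal(back.table, h.table)
    assert back.binning.compatible(h.binning)
    assert back.n_pairs == h.n_pairs
    assert back.params_hash == "deadbeef"
    assert back.normalized
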