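import numpy as np
import pytest

import fibermap as fm
from fibermap.core import ContentError, FiberField, RegionFiberSpec
from fibermap.harmonic import assign_region_fibers, harmonic_lift, stiffness_matrix


def _slab_dirichlet(slab, endo_vec, epi_vec):
    n = len(slab.nodes)
    vec = np.zeros((n, 3))
    mask = np.zeros(n, dtype=bool)
    for tag, v in (("endo", endo_vec), ("epi", epi_vec)):
        idx = slab.surface_tags[tag]
        vec[idx] = v
        mask[idx] = True
    return FiberField(vec, mask)


@pytest.fixture(scope="module")
def fine_slab():
    return fm.make_slab_mesh((10.0, 10.0, 4.0), h=0.5)


def test_constant_boundary_data_fills_interior(fine_slab):
    d = _slab_dirichlet(fine_slab, [1.0, 0, 0], [1.0, 0, 0])
    lifted = harmonic_lift(fine_slab, d)
    assert np.allclose(lifted.vectors, [1.0, 0, 0], atol=1e-9)


def test_slab_matches_one_dimensional_closed_form(fine_slab):
    """Orthogonal data on the two faces: each raw component is linear in
    depth, so the mid-plane value is (1/2, 1/2, 0) within 2%."""
    d = _slab_dirichlet(fine_slab, [1.0, 0, 0], [0.0, 1.0, 0])
    lifted, raw, flags = harmonic_lift(fine_slab, d, return_raw=True)
    z = fine_slab.nodes[:, 2]
    frac = z / 4.0
    assert np.abs(raw[:, 0] - (1 - frac)).max() < 0.02
    assert np.abs(raw[:, 1] - frac).max() < 0.02
    mid = np.isclose(z, 2.0)
    assert np.abs(raw[mid][:, :2] - 0.5).max() < 0.02
    assert not flags.any()


def test_discrete_maximum_principle(fine_slab):
    d = _slab_dirichlet(fine_slab, [1.0, 0, 0], [0.0, 1.0, 0])
    _, raw, _ = harmonic_lift(fine_slab, d, return_raw=True)
    fixed = d.defined_mask
    for c in range(3):
        assert raw[~fixed, c].min() >= raw[fixed, c].min() - 1e-8
        assert raw[~fixed, c].max() <= raw[fixed, c].max() + 1e-8


def test_dirichlet_values_reproduced_exactly(shell_mesh, shell_spec):
    fib, _ = fm.analytic_fibers(shell_mesh, "circumferential", shell_spec)
    mask = np.zeros(len(shell_mesh.nodes), dtype=bool)
    for tag in ("endo", "epi"):
        mask[shell_mesh.surface_tags[tag]] = True
    d = FiberField(fib.vectors, mask)
    lifted = harmonic_lift(shell_mesh, d)
    dots = np.abs(np.sum(lifted.vectors[mask] * fib.vectors[mask], axis=1))
    assert np.allclose(dots, 1.0, atol=1e-9)


def test_stiffness_symmetric_and_permutation_invariant():
    slab = fm.make_slab_mesh((4.0, 4.0, 2.0), h=1.0)
    K = stiffness_matrix(slab)
    assert (K != K.T).nnz == 0
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(slab.nodes))
    inv = np.argsort(perm)
    permuted = fm.TetMesh(slab.nodes[perm], inv[slab.tets],
                          {k: inv[v] for k, v in slab.surface_tags.items()})
    d = _slab_dirichlet(slab, [1.0, 0, 0], [0.0, 1, 0])
    dp = FiberField(d.vectors[perm], d.defined_mask[perm])
    a = harmonic_lift(slab, d).vectors
    b = harmonic_lift(permuted, dp).vectors
    assert np.allclose(a[perm], b, atol=1e-9)


def test_no_dirichlet_nodes_rejected(fine_slab):
    empty = FiberField(np.zeros((len(fine_slab.nodes), 3)),
                       np.zeros(len(fine_slab.nodes), dtype=bool))
    with pytest.raises(ContentError):
        harmonic_lift(fine_slab, empty)


def test_sign_sweep_makes_antipodal_data_equivalent(fine_slab):
    d = _slab_dirichlet(fine_slab, [1.0, 0, 0], [1.0, 0, 0])
    rng = np.random.default_rng(5)
    flip = rng.random(len(fine_slab.nodes)) < 0.5
    vec = d.vectors.copy()
    vec[flip & d.defined_mask] *= -1.0
    flipped = FiberField(vec, d.defined_mask)
    a = harmonic_lift(fine_slab, d).vectors
    b = harmonic_lift(fine_slab, flipped).vectors
    assert np.allclose(np.abs(np.sum(a * b, axis=1)), 1.0, atol=1e-9)


def test_two_layer_angle_rotates_monotonically_through_wall(fine_slab):
    """Endo fibers along x, epi along y: the lifted fiber angle grows
    monotonically with depth along transmural lines of the slab."""
    d = _slab_dirichlet(fine_slab, [1.0, 0, 0], [0.0, 1.0, 0])
    lifted = harmonic_lift(fine_slab, d)
    z = fine_slab.nodes[:, 2]
    angles = np.arctan2(np.abs(lifted.vectors[:, 1]), np.abs(lifted.vectors[:, 0]))
    xy = np.round(fine_slab.nodes[:, :2] / 0.5).astype(int)
    key = xy[:, 0] * 10_000 + xy[:, 1]
    for col in np.unique(key)[:50]:
        sel = key == col
        order = np.argsort(z[sel])
        a = angles[sel][order]
        assert np.all(np.diff(a) >= -1e-9)


def test_region_fibers_single_and_two_regions(shell_mesh):
    endo = shell_mesh.surface_tags["endo"]
    labels = np.array(["all"] * len(endo), dtype=object)
    spec = RegionFiberSpec({"all": np.array([0.0, 0, 1.0])}, labels)
    field = assign_region_fibers(shell_mesh, spec, "endo")
    nodes = shell_mesh.nodes[endo]
    from fibermap.mapping import surface_normals
    n = surface_normals(shell_mesh, "endo")[endo]
    z = np.array([0.0, 0, 1.0])
    expected = z - n * (n @ z)[:, None]
    nrm = np.linalg.norm(expected, axis=1)
    ok = nrm > 1e-6
    expected[ok] /= nrm[ok, None]
    dots = np.abs(np.sum(field.vectors[endo][ok] * expected[ok], axis=1))
    assert np.allclose(dots, 1.0, atol=1e-9)
    # two hemispheric regions -> piecewise constant with equatorial seam
    labels2 = np.where(nodes[:, 2] >= 0, "north", "south").astype(object)
    spec2 = RegionFiberSpec({"north": np.array([1.0, 0, 0]),
                             "south": np.array([0.0, 1.0, 0])}, labels2)
    field2 = assign_region_fibers(shell_mesh, spec2, "endo")
    assert field2.defined_mask[endo].all()


def test_region_fibers_missing_region_rejected(shell_mesh):
    endo = shell_mesh.surface_tags["endo"]
    labels = np.array(["mystery"] * len(endo), dtype=object)
    spec = RegionFiberSpec({"known": np.array([1.0, 0, 0])}, labels)
    with pytest.raises(ContentError):
        assign_region_fibers(shell_mesh, spec, "endo")
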