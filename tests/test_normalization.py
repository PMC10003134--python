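import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from thinfilament.normalization import (fit_filament_axis, helical_axis_fit,
                                        monomer_centers_of_mass, normalize_frame,
                                        unwrap_signed_degrees)


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def test_monomer_com_matches_direct_mass_weighted_sum(ideal):
    structure, cmap = ideal
    rng = np.random.default_rng(1)
    coords = structure.positions + rng.normal(0, 0.3, structure.positions.shape)
    coms = monomer_centers_of_mass(coords, structure, cmap)
    for k, idx in enumerate(cmap.monomer_atom_indices(structure)):
        m = structure.masses[idx]
        expected = (m[:, None] * coords[idx]).sum(axis=0) / m.sum()
        np.testing.assert_allclose(coms[k], expected, atol=1e-12)


def test_single_and_two_point_monomers():
    # degenerate mass-weighting sanity on hand-built selections
    from thinfilament.models import ComponentMap, StructureModel
    s = StructureModel(
        chain_ids=np.array(["A", "B", "B", "C", "D"]),
        resids=np.array([1, 1, 2, 1, 1]),
        resnames=np.array(["X"] * 5), names=np.array(["C1", "C1", "C2", "C1", "C1"]),
        elements=np.array(["C"] * 5), masses=np.full(5, 12.011),
        positions=np.array([[1., 2, 3], [0, 0, 0], [2, 0, 0], [5, 5, 5], [9, 9, 9]]))
    cmap = ComponentMap(monomers={1: [("A", (1, 1))], 2: [("B", (1, 2))],
                                  3: [("C", (1, 1))], 4: [("D", (1, 1))]},
                        long_helix={1: 1, 2: 2, 3: 1, 4: 2})
    coms = monomer_centers_of_mass(s.positions, s, cmap)
    np.testing.assert_allclose(coms[0], [1, 2, 3])
    np.testing.assert_allclose(coms[1], [1, 0, 0])


def test_axis_fit_on_collinear_points_is_exact():
    z = np.linspace(-5, 5, 11)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z]) + np.array([1.0, 2.0, 0.0])
    c, u = fit_filament_axis(pts)
    np.testing.assert_allclose(np.abs(u), [0, 0, 1], atol=1e-12)
    # zero residual: all points on the line
    d = (pts - c) - np.outer((pts - c) @ u, u)
    assert np.linalg.norm(d, axis=1).max() < 1e-12


def test_axis_fit_matches_brute_force_minimizer():
    """TLS line vs direct numeric minimization over direction and offset."""
    rng = np.random.default_rng(3)
    pts = np.column_stack([rng.normal(0, 1, 26), rng.normal(0, 1, 26),
                           np.linspace(-30, 30, 26)])

    def sum_sq(params):
        th, ph, ox, oy = params
        u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        p0 = np.array([ox, oy, 0.0])
        d = (pts - p0) - np.outer((pts - p0) @ u, u)
        return (d**2).sum()

    c, u = fit_filament_axis(pts)
    res = minimize(sum_sq, x0=[1e-3, 0.0, 0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    d = (pts - c) - np.outer((pts - c) @ u, u)
    assert (d**2).sum() == pytest.approx(res.fun, abs=1e-8)


def test_axis_fit_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_filament_axis(np.zeros((2, 3)))
    with pytest.raises(ValueError):
        fit_filament_axis(np.full((5, 3), 3.14))


def test_helical_axis_fit_exact_on_ideal_filament(ideal):
    structure, cmap = ideal
    coms = monomer_centers_of_mass(structure.positions, structure, cmap)
    c, u = helical_axis_fit(coms)
    assert abs(u[2]) > 1 - 1e-12
    assert np.hypot(c[0], c[1]) < 1e-9


def test_normalized_frame_invariants(fluct):
    _, traj, cmap = fluct
    nf = normalize_frame(traj.frames[10], traj.structure, cmap)
    # rotation proper orthogonal
    assert np.linalg.det(nf.rotation) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(nf.rotation @ nf.rotation.T, np.eye(3), atol=1e-12)
    # mean z of monomer COMs at the origin
    assert abs(nf.z.mean()) < 1e-9
    # azimuthal regression intercept is zero
    slope, intercept = np.polyfit(nf.z, nf.phi_deg, 1)
    assert abs(intercept) < 1e-9
    # transform consistency: coords = rotation @ x + translation
    recon = traj.frames[10] @ nf.rotation.T + nf.translation
    np.testing.assert_allclose(recon, nf.coords, atol=1e-12)
    np.testing.assert_allclose(nf.to_original(nf.coords), traj.frames[10], atol=1e-10)


def test_normalization_idempotent(fluct):
    _, traj, cmap = fluct
    nf = normalize_frame(traj.frames[3], traj.structure, cmap)
    nf2 = normalize_frame(nf.coords, traj.structure, cmap)
    np.testing.assert_allclose(nf2.rotation, np.eye(3), atol=1e-7)
    np.testing.assert_allclose(nf2.translation, 0.0, atol=1e-7)


def test_rigid_body_invariance(fluct):
    """(r, z) per monomer and phi differences survive any proper rigid motion."""
    _, traj, cmap = fluct
    rng = np.random.default_rng(11)
    base = normalize_frame(traj.frames[0], traj.structure, cmap)
    for _ in range(3):
        R, t = random_rigid(rng)
        nf = normalize_frame(traj.frames[0] @ R.T + t, traj.structure, cmap)
        np.testing.assert_allclose(nf.r, base.r, atol=1e-8)
        np.testing.assert_allclose(nf.z, base.z, atol=1e-8)
        np.testing.assert_allclose(np.diff(nf.phi_deg), np.diff(base.phi_deg),
                                   atol=1e-8)


def test_signed_unwrap_handles_steps_past_minus_180():
    true = np.cumsum([0, -166.6, -195.0, -140.0, -166.6])
    wrapped = (true + 180.0) % 360.0 - 180.0
    rec = unwrap_signed_degrees(wrapped)
    np.testing.assert_allclose(np.diff(rec), np.diff(true), atol=1e-12)
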