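import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thinfilament.skeleton import (best_match_interval, coiled_coil_skeleton,
                                   find_extension_factor, local_helix_skeleton,
                                   rescale_along_skeleton)
from thinfilament.synth import generate_coiledcoil


def test_ideal_helix_skeleton_rise_and_radius():
    ca, _ = generate_coiledcoil(40, rise=0.15, helix_radius=0.23)
    skel = local_helix_skeleton(ca)
    assert skel.mean_rise == pytest.approx(0.150, abs=1e-3)
    assert skel.mean_radius == pytest.approx(0.23, abs=1e-3)
    # straight skeleton: points on the axis
    assert np.hypot(skel.points[:, 0], skel.points[:, 1]).max() < 1e-9


def test_skeleton_rise_0142():
    ca, _ = generate_coiledcoil(40, rise=0.142)
    assert local_helix_skeleton(ca).mean_rise == pytest.approx(0.142, abs=1e-3)


def test_skeleton_on_arc_matches_construction():
    """Helix bent onto a 10 nm arc: skeleton within 0.05 nm of the arc."""
    ca, _ = generate_coiledcoil(60, rise=0.15, curvature_radius=10.0)
    skel = local_helix_skeleton(ca)
    R = 10.0
    # arc in the x-z plane: (R(1-cos), 0, R sin)
    d = np.hypot(skel.points[:, 0] - R, skel.points[:, 2])
    assert np.abs(d - R).max() < 0.05
    assert np.abs(skel.points[:, 1]).max() < 0.05


def test_skeleton_rigid_invariance():
    ca, _ = generate_coiledcoil(30, rise=0.15)
    skel = local_helix_skeleton(ca)
    rng = np.random.default_rng(5)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-4, 4, 3)
    skel2 = local_helix_skeleton(ca @ R.T + t)
    np.testing.assert_allclose(skel2.points, skel.points @ R.T + t, atol=1e-9)
    np.testing.assert_allclose(skel2.rises, skel.rises, atol=1e-12)


def test_skeleton_errors():
    with pytest.raises(ValueError, match="at least 5"):
        local_helix_skeleton(np.zeros((4, 3)))
    ca, _ = generate_coiledcoil(20, rise=0.15)
    broken = ca.copy()
    broken[10:] += 2.0
    with pytest.raises(ValueError, match="chain break"):
        local_helix_skeleton(broken)


def test_coiled_coil_midcurve():
    a, b = generate_coiledcoil(30, rise=0.15, chain_separation=0.5)
    mid = coiled_coil_skeleton(local_helix_skeleton(a), local_helix_skeleton(b))
    np.testing.assert_allclose(mid[:, 0], 0.25, atol=1e-6)


def test_rescale_identity_and_straight_scaling():
    ca, _ = generate_coiledcoil(40, rise=0.142)
    skel = local_helix_skeleton(ca)
    same = rescale_along_skeleton(ca, skel, 1.0, anchor_residue=5)
    np.testing.assert_allclose(same, ca, atol=1e-9)

    scaled = rescale_along_skeleton(ca, skel, 1.082, anchor_residue=5)
    # straight skeleton along z: z-distances from the anchor scale, x/y intact
    np.testing.assert_allclose(scaled[:, :2], ca[:, :2], atol=1e-9)
    np.testing.assert_allclose(scaled[:, 2] - ca[5, 2],
                               1.082 * (ca[:, 2] - ca[5, 2]), atol=1e-9)
    # measured rise scales by the factor
    assert local_helix_skeleton(scaled).mean_rise == pytest.approx(
        0.142 * 1.082, abs=1e-3)


def test_rescale_round_trip_inverse():
    ca, _ = generate_coiledcoil(35, rise=0.15)
    skel = local_helix_skeleton(ca)
    out = rescale_along_skeleton(ca, skel, 1.07, anchor_residue=10)
    back = rescale_along_skeleton(out, local_helix_skeleton(out), 1 / 1.07,
                                  anchor_residue=10)
    np.testing.assert_allclose(back, ca, atol=1e-6)


def test_rescale_anchor_validation():
    ca, _ = generate_coiledcoil(20, rise=0.15)
    skel = local_helix_skeleton(ca)
    with pytest.raises(ValueError, match="outside"):
        rescale_along_skeleton(ca, skel, 1.1, anchor_residue=25)
    with pytest.raises(ValueError, match="positive"):
        rescale_along_skeleton(ca, skel, -1.0, anchor_residue=5)


def test_find_extension_factor_identity_and_recovery():
    ca, _ = generate_coiledcoil(50, rise=0.15)
    resids = np.arange(1, 51)
    f, res, dist = find_extension_factor(ca, resids, ca, resids, anchor_residue=10)
    assert f == pytest.approx(1.0, abs=1e-9)
    assert dist < 1e-9

    skel = local_helix_skeleton(ca)
    target = rescale_along_skeleton(ca, skel, 1.05, anchor_residue=10)
    f, res, dist = find_extension_factor(ca, resids, target, resids,
                                         anchor_residue=10, step=0.001)
    assert f == pytest.approx(1.05, abs=0.0015)

    far = ca + 5.0
    with pytest.raises(ValueError, match="no factor"):
        find_extension_factor(ca, resids, far, resids, anchor_residue=10,
                              factor_range=(0.95, 1.05))


def test_best_match_interval_tie_break_and_perturbation():
    ca, _ = generate_coiledcoil(80, rise=0.15)
    resids = np.arange(1, 81)
    candidates = [(i, j) for i in (10, 20, 30) for j in (50, 60, 70)]
    i, j, rmsd = best_match_interval(ca, resids, ca, resids, candidates)
    assert (i, j) == (10, 50)        # all-zero RMSD: lexicographic tie-break
    assert rmsd == pytest.approx(0.0, abs=1e-12)

    other = ca.copy()
    other[39:60] += 1.0              # displace residues 40-60
    i, j, rmsd = best_match_interval(ca, resids, other, resids, candidates)
    assert (i, j) == (10, 70)        # optimum avoids the displaced block
    assert rmsd < 1e-9

    with pytest.raises(ValueError, match="empty"):
        best_match_interval(ca, resids, ca, resids, [])
    with pytest.raises(ValueError, match="missing"):
        best_match_interval(ca, resids, ca, resids, [(1, 50)])
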