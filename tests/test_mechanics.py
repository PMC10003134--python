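import numpy as np
import pytest

from thinfilament.mechanics import (central_segment_observables, end_tangent_cosine,
                                    equipartition_stiffness, fit_bend_parabolas,
                                    persistence_length, sliding_window_variance,
                                    summarize_mechanics)
from thinfilament.models import AnalysisConfig, BOLTZMANN
from thinfilament.normalization import normalize_frame


# ---------------------------------------------------------------- parabolas

def _frame_from_points(points):
    """Minimal NormalizedFrame stand-in for the parabola fit."""
    class NF:
        com_xyz = np.asarray(points, dtype=float)
    return NF()


def test_straight_filament_has_zero_curvature():
    z = np.linspace(-30, 30, 26)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    kx, bx, ky, by = fit_bend_parabolas(_frame_from_points(pts), points="com")
    assert max(abs(kx), abs(bx), abs(ky), abs(by)) < 1e-12


def test_constructed_parabola_recovered_exactly():
    z = np.linspace(-30, 30, 26)
    pts = np.column_stack([0.5 * 0.001 * z**2, np.zeros_like(z), z])
    kx, _, ky, _ = fit_bend_parabolas(_frame_from_points(pts), points="com")
    assert kx == pytest.approx(0.001, abs=1e-12)
    assert ky == pytest.approx(0.0, abs=1e-12)


def test_parabola_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(2)
    z = np.linspace(-30, 30, 26)
    x = 0.5 * 2e-3 * z**2 + 0.3 + rng.normal(0, 0.1, z.size)
    y = rng.normal(0, 0.1, z.size)
    pts = np.column_stack([x, y, z])
    kx, bx, ky, by = fit_bend_parabolas(_frame_from_points(pts), points="com")
    A = np.column_stack([0.5 * z**2, np.ones_like(z)])
    ref_x = np.linalg.solve(A.T @ A, A.T @ x)
    ref_y = np.linalg.solve(A.T @ A, A.T @ y)
    resid = ((x - A @ [kx, bx])**2).sum()
    assert resid == pytest.approx(((x - A @ ref_x)**2).sum(), abs=1e-10)
    assert [ky, by] == pytest.approx(list(ref_y), abs=1e-10)


def test_degenerate_z_spread_rejected():
    pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="degenerate"):
        fit_bend_parabolas(_frame_from_points(pts), points="com")


# -------------------------------------------------------------- end tangent

def test_end_tangent_closed_forms():
    assert end_tangent_cosine(0.0, 0.0, 30.0) == 1.0
    assert end_tangent_cosine(1.0, 0.0, 1.0) == pytest.approx(1 / np.sqrt(2))


def test_end_tangent_matches_finite_difference_tangent():
    kx, ky, l = 3e-3, -1.5e-3, 28.0
    cos_a = end_tangent_cosine(kx, ky, l)
    h = 1e-6
    tangent = np.array([0.5 * kx * ((l + h)**2 - (l - h)**2) / (2 * h),
                        0.5 * ky * ((l + h)**2 - (l - h)**2) / (2 * h), 1.0])
    ref = tangent[2] / np.linalg.norm(tangent)
    assert cos_a == pytest.approx(ref, abs=1e-10)


# -------------------------------------------------------- persistence length

def test_persistence_length_closed_form():
    xi, Kb = persistence_length(np.full(10, np.exp(-1.0)), 35.0, 300.0, BOLTZMANN)
    assert xi == pytest.approx(35e-9, rel=1e-12)
    assert Kb == pytest.approx(35e-9 * BOLTZMANN * 300.0, rel=1e-12)


def test_persistence_length_flags_no_bending():
    xi, Kb = persistence_length(np.ones(5), 35.0, 300.0, BOLTZMANN)
    assert np.isinf(xi) and np.isinf(Kb)
    with pytest.raises(ValueError):
        persistence_length(np.full(5, -0.2), 35.0, 300.0, BOLTZMANN)


# ------------------------------------------------------ segment / equipartition

def test_segment_observables_on_ideal_filament(ideal, ideal_params):
    structure, cmap = ideal
    nf = normalize_frame(structure.positions, structure, cmap)
    # literal z-axis azimuths: exact index algebra on the ideal helix
    cfg = AnalysisConfig(azimuth_reference="z")
    L, psi = central_segment_observables(nf, cfg)
    assert L == pytest.approx(16 * ideal_params.d0, abs=1e-9)
    assert abs(psi) == pytest.approx(np.radians(16 * ideal_params.phi0), abs=1e-9)
    # the bent-centerline default only differs by the tiny static
    # parabola correction of the helical offsets
    _, psi_p = central_segment_observables(nf, AnalysisConfig())
    assert abs(psi_p) == pytest.approx(np.radians(16 * ideal_params.phi0), abs=0.01)


def test_window_spanning_series_equals_plain_variance():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 2.0, 500)
    assert sliding_window_variance(x, 500) == pytest.approx(np.var(x, ddof=1))
    assert sliding_window_variance(x, 10_000) == pytest.approx(np.var(x, ddof=1))


def test_equipartition_recovery_on_iid_series():
    """K and G recovered within 15% from i.i.d. Gaussian fluctuations."""
    rng = np.random.default_rng(8)
    T, kT = 300.0, BOLTZMANN * 300.0
    L0 = 44e-9
    K0, G0 = 48e-9, 4e-26
    n = 2000
    L = (L0 + rng.normal(0, np.sqrt(kT * L0 / K0), n)) * 1e9  # nm
    psi = rng.normal(0, np.sqrt(kT * L0 / G0), n)
    K, G, L_mean = equipartition_stiffness(L, psi, 80, T, BOLTZMANN)
    assert K == pytest.approx(K0, rel=0.15)
    assert G == pytest.approx(G0, rel=0.15)
    assert L_mean == pytest.approx(L0, rel=1e-3)


def test_stiffness_invariant_under_psi_offset():
    rng = np.random.default_rng(9)
    L = 44.0 + rng.normal(0, 0.05, 800)
    psi = rng.normal(0, 0.06, 800)
    K1, G1, _ = equipartition_stiffness(L, psi, 80, 300.0, BOLTZMANN)
    K2, G2, _ = equipartition_stiffness(L, psi + 5.0, 80, 300.0, BOLTZMANN)
    assert G1 == pytest.approx(G2, rel=1e-12)
    assert K1 == pytest.approx(K2, rel=1e-12)


def test_zero_variance_flags_infinite_stiffness():
    K, G, _ = equipartition_stiffness(np.full(100, 44.0), np.zeros(100), 10,
                                      300.0, BOLTZMANN)
    assert np.isinf(K) and np.isinf(G)


# ----------------------------------------------------------------- pipeline

def test_summarize_mechanics_identity_and_settings(fluct, config):
    _, traj, cmap = fluct
    props, table = summarize_mechanics(traj, cmap, config)
    # worm-like-chain identity Kb = xi kB T
    assert props.Kb == pytest.approx(props.xi_m * BOLTZMANN * config.temperature,
                                     rel=1e-12)
    assert set(table.columns) >= {"time_ps", "cos_alpha", "L_nm", "psi_rad"}
    assert np.all(table.cos_alpha > 0) and np.all(table.cos_alpha <= 1)
    assert props.second_half["longitudinal_stiffness_N"] > 0
    # psi series continuous after unwrap: no 2-pi jumps frame to frame
    assert np.abs(np.diff(table.psi_rad)).max() < np.pi
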