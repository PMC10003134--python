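"""Bending, longitudinal and torsional stiffness estimators.

Bending: per frame the monomer centers of mass are fitted with parabolas
x = kx z²/2 + bx and y = ky z²/2 + by; the cosine of the end-tangent
angle, cos a = 1/sqrt(1 + l²(kx² + ky²)), is averaged over frames and
inverted through the worm-like-chain relation <cos a> = exp(-l/xi) to
give the persistence length xi and bending stiffness Kb = xi kB T.

Longitudinal/torsional: the axial extension L and twist Psi of the
central segment (between the 5th/6th monomers from either end) are
tracked over time; equipartition gives K = kB T <L> / <dL²> and
G = kB T <L> / <dPsi²>, the variances taken within a sliding time
window and averaged over window positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import AnalysisConfig, ComponentMap, FilamentTrajectory
from .normalization import (NormalizedFrame, normalize_frame,
                            unwrap_signed_degrees)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- bending

def fit_bend_parabolas(nframe: NormalizedFrame,
                       points: str = "com") -> tuple[float, float, float, float]:
    """Least-squares parabola coefficients (kx, bx, ky, by) for one frame.

    ``points`` selects the point set describing the filament centerline:

    - ``"com"`` (default): the raw monomer COMs.  The static helical
      offset of the COMs largely cancels in the quadratic fit because
      consecutive monomers sit nearly opposite the axis.
    - ``"midpoints"``: midpoints of adjacent monomer COM pairs, which
      trace the centerline with a much smaller helical ripple.
    """
    if points == "midpoints":
        pts = 0.5 * (nframe.com_xyz[1:] + nframe.com_xyz[:-1])
    elif points == "com":
        pts = nframe.com_xyz
    else:
        raise ValueError("points must be 'midpoints' or 'com'")
    if len(pts) < 3:
        raise ValueError("parabola fit needs at least 3 points")
    z = pts[:, 2]
    if np.ptp(z) < 1e-9:
        raise ValueError("degenerate z spread for parabola fit")
    design = np.column_stack([0.5 * z**2, np.ones_like(z)])
    (kx, bx), *_ = np.linalg.lstsq(design, pts[:, 0], rcond=None)
    (ky, by), *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    return float(kx), float(bx), float(ky), float(by)


def end_tangent_cosine(kx, ky, l: float):
    """cos of the angle between z and the parabola tangent at z = l."""
    if l <= 0:
        raise ValueError("half-length l must be positive")
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    return 1.0 / np.sqrt(1.0 + l**2 * (kx**2 + ky**2))


def persistence_length(cos_series, l_nm: float, temperature: float,
                       kB: float) -> tuple[float, float]:
    """Worm-like-chain persistence length xi (m) and Kb = xi kB T (N·m²).

    Inverts <cos a> = exp(-l/xi).  A fluctuation-free series
    (<cos a> >= 1) yields (inf, inf).
    """
    mean_cos = float(np.mean(cos_series))
    if mean_cos <= 0:
        raise ValueError("mean end-tangent cosine must be positive")
    if mean_cos >= 1.0:
        log.warning("no bending signal (<cos a> >= 1); persistence length infinite")
        return np.inf, np.inf
    xi_m = -l_nm * 1e-9 / np.log(mean_cos)
    return xi_m, xi_m * kB * temperature


# ------------------------------------------------- central segment L, Psi

def _endpoint_monomers(n: int, offset: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """1-based monomer index pairs defining the central-segment endpoints."""
    if n < 2 * offset + 2:
        raise ValueError(f"need at least {2 * offset + 2} monomers for "
                         f"segment offset {offset}")
    return (offset, offset + 1), (n - offset, n - offset + 1)


def central_segment_observables(nframe: NormalizedFrame, config: AnalysisConfig,
                                bend: tuple[float, float, float, float] | None = None,
                                ) -> tuple[float, float]:
    """Axial projection L (nm) and twist Psi (radians) of the central segment.

    Endpoint axial positions are the mean z of the two monomers on each
    side; endpoint azimuths are (by default) the mean of the two monomers'
    unwrapped azimuths.  With ``config.azimuth_reference == "parabola"``
    the azimuths are measured about the frame's bent centerline (the
    fitted parabola) rather than the z-axis, which decouples the twist
    observable from bending.
    """
    n = len(nframe.z)
    (a1, a2), (b1, b2) = _endpoint_monomers(n, config.segment_offset)
    lo = np.array([a1, a2]) - 1
    hi = np.array([b1, b2]) - 1

    z = nframe.z
    L = float(z[hi].mean() - z[lo].mean())

    xy = nframe.com_xyz[:, :2].copy()
    if config.azimuth_reference == "parabola":
        if bend is None:
            bend = fit_bend_parabolas(nframe)
        kx, bx, ky, by = bend
        xy[:, 0] -= 0.5 * kx * z**2 + bx
        xy[:, 1] -= 0.5 * ky * z**2 + by
    phi = unwrap_signed_degrees(np.degrees(np.arctan2(xy[:, 1], xy[:, 0])))

    if config.segment_endpoint == "monomer_mean":
        psi = np.radians(phi[hi].mean() - phi[lo].mean())
    else:  # combined_com: azimuth of the mass-weighted two-monomer center
        masses = np.array([_monomer_mass(nframe, i) for i in range(n)])

        def com_phi(sel: np.ndarray) -> float:
            w = masses[sel] / masses[sel].sum()
            c = w @ nframe.com_xyz[sel]
            return np.degrees(np.arctan2(c[1], c[0]))

        psi = np.radians(com_phi(hi) - com_phi(lo))
    return L, float(psi)


def _monomer_mass(nframe: NormalizedFrame, i: int) -> float:
    idx = np.concatenate([nframe.structure.atom_indices(c, rng)
                          for c, rng in nframe.cmap.monomers[i + 1]])
    return float(nframe.structure.masses[idx].sum())


# ----------------------------------------------------------- equipartition

def sliding_window_variance(x: np.ndarray, window: int) -> float:
    """Mean over sliding windows (stride 1) of the within-window variance.

    Uses the unbiased (n-1) estimator within each window.  A window at
    least as long as the series degrades to the plain sample variance.
    """
    x = np.asarray(x, dtype=float)
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    if window >= len(x):
        return float(np.var(x, ddof=1))
    views = np.lib.stride_tricks.sliding_window_view(x, window)
    return float(np.var(views, axis=1, ddof=1).mean())


def equipartition_stiffness(L_nm: np.ndarray, psi_rad: np.ndarray,
                            window: int, temperature: float, kB: float,
                            ) -> tuple[float, float, float]:
    """(K in N, G in N·m², <L> in m) from equipartition of L and Psi.

    K <dL²> / <L> = kB T and G <dPsi²> / <L> = kB T, with the variances
    averaged over sliding windows of ``window`` frames.
    """
    L_m = np.asarray(L_nm, dtype=float) * 1e-9
    psi_rad = np.asarray(psi_rad, dtype=float)
    var_L = sliding_window_variance(L_m, window)
    var_psi = sliding_window_variance(psi_rad, window)
    L_mean = float(L_m.mean())
    kT = kB * temperature
    # variances at the level of rounding noise count as zero fluctuation
    eps = np.finfo(float).eps
    floor_L = (16 * eps * max(abs(L_m).max(), eps)) ** 2
    floor_psi = (16 * eps * max(np.abs(psi_rad).max(), 1.0)) ** 2
    K = kT * L_mean / var_L if var_L > floor_L else np.inf
    G = kT * L_mean / var_psi if var_psi > floor_psi else np.inf
    if not np.isfinite(K) or not np.isfinite(G):
        log.warning("zero fluctuation variance; stiffness reported as infinite")
    return K, G, L_mean


# ------------------------------------------------------------- trajectory

@dataclass
class MechanicalProps:
    """Stiffness summary of one trajectory (SI units)."""

    xi_m: float                   # persistence length, m
    Kb: float                     # bending stiffness, N·m²
    K: float                      # longitudinal stiffness, N
    G: float                      # torsional stiffness, N·m²
    L_mean_m: float               # mean central-segment length, m
    half_length_nm: float         # l of the WLC estimator, nm
    window_ns: float
    second_half: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "persistence_length_m": self.xi_m,
            "bending_stiffness_Nm2": self.Kb,
            "longitudinal_stiffness_N": self.K,
            "torsional_stiffness_Nm2": self.G,
            "segment_length_mean_m": self.L_mean_m,
            "half_length_nm": self.half_length_nm,
            "window_ns": self.window_ns,
            "second_half": self.second_half,
            "settings": self.settings,
        }


def summarize_mechanics(traj: FilamentTrajectory, cmap: ComponentMap,
                        config: AnalysisConfig,
                        bend_points: str = "com",
                        ) -> tuple[MechanicalProps, pd.DataFrame]:
    """Run the full mechanics analysis over a trajectory.

    Returns the stiffness summary (full trajectory plus second-half
    values) and a per-frame table of the raw observables.
    """
    cache = cmap.monomer_atom_indices(traj.structure)
    n_frames = traj.n_frames
    excl = config.end_exclusion
    n = cmap.n_monomers
    if n - 2 * excl < 3:
        raise ValueError("too few monomers after end exclusion")

    kx = np.empty(n_frames)
    ky = np.empty(n_frames)
    L = np.empty(n_frames)
    psi = np.empty(n_frames)
    extent = np.empty(n_frames)
    for f in range(n_frames):
        nf = normalize_frame(traj.frames[f], traj.structure, cmap, cache)
        bend = fit_bend_parabolas(nf, points=bend_points)
        kx[f], _, ky[f], _ = bend
        L[f], psi[f] = central_segment_observables(nf, config, bend=bend)
        z_inc = nf.z[excl:n - excl] if excl else nf.z
        extent[f] = np.ptp(z_inc)
    psi = np.unwrap(psi)

    l_nm = 0.5 * float(extent.mean())
    cos_a = end_tangent_cosine(kx, ky, l_nm)
    window = config.window_frames(traj.frame_interval)

    xi, Kb = persistence_length(cos_a, l_nm, config.temperature, config.kB)
    K, G, L_mean = equipartition_stiffness(L, psi, window, config.temperature, config.kB)

    half = traj.second_half_mask()
    xi_h, Kb_h = persistence_length(cos_a[half], l_nm, config.temperature, config.kB)
    K_h, G_h, L_mean_h = equipartition_stiffness(L[half], psi[half], window,
                                                 config.temperature, config.kB)

    frame_table = pd.DataFrame({
        "time_ps": traj.times,
        "kx_per_nm": kx, "ky_per_nm": ky, "cos_alpha": cos_a,
        "L_nm": L, "psi_rad": psi,
    })
    props = MechanicalProps(
        xi_m=xi, Kb=Kb, K=K, G=G, L_mean_m=L_mean,
        half_length_nm=l_nm, window_ns=config.window_ns,
        second_half={
            "persistence_length_m": xi_h, "bending_stiffness_Nm2": Kb_h,
            "longitudinal_stiffness_N": K_h, "torsional_stiffness_Nm2": G_h,
            "segment_length_mean_m": L_mean_h,
        },
        settings={
            "end_exclusion": excl, "segment_offset": config.segment_offset,
            "azimuth_reference": config.azimuth_reference,
            "segment_endpoint": config.segment_endpoint,
            "bend_fit_points": bend_points,
            "window_frames": window, "temperature_K": config.temperature,
        },
    )
    return props, frame_table
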