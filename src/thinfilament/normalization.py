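"""Per-frame removal of rigid-body motion.

Each frame is normalized by (i) fitting the filament axis as the
orthogonal-least-squares line through the monomer centers of mass,
(ii) rotating that axis onto z and translating the COM centroid to the
origin, and (iii) rotating about z so that the linear regression of the
monomer azimuth on z has zero intercept.  All downstream geometry
(helix parameters, bending, twist, Tpm profiles) is computed on the
normalized frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ComponentMap, StructureModel


def monomer_centers_of_mass(coords: np.ndarray, structure: StructureModel,
                            cmap: ComponentMap,
                            index_cache: list[np.ndarray] | None = None) -> np.ndarray:
    """Mass-weighted centers of the monomers, ordered by monomer index.

    ``index_cache`` (from :meth:`ComponentMap.monomer_atom_indices`) avoids
    re-selecting atoms on every frame of a trajectory.
    """
    idx_sets = index_cache if index_cache is not None else cmap.monomer_atom_indices(structure)
    coms = np.empty((len(idx_sets), 3))
    for k, idx in enumerate(idx_sets):
        m = structure.masses[idx]
        coms[k] = m @ coords[idx] / m.sum()
    return coms


def fit_filament_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through ``points``.

    Returns (point on line, unit direction).  The line is the principal
    axis of the centered point set, which minimizes the sum of squared
    perpendicular distances.  The direction is oriented from the first
    point toward the last.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("axis fit needs at least 3 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    if np.max(np.linalg.norm(centered, axis=1)) < 1e-12:
        raise ValueError("points coincident; axis direction undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ (points[-1] - points[0]) < 0:
        direction = -direction
    return centroid, direction


def _rotation_onto_z(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking the unit vector ``direction`` to (0, 0, 1)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(direction, z)
    c = float(direction @ z)
    s = np.linalg.norm(v)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def unwrap_degrees(phi: np.ndarray) -> np.ndarray:
    """Nearest-branch unwrap of an angle sequence in degrees."""
    return np.unwrap(np.asarray(phi, dtype=float), period=360.0)


def unwrap_signed_degrees(phi: np.ndarray, step_range: tuple[float, float] = (-360.0, 0.0),
                          ) -> np.ndarray:
    """Unwrap an angle sequence whose true steps lie in ``step_range``.

    The F-actin genetic helix is left-handed with steps near -166.6
    degrees; azimuthal perturbations (bending of the filament) can push
    a step past -180 degrees, where the nearest-branch convention of
    ``np.unwrap`` would flip it to +~180.  Mapping each raw step into
    (-360, 0] instead keeps the unwrap correct for any left-handed step.
    """
    phi = np.asarray(phi, dtype=float)
    lo, hi = step_range
    width = hi - lo
    steps = np.diff(phi)
    steps = (steps - lo) % width + lo
    return np.concatenate([[phi[0]], phi[0] + np.cumsum(steps)])


def helical_axis_fit(points: np.ndarray, tol: float = 1e-13,
                     max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Filament axis fit with helical-offset and bending biases removed.

    The plain principal axis of the monomer COMs is systematically
    tilted for a finite helix whose length is not an integer number of
    turns (the residual sum over z-weighted radial unit vectors does
    not cancel).  This fit iterates a joint decomposition into axis +
    smooth quadratic centerline + constant-radius helical offset:

    1. in the current axis frame, subtract the current quadratic bend
       estimate and read each point's azimuth about that centerline;
    2. strip the mean-radius helical offset at those azimuths;
    3. refit x(z), y(z) of the stripped points with a full quadratic;
       absorb its linear and constant parts into the axis update and
       keep the curvature as the new bend estimate.

    On an ideal helix the fixed point is the exact construction axis;
    on a bent helix the curvature is carried by the quadratic term so
    the axis does not tilt with the bend.
    """
    points = np.asarray(points, dtype=float)
    c, u = fit_filament_axis(points)
    kx = ky = 0.0

    def step(u, c, kx, ky):
        rot = _rotation_onto_z(u)
        local = (points - c) @ rot.T
        z = local[:, 2] - local[:, 2].mean()
        qx = local[:, 0] - 0.5 * kx * z**2
        qy = local[:, 1] - 0.5 * ky * z**2
        rbar = np.hypot(qx, qy).mean()
        theta = np.arctan2(qy, qx)
        clx = local[:, 0] - rbar * np.cos(theta)
        cly = local[:, 1] - rbar * np.sin(theta)
        design = np.column_stack([0.5 * z**2, z, np.ones_like(z)])
        coef = np.linalg.solve(design.T @ design,
                               design.T @ np.column_stack([clx, cly]))
        (kx2, cx, bx), (ky2, cy, by) = coef[:, 0], coef[:, 1]
        v = np.array([cx, cy, 1.0])
        v /= np.linalg.norm(v)
        u_new = rot.T @ v
        if u_new @ u < 0:
            u_new = -u_new
        c_new = c + rot.T @ np.array([bx, by, 0.0])
        shift = np.linalg.norm(np.cross(u_new, u)) + np.hypot(bx, by)
        return u_new, c_new, float(kx2), float(ky2), shift

    # plain fixed-point convergence is linear with a rate close to 1;
    # Aitken extrapolation along the slow mode is attempted every third
    # iteration and accepted only when it shrinks the step residual
    history: list[np.ndarray] = []
    for it in range(max_iter):
        u, c, kx, ky, shift = step(u, c, kx, ky)
        if shift < tol:
            break
        history.append(np.concatenate([u, c, [kx, ky]]))
        if len(history) == 3:
            s0, s1, s2 = history
            d1, d2 = s1 - s0, s2 - s1
            denom = float(d1 @ d1)
            lam = float(d1 @ d2) / denom if denom > 0 else 0.0
            if 0.0 < lam < 0.999:
                s_ex = s2 + d2 * (lam / (1.0 - lam))
                u_try = s_ex[:3] / np.linalg.norm(s_ex[:3])
                c_try, k_try = s_ex[3:6], s_ex[6:8]
                trial = step(u_try, c_try, k_try[0], k_try[1])
                if trial[4] < shift:
                    u, c, kx, ky, shift = trial
                    if shift < tol:
                        break
            history = []
    if u @ (points[-1] - points[0]) < 0:
        u = -u
    return c, u


@dataclass
class NormalizedFrame:
    """A frame after rigid-body removal.

    ``phi_deg`` is the monomer-COM azimuth sequence, unwrapped along the
    monomer index (for the left-handed genetic helix the steps are
    negative, about -166.6 degrees).
    """

    coords: np.ndarray             # (n_atoms, 3), nm
    com_xyz: np.ndarray            # (n_monomers, 3), nm
    r: np.ndarray                  # (n_monomers,), nm
    phi_deg: np.ndarray            # (n_monomers,), degrees, unwrapped
    z: np.ndarray                  # (n_monomers,), nm
    rotation: np.ndarray           # (3, 3) proper orthogonal
    translation: np.ndarray        # (3,) nm; x_norm = rotation @ x + translation
    structure: StructureModel
    cmap: ComponentMap

    def to_original(self, coords: np.ndarray) -> np.ndarray:
        """Map normalized-frame coordinates back to the input frame."""
        return (coords - self.translation) @ self.rotation

    def cylindrical_of(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r, phi_deg in (-180, 180], z) of points in the normalized frame."""
        r = np.hypot(coords[..., 0], coords[..., 1])
        phi = np.degrees(np.arctan2(coords[..., 1], coords[..., 0]))
        return r, phi, coords[..., 2]


def normalize_frame(coords: np.ndarray, structure: StructureModel,
                    cmap: ComponentMap,
                    index_cache: list[np.ndarray] | None = None) -> NormalizedFrame:
    """Remove rigid-body motion from one frame (see module docstring)."""
    coms = monomer_centers_of_mass(coords, structure, cmap, index_cache)
    centroid, direction = helical_axis_fit(coms)
    rot = _rotation_onto_z(direction)
    coords_n = (coords - centroid) @ rot.T
    coms_n = (coms - centroid) @ rot.T
    # pin the COM centroid to the origin exactly
    zshift = coms_n[:, 2].mean()
    coords_n[:, 2] -= zshift
    coms_n[:, 2] -= zshift

    phi = unwrap_signed_degrees(np.degrees(np.arctan2(coms_n[:, 1], coms_n[:, 0])))
    z = coms_n[:, 2]
    slope, intercept = np.polyfit(z, phi, 1)
    a = np.radians(-intercept)
    rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                   [np.sin(a), np.cos(a), 0.0],
                   [0.0, 0.0, 1.0]])
    coords_n = coords_n @ rz.T
    coms_n = coms_n @ rz.T

    rotation = rz @ rot
    translation = -rotation @ centroid - np.array([0.0, 0.0, zshift])
    r = np.hypot(coms_n[:, 0], coms_n[:, 1])
    return NormalizedFrame(coords=coords_n, com_xyz=coms_n, r=r,
                           phi_deg=phi - intercept, z=z,
                           rotation=rotation, translation=translation,
                           structure=structure, cmap=cmap)
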