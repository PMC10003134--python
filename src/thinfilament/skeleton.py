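"""Coiled-coil skeleton operators (TWISTER-style local-axis scheme).

The local helix axis at residue i is built from four consecutive
Calpha positions: the bond-angle bisectors at residues i and i+1 both
point from the backbone toward the local axis and are perpendicular to
it, so their cross product gives the local axis direction and the
chord geometry gives the local radius and per-residue rise.  The
resulting per-residue skeleton supports arc-length rescaling of a
chain along its own axis (the "extend along the skeleton" operation of
model building), an extension-factor scan with a Calpha coincidence
criterion, and a best-match interval search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CHAIN_BREAK_NM = 0.45  # max Calpha-Calpha distance within a chain


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class CoiledCoilSkeleton:
    """Per-residue local-axis curve of one alpha-helix.

    ``residue_offset`` is the index (into the input Calpha trace) of the
    first residue that carries a skeleton point; the window construction
    trims one residue at the start and two at the end.
    """

    points: np.ndarray        # (m, 3) skeleton points, nm
    axes: np.ndarray          # (m, 3) local axis unit vectors
    rises: np.ndarray         # (m-1,) per-residue rise, nm
    radii: np.ndarray         # (m,) local radius, nm
    residue_offset: int

    @property
    def mean_rise(self) -> float:
        return float(np.mean(self.rises))

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


def local_helix_skeleton(ca_trace: np.ndarray) -> CoiledCoilSkeleton:
    """Skeleton of an alpha-helical Calpha trace (nm coordinates).

    Raises on chain breaks (consecutive Calpha further apart than
    0.45 nm) and on traces shorter than 5 residues.
    """
    ca = np.asarray(ca_trace, dtype=float)
    n = len(ca)
    if n < 5:
        raise ValueError("need at least 5 residues for a skeleton")
    steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if np.any(steps > CHAIN_BREAK_NM):
        bad = int(np.argmax(steps > CHAIN_BREAK_NM))
        raise ValueError(f"chain break between residues {bad} and {bad + 1} "
                         f"({steps[bad]:.3f} nm > {CHAIN_BREAK_NM} nm)")

    # bond-angle bisectors, defined for residues 1..n-2
    bis = np.empty((n, 3))
    bis[:] = np.nan
    for i in range(1, n - 1):
        bis[i] = _unit(_unit(ca[i - 1] - ca[i]) + _unit(ca[i + 1] - ca[i]))

    points, axes, radii = [], [], []
    for i in range(1, n - 2):
        axis = np.cross(bis[i], bis[i + 1])
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            raise ValueError(f"degenerate local axis at residue {i}")
        axis /= norm
        chord = ca[i + 1] - ca[i]
        if axis @ chord < 0:
            axis = -axis
        rise = axis @ chord
        perp = chord - rise * axis
        # twist between consecutive bisectors about the local axis
        b1 = _unit(bis[i] - (bis[i] @ axis) * axis)
        b2 = _unit(bis[i + 1] - (bis[i + 1] @ axis) * axis)
        twist = np.arccos(np.clip(b1 @ b2, -1.0, 1.0))
        if twist < 1e-9:
            raise ValueError(f"degenerate twist at residue {i}")
        radius = np.linalg.norm(perp) / (2.0 * np.sin(twist / 2.0))
        points.append(ca[i] + radius * b1)
        axes.append(axis)
        radii.append(radius)
    # one more skeleton point from the last usable bisector, on the last axis
    i_last = n - 2
    b_last = _unit(bis[i_last] - (bis[i_last] @ axes[-1]) * axes[-1])
    points.append(ca[i_last] + radii[-1] * b_last)
    axes.append(axes[-1])
    radii.append(radii[-1])

    points = np.array(points)
    axes = np.array(axes)
    rises = np.einsum("ij,ij->i", np.diff(points, axis=0), axes[:-1])
    return CoiledCoilSkeleton(points=points, axes=axes, rises=rises,
                              radii=np.array(radii), residue_offset=1)


def coiled_coil_skeleton(skel_a: CoiledCoilSkeleton,
                         skel_b: CoiledCoilSkeleton) -> np.ndarray:
    """Midpoint curve of the two single-helix skeletons (dimer axis)."""
    m = min(len(skel_a.points), len(skel_b.points))
    return 0.5 * (skel_a.points[:m] + skel_b.points[:m])


# ------------------------------------------------------------- rescaling

def _transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent / normal / binormal frames along a polyline, with the
    normal parallel-transported to avoid spurious frame twist."""
    m = len(points)
    tangents = np.empty((m, 3))
    tangents[0] = _unit(points[1] - points[0])
    tangents[-1] = _unit(points[-1] - points[-2])
    for k in range(1, m - 1):
        tangents[k] = _unit(points[k + 1] - points[k - 1])
    normals = np.empty((m, 3))
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ tangents[0]) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    normals[0] = _unit(seed - (seed @ tangents[0]) * tangents[0])
    for k in range(1, m):
        v = np.cross(tangents[k - 1], tangents[k])
        s = np.linalg.norm(v)
        c = float(tangents[k - 1] @ tangents[k])
        if s < 1e-12:
            normals[k] = normals[k - 1]
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
            normals[k] = _unit(R @ normals[k - 1])
        normals[k] = _unit(normals[k] - (normals[k] @ tangents[k]) * tangents[k])
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def _point_at_arc(points: np.ndarray, cum: np.ndarray, frames, t: float):
    """Position and frame on the polyline at arc length ``t`` (linear
    extrapolation beyond the ends)."""
    tangents, normals, binormals = frames
    if t <= cum[0]:
        p = points[0] + (t - cum[0]) * tangents[0]
        k = 0
    elif t >= cum[-1]:
        p = points[-1] + (t - cum[-1]) * tangents[-1]
        k = len(points) - 1
    else:
        k = int(np.searchsorted(cum, t, side="right") - 1)
        frac = (t - cum[k]) / (cum[k + 1] - cum[k])
        p = points[k] + frac * (points[k + 1] - points[k])
        if frac > 0.5:
            k = k + 1
    return p, (tangents[k], normals[k], binormals[k])


def rescale_along_skeleton(ca_trace: np.ndarray, skeleton: CoiledCoilSkeleton,
                           factor: float, anchor_residue: int) -> np.ndarray:
    """Rescale a chain's arc length along its skeleton by ``factor``.

    The arc-length distance of every residue's skeleton foot from the
    anchor residue's foot is multiplied by ``factor``; each Calpha is
    re-placed preserving its offset vector in the local
    tangent/normal/binormal frame.  ``anchor_residue`` is a 0-based
    index into ``ca_trace`` and must have a skeleton point.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    ca = np.asarray(ca_trace, dtype=float)
    n = len(ca)
    off = skeleton.residue_offset
    m = len(skeleton.points)
    if not 0 <= anchor_residue < n:
        raise ValueError("anchor residue outside the chain")
    if not off <= anchor_residue < off + m:
        raise ValueError("anchor residue has no skeleton point")

    pts = skeleton.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    frames = _transport_frames(pts)
    mean_step = float(seg.mean())

    # arc-length coordinate of each residue's skeleton foot
    t_res = np.empty(n)
    for j in range(n):
        k = j - off
        if k < 0:
            t_res[j] = cum[0] + k * mean_step
        elif k >= m:
            t_res[j] = cum[-1] + (k - (m - 1)) * mean_step
        else:
            t_res[j] = cum[k]
    t_anchor = t_res[anchor_residue]

    out = np.empty_like(ca)
    for j in range(n):
        foot, (T, N, B) = _point_at_arc(pts, cum, frames, t_res[j])
        offset = ca[j] - foot
        local = np.array([offset @ T, offset @ N, offset @ B])
        t_new = t_anchor + factor * (t_res[j] - t_anchor)
        foot2, (T2, N2, B2) = _point_at_arc(pts, cum, frames, t_new)
        out[j] = foot2 + local[0] * T2 + local[1] * N2 + local[2] * B2
    return out


# ----------------------------------------------------- model-building ops

def find_extension_factor(ca_trace: np.ndarray, resids: np.ndarray,
                          target_trace: np.ndarray, target_resids: np.ndarray,
                          anchor_residue: int,
                          factor_range: tuple[float, float] = (0.9, 1.2),
                          step: float = 0.001,
                          match_distance: float = 0.05,
                          ) -> tuple[float, int, float]:
    """Scan extension factors until a Calpha of the rescaled chain
    coincides with the target chain.

    Returns (factor, matching residue number, distance in nm) for the
    scanned factor whose best-matching shared residue (the anchor
    itself excluded — it coincides trivially at every factor) comes
    closest, subject to the coincidence criterion ``match_distance``
    (default 0.05 nm = 0.5 A).  Ties break toward the smallest factor.
    """
    resids = np.asarray(resids)
    target_resids = np.asarray(target_resids)
    shared, ia, ib = np.intersect1d(resids, target_resids, return_indices=True)
    anchor_resid = resids[anchor_residue]
    keep = shared != anchor_resid
    shared, ia, ib = shared[keep], ia[keep], ib[keep]
    if len(shared) == 0:
        raise ValueError("no shared residue numbering between chains")
    skeleton = local_helix_skeleton(ca_trace)
    factors = np.arange(factor_range[0], factor_range[1] + 0.5 * step, step)
    best: tuple[float, int, float] | None = None
    for factor in factors:
        rescaled = rescale_along_skeleton(ca_trace, skeleton, float(factor),
                                          anchor_residue)
        dist = np.linalg.norm(rescaled[ia] - np.asarray(target_trace)[ib], axis=1)
        j = int(np.argmin(dist))
        if dist[j] <= match_distance and (best is None or dist[j] < best[2]):
            best = (float(factor), int(shared[j]), float(dist[j]))
    if best is None:
        raise ValueError(f"no factor in [{factor_range[0]}, {factor_range[1]}] "
                         f"brings any shared Calpha within {match_distance} nm")
    return best


def best_match_interval(ca_a: np.ndarray, resids_a: np.ndarray,
                        ca_b: np.ndarray, resids_b: np.ndarray,
                        candidates: list[tuple[int, int]],
                        ) -> tuple[int, int, float]:
    """Exhaustive (i, j) interval search minimizing the end-triple RMSD.

    For each candidate interval the RMSD over the six Calpha pairs
    {i-1, i, i+1, j-1, j, j+1} is computed in the common frame (no
    superposition).  Ties break toward the smallest i, then smallest j.
    """
    if not candidates:
        raise ValueError("empty candidate interval set")
    map_a = {int(r): k for k, r in enumerate(np.asarray(resids_a))}
    map_b = {int(r): k for k, r in enumerate(np.asarray(resids_b))}
    best: tuple[int, int, float] | None = None
    for i, j in sorted(candidates):
        res = [i - 1, i, i + 1, j - 1, j, j + 1]
        if not all(r in map_a and r in map_b for r in res):
            raise ValueError(f"interval ({i}, {j}): end-triple residues "
                             "missing from one of the chains")
        pa = np.asarray(ca_a)[[map_a[r] for r in res]]
        pb = np.asarray(ca_b)[[map_b[r] for r in res]]
        rmsd = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
        if best is None or rmsd < best[2]:
            best = (i, j, rmsd)
    return best
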