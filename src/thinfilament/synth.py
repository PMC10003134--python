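"""Synthetic fluctuating-filament generator.

Builds a two-start helical pseudo-filament (26 monomers by default,
rise d0, left-handed rotation phi0 per monomer) whose thermal
fluctuations have prescribed longitudinal (K), torsional (G) and
bending (persistence length xi) stiffness, so every analysis stage can
be validated by parameter recovery without any external trajectory.

Each pseudo-monomer is a small rigid group of atoms on its own chain:
a body atom on the COM ring, a Lys328 Calpha surrogate marker, Lys326/
Lys328 side-chain-nitrogen donor surrogates with attached hydrogens,
and one balance atom placed so that the mass-weighted monomer COM falls
exactly on the ideal helix.  Frames are drawn independently: a uniform
axial strain, a uniform twist increment, a parabolic bend, optional
per-atom jitter, and a random proper rigid-body motion, all from a
single seeded generator.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .models import (ATOMIC_MASSES, BOLTZMANN, ComponentMap, FilamentTrajectory,
                     StructureModel)

_CHAIN_ALPHABET = string.ascii_uppercase + string.digits

# atom-name conventions of the pseudo-monomer
BODY_RESID, BALANCE_RESID = 100, 999
DONOR_OFFSET_NM = 0.15      # donor N radial offset beyond the COM ring
HYDROGEN_OFFSET_NM = 0.10   # H placed radially outward from its donor
DONOR_Z_OFFSET_NM = 0.20    # +/- axial offset of the two donor residues


@dataclass
class SyntheticParams:
    """Ground-truth parameters of the generator.

    Defaults emulate the study conditions: a 26-monomer filament with
    d0 = 2.75 nm / phi0 = 166.6 deg, 200 ps frame spacing, stiffness in
    the range reported for reconstructed cardiac thin filaments
    (K ~ 48 nN, G ~ 4e-26 N·m², xi ~ 7 um) at 300 K.
    """

    n_monomers: int = 26
    d0: float = 2.75                 # nm, axial rise per monomer
    phi0: float = 166.6              # degrees, left-handed rotation per monomer
    monomer_radius: float = 2.5      # nm, COM ring radius
    marker_radius: float = 2.7       # nm, Lys328 Calpha surrogate radius
    K_true: float = 48e-9            # N
    G_true: float = 4e-26            # N·m²
    xi_true: float = 7e-6            # m
    temperature: float = 300.0       # K
    n_frames: int = 2000
    frame_interval: float = 200.0    # ps
    jitter_sd: float = 0.02          # nm, per-atom Gaussian jitter
    rigid_translation: float = 5.0   # nm, amplitude of random per-frame shifts
    first_frame_ideal: bool = True   # seed frame 0 with the noise-free model
    end_exclusion: int = 2           # matches the analysis convention for l
    segment_offset: int = 5          # matches the central-segment convention
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 12:
            raise ValueError("need at least 12 monomers")
        if self.n_monomers > len(_CHAIN_ALPHABET):
            raise ValueError("too many monomers for single-character chain ids")
        if min(self.K_true, self.G_true, self.xi_true) <= 0:
            raise ValueError("stiffness parameters must be positive")

    # -- derived geometry shared by generator and calibration ------------

    @property
    def segment_span(self) -> int:
        """Monomer steps between central-segment endpoint midpoints."""
        return self.n_monomers - 2 * self.segment_offset - 1 + 1

    @property
    def segment_length_nm(self) -> float:
        return self.segment_span * self.d0

    @property
    def half_length_nm(self) -> float:
        """Half axial extent of the monomers kept after end exclusion."""
        return 0.5 * (self.n_monomers - 1 - 2 * self.end_exclusion) * self.d0

    def noise_scales(self) -> tuple[float, float, float]:
        """(sigma_strain, sigma_psi in rad, sigma_k in 1/nm).

        Calibrated so the analysis-side estimators see
        Var(L) = kB T <L> / K, Var(Psi) = kB T <L> / G and, via the
        small-angle expansion of the end-tangent cosine,
        <1 - cos a> ~ l / xi.
        """
        kT = BOLTZMANN * self.temperature
        L0_m = self.segment_length_nm * 1e-9
        sigma_strain = np.sqrt(kT / (self.K_true * L0_m)) if np.isfinite(self.K_true) else 0.0
        sigma_psi = np.sqrt(kT * L0_m / self.G_true) if np.isfinite(self.G_true) else 0.0
        xi_nm = self.xi_true * 1e9
        sigma_k = (1.0 / np.sqrt(self.half_length_nm * xi_nm)
                   if np.isfinite(self.xi_true) else 0.0)
        return float(sigma_strain), float(sigma_psi), float(sigma_k)


def monomer_chain_id(i: int) -> str:
    """Chain id of 1-based monomer ``i`` (A..Z, then digits)."""
    return _CHAIN_ALPHABET[i - 1]


def generate_ideal_filament(params: SyntheticParams) -> tuple[StructureModel, ComponentMap]:
    """Noise-free two-start helical pseudo-filament and its component map.

    Monomer i sits at z = (i - (n+1)/2) d0, azimuth -i phi0 (left-handed),
    radius ``monomer_radius``; odd monomers belong to long helix 1, even
    to helix 2.  The mass-weighted COM of every monomer lies exactly on
    that ideal ring position by construction (balance atom).
    """
    n = params.n_monomers
    chain_ids, resids, resnames, names, elements, positions = [], [], [], [], [], []
    mC, mN, mH = ATOMIC_MASSES["C"], ATOMIC_MASSES["N"], ATOMIC_MASSES["H"]

    for i in range(1, n + 1):
        chain = monomer_chain_id(i)
        z = (i - (n + 1) / 2.0) * params.d0
        az = np.radians(-i * params.phi0)
        u = np.array([np.cos(az), np.sin(az), 0.0])
        ez = np.array([0.0, 0.0, 1.0])
        com = params.monomer_radius * u + z * ez

        atoms = [
            ("BDY", BODY_RESID, "C1", "C", mC, com),
            ("LYS", 326, "NZ", "N", mN,
             (params.monomer_radius + DONOR_OFFSET_NM) * u + (z - DONOR_Z_OFFSET_NM) * ez),
            ("LYS", 326, "HZ", "H", mH,
             (params.monomer_radius + DONOR_OFFSET_NM + HYDROGEN_OFFSET_NM) * u
             + (z - DONOR_Z_OFFSET_NM) * ez),
            ("LYS", 328, "CA", "C", mC, params.marker_radius * u + z * ez),
            ("LYS", 328, "NZ", "N", mN,
             (params.monomer_radius + DONOR_OFFSET_NM) * u + (z + DONOR_Z_OFFSET_NM) * ez),
            ("LYS", 328, "HZ", "H", mH,
             (params.monomer_radius + DONOR_OFFSET_NM + HYDROGEN_OFFSET_NM) * u
             + (z + DONOR_Z_OFFSET_NM) * ez),
        ]
        total_mass = sum(a[4] for a in atoms) + mC
        weighted = sum(a[4] * a[5] for a in atoms)
        balance = (total_mass * com - weighted) / mC
        atoms.append(("BAL", BALANCE_RESID, "XB", "C", mC, balance))

        for resname, resid, name, element, _mass, pos in atoms:
            chain_ids.append(chain)
            resids.append(resid)
            resnames.append(resname)
            names.append(name)
            elements.append(element)
            positions.append(pos)

    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    structure = StructureModel(
        chain_ids=np.array(chain_ids), resids=np.array(resids),
        resnames=np.array(resnames), names=np.array(names),
        elements=np.array(elements), masses=masses,
        positions=np.array(positions))
    cmap = ComponentMap(
        monomers={i: [(monomer_chain_id(i), (1, 999))] for i in range(1, n + 1)},
        long_helix={i: 1 if i % 2 == 1 else 2 for i in range(1, n + 1)})
    return structure, cmap


def generate_fluctuating_trajectory(params: SyntheticParams,
                                    ) -> tuple[FilamentTrajectory, ComponentMap]:
    """Trajectory of independent thermally fluctuating frames.

    Deterministic for a fixed ``params.seed``.  With
    ``first_frame_ideal`` the first frame is the unperturbed model, so a
    loaded trajectory can be checked against the written structure.
    """
    structure, cmap = generate_ideal_filament(params)
    rng = np.random.default_rng(params.seed)
    n = params.n_monomers
    base = structure.positions
    sigma_strain, sigma_psi, sigma_k = params.noise_scales()

    # per-atom monomer index (1-based) for the twist perturbation
    chain_of = {monomer_chain_id(i): i for i in range(1, n + 1)}
    mono_idx = np.array([chain_of[c] for c in structure.chain_ids], dtype=float)
    center = (n + 1) / 2.0

    # hydrogens ride their donor nitrogen rigidly under jitter
    h_idx = np.flatnonzero(structure.elements == "H")
    donor_of_h = np.array([
        structure.atom_indices(structure.chain_ids[h],
                               resid=int(structure.resids[h]), element="N")[0]
        for h in h_idx], dtype=int)

    frames = np.empty((params.n_frames, structure.n_atoms, 3))
    for f in range(params.n_frames):
        if f == 0 and params.first_frame_ideal:
            frames[0] = base
            continue
        X = base.copy()
        # uniform axial strain
        eps = rng.normal(0.0, sigma_strain) if sigma_strain else 0.0
        X[:, 2] *= 1.0 + eps
        # uniform twist increment: endpoint Psi perturbed by dpsi
        dpsi = rng.normal(0.0, sigma_psi) if sigma_psi else 0.0
        theta = (mono_idx - center) * (dpsi / params.segment_span)
        c, s = np.cos(theta), np.sin(theta)
        X[:, 0], X[:, 1] = c * X[:, 0] - s * X[:, 1], s * X[:, 0] + c * X[:, 1]
        # parabolic bend
        kx = rng.normal(0.0, sigma_k) if sigma_k else 0.0
        ky = rng.normal(0.0, sigma_k) if sigma_k else 0.0
        z2 = 0.5 * X[:, 2] ** 2
        X[:, 0] += kx * z2
        X[:, 1] += ky * z2
        # per-atom jitter (donor-H pairs move rigidly)
        if params.jitter_sd:
            noise = rng.normal(0.0, params.jitter_sd, size=X.shape)
            noise[h_idx] = noise[donor_of_h]
            X += noise
        # random proper rigid-body motion
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-params.rigid_translation, params.rigid_translation, size=3)
        frames[f] = X @ R.T + t

    times = np.arange(params.n_frames) * params.frame_interval
    return FilamentTrajectory(structure=structure, frames=frames, times=times), cmap


# --------------------------------------------------------- coiled coils

def generate_coiledcoil(n_res: int, rise: float = 0.15, helix_radius: float = 0.23,
                        twist_deg: float = 100.0, curvature_radius: float | None = None,
                        chain_separation: float = 0.5, seed: int | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Ideal alpha-helical Calpha traces of a two-chain coiled-coil fixture.

    Each chain winds at ``twist_deg`` per residue around its own axis;
    the two axes run parallel, ``chain_separation`` nm apart.  With
    ``curvature_radius`` the axes are bent onto a circular arc of that
    radius in the x-z plane.  Returns two (n_res, 3) arrays in nm.
    """
    if n_res < 10:
        raise ValueError("need at least 10 residues")
    k = np.arange(n_res)
    theta = np.radians(twist_deg) * k
    local = np.column_stack([helix_radius * np.cos(theta),
                             helix_radius * np.sin(theta),
                             rise * k])

    def place(axis_offset: np.ndarray, phase: float) -> np.ndarray:
        th = theta + phase
        pts_local = np.column_stack([helix_radius * np.cos(th),
                                     helix_radius * np.sin(th)])
        s = rise * k  # arc length along the chain axis
        if curvature_radius is None:
            out = np.column_stack([pts_local[:, 0] + axis_offset[0],
                                   pts_local[:, 1] + axis_offset[1],
                                   s])
        else:
            R = curvature_radius
            ang = s / R
            centre = np.column_stack([R * (1 - np.cos(ang)) + axis_offset[0],
                                      np.full(n_res, axis_offset[1]),
                                      R * np.sin(ang)])
            # local frame: tangent in x-z plane, normal toward arc centre
            tangent = np.column_stack([np.sin(ang), np.zeros(n_res), np.cos(ang)])
            normal = np.column_stack([np.cos(ang), np.zeros(n_res), -np.sin(ang)])
            binormal = np.cross(tangent, normal)
            out = (centre + pts_local[:, :1] * normal + pts_local[:, 1:2] * binormal)
        return out

    chain_a = place(np.array([0.0, 0.0]), 0.0)
    chain_b = place(np.array([chain_separation, 0.0]), np.pi)
    return chain_a, chain_b


# ------------------------------------------------------------ Tpm strand

def generate_tpm_strand(traj: FilamentTrajectory, cmap: ComponentMap,
                        strand: int, radius_offset: float = 1.0,
                        angular_noise_deg: float = 0.0,
                        radial_noise_nm: float = 0.0,
                        contact_pattern: np.ndarray | None = None,
                        contact_schedule: np.ndarray | None = None,
                        seed: int = 0,
                        ) -> tuple[FilamentTrajectory, ComponentMap]:
    """Append a pseudo-Calpha Tpm strand that tracks one long actin helix.

    One GLU pseudo-residue per helix monomer is placed, frame by frame,
    exactly on that frame's long-helix regression line at radius
    (monomer radius + ``radius_offset``), then perturbed by Gaussian
    angular/radial noise.  For monomers flagged in ``contact_pattern``
    (and frames flagged in ``contact_schedule``), the residue's acceptor
    oxygen is placed 0.30 nm from the monomer's Lys328 donor nitrogen
    along its N-H direction, i.e. inside hydrogen-bond range; otherwise
    the acceptor sits on the strand backbone, out of range.
    """
    from .normalization import normalize_frame
    from .tpm import long_helix_regression

    helix_monomers = cmap.helix_monomers(strand)
    n_res = len(helix_monomers)
    if contact_pattern is None:
        contact_pattern = np.zeros(n_res, dtype=bool)
    contact_pattern = np.asarray(contact_pattern, dtype=bool)
    if len(contact_pattern) != n_res:
        raise ValueError(f"contact_pattern must have one flag per helix monomer "
                         f"({n_res}), got {len(contact_pattern)}")
    if contact_schedule is None:
        contact_schedule = np.ones(traj.n_frames, dtype=bool)
    contact_schedule = np.asarray(contact_schedule, dtype=bool)
    if len(contact_schedule) != traj.n_frames:
        raise ValueError("contact_schedule must have one flag per frame")

    rng = np.random.default_rng(seed)
    structure = traj.structure
    chain = "a" if strand == 1 else "b"
    if np.any(structure.chain_ids == chain):
        raise ValueError(f"chain {chain!r} already present")

    # new static atoms: per residue a backbone CA (C) and acceptor OE1 (O)
    new_chain, new_resids, new_resnames, new_names, new_elements = [], [], [], [], []
    for k in range(1, n_res + 1):
        for name, element in (("CA", "C"), ("OE1", "O")):
            new_chain.append(chain)
            new_resids.append(k)
            new_resnames.append("GLU")
            new_names.append(name)
            new_elements.append(element)
    n_new = len(new_chain)

    monomer_radius = float(np.mean(
        np.hypot(*_ideal_com_xy(traj.frames[0], structure, cmap))))
    cache = cmap.monomer_atom_indices(structure)
    donor_idx = [structure.atom_indices(monomer_chain_id(m), resid=328, name="NZ")[0]
                 for m in helix_monomers]
    hydrogen_idx = [structure.atom_indices(monomer_chain_id(m), resid=328, name="HZ")[0]
                    for m in helix_monomers]

    new_frames = np.empty((traj.n_frames, n_new, 3))
    for f in range(traj.n_frames):
        X = traj.frames[f]
        nf = normalize_frame(X, structure, cmap, cache)
        reg = long_helix_regression(nf, strand)
        for k, m in enumerate(helix_monomers):
            z = nf.z[m - 1]
            phi = reg.slope * z + reg.intercept
            if angular_noise_deg:
                phi += rng.normal(0.0, angular_noise_deg)
            r = monomer_radius + radius_offset
            if radial_noise_nm:
                r += rng.normal(0.0, radial_noise_nm)
            ca_norm = np.array([r * np.cos(np.radians(phi)),
                                r * np.sin(np.radians(phi)), z])
            ca = nf.to_original(ca_norm)
            if contact_pattern[k] and contact_schedule[f]:
                d_pos = X[donor_idx[k]]
                h_pos = X[hydrogen_idx[k]]
                u = h_pos - d_pos
                acc = d_pos + 0.30 * u / np.linalg.norm(u)
            else:
                acc = ca
            new_frames[f, 2 * k] = ca
            new_frames[f, 2 * k + 1] = acc

    new_masses = np.array([ATOMIC_MASSES[e] for e in new_elements])
    structure2 = StructureModel(
        chain_ids=np.concatenate([structure.chain_ids, new_chain]),
        resids=np.concatenate([structure.resids, new_resids]),
        resnames=np.concatenate([structure.resnames, new_resnames]),
        names=np.concatenate([structure.names, new_names]),
        elements=np.concatenate([structure.elements, new_elements]),
        masses=np.concatenate([structure.masses, new_masses]),
        positions=np.vstack([structure.positions, new_frames[0]]))
    frames2 = np.concatenate([traj.frames, new_frames], axis=1)
    cmap2 = ComponentMap(
        monomers=cmap.monomers, long_helix=cmap.long_helix,
        tpm_chains={**cmap.tpm_chains, chain: (strand, 1)},
        tn_chains=cmap.tn_chains, marker_residue=cmap.marker_residue,
        donor_residues=cmap.donor_residues,
        acceptor_residues=cmap.acceptor_residues)
    traj2 = FilamentTrajectory(structure=structure2, frames=frames2,
                               times=traj.times.copy())
    return traj2, cmap2


def _ideal_com_xy(coords: np.ndarray, structure: StructureModel,
                  cmap: ComponentMap) -> tuple[np.ndarray, np.ndarray]:
    from .normalization import normalize_frame
    nf = normalize_frame(coords, structure, cmap)
    return nf.com_xyz[:, 0], nf.com_xyz[:, 1]
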