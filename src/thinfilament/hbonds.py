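"""Geometric hydrogen-bond detection and actin-Tpm occupancy profiles.

A donor-acceptor pair is hydrogen bonded when the D...A distance is at
most 0.35 nm and, if hydrogens are present, the smallest H-D...A angle
over the donor's hydrogens is at most 30 degrees (the GROMACS ``hbond``
convention).  Structures without hydrogens fall back to the
distance-only criterion with a logged warning.

For each actin monomer the per-frame occupancy is 1 when at least one
bond exists between its Lys326/Lys328 donor nitrogens and the acidic
side-chain oxygens of the paired Tpm strand; the time average is the
lifetime fraction, also reported per trajectory quarter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .models import ComponentMap, FilamentTrajectory, HBondCriteria, StructureModel

log = logging.getLogger(__name__)

#: side-chain carboxyl oxygens of Asp/Glu
ACID_ACCEPTOR_NAMES = {"OD1", "OD2", "OE1", "OE2"}
ACID_RESNAMES = {"ASP", "GLU"}

# hydrogens within this distance of a donor heavy atom count as attached
_COVALENT_H_CUTOFF = 0.12  # nm


def attached_hydrogens(structure: StructureModel, coords: np.ndarray,
                       donor_index: int) -> np.ndarray:
    """Indices of hydrogens covalently attached to a donor heavy atom.

    Attachment is inferred geometrically (same residue, within 0.12 nm)
    because plain coordinate files carry no bond topology.
    """
    sel = ((structure.elements == "H")
           & (structure.chain_ids == structure.chain_ids[donor_index])
           & (structure.resids == structure.resids[donor_index]))
    cand = np.flatnonzero(sel)
    if len(cand) == 0:
        return cand
    dist = np.linalg.norm(coords[cand] - coords[donor_index], axis=1)
    return cand[dist <= _COVALENT_H_CUTOFF]


def detect_hbonds(coords: np.ndarray, structure: StructureModel,
                  donors: np.ndarray, acceptors: np.ndarray,
                  criteria: HBondCriteria) -> list[tuple[int, int | None, int]]:
    """Hydrogen bonds between donor and acceptor atom selections.

    Returns (donor, hydrogen, acceptor) index triples; hydrogen is None
    under the distance-only fallback.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("empty donor or acceptor selection")
    dist = cdist(coords[donors], coords[acceptors])
    bonds: list[tuple[int, int | None, int]] = []
    for i, didx in enumerate(donors):
        within = np.flatnonzero(dist[i] <= criteria.max_distance)
        if len(within) == 0:
            continue
        hyds = attached_hydrogens(structure, coords, didx)
        if len(hyds) == 0:
            if criteria.hydrogen_required:
                raise ValueError(
                    f"donor atom {didx} ({structure.chain_ids[didx]}/"
                    f"{structure.resids[didx]}/{structure.names[didx]}) has no "
                    "attached hydrogen; set hydrogen_required=False for "
                    "distance-only detection")
            for j in within:
                bonds.append((int(didx), None, int(acceptors[j])))
            continue
        d_pos = coords[didx]
        for j in within:
            a_vec = coords[acceptors[j]] - d_pos
            a_norm = np.linalg.norm(a_vec)
            best = 180.0
            for h in hyds:
                h_vec = coords[h] - d_pos
                cosang = h_vec @ a_vec / (np.linalg.norm(h_vec) * a_norm)
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                best = min(best, ang)
            if best <= criteria.max_angle:
                bonds.append((int(didx), int(hyds[0]), int(acceptors[j])))
    return bonds


@dataclass
class OccupancySeries:
    """Binary contact series of one (monomer, strand) pair."""

    monomer: int
    strand: int
    occupancy: np.ndarray          # (n_frames,) 0/1
    mean_z_nm: float

    @property
    def lifetime(self) -> float:
        return float(self.occupancy.mean())

    @property
    def quarters(self) -> tuple[float, ...]:
        return tuple(float(q.mean()) for q in np.array_split(self.occupancy, 4))


def _donor_selection(structure: StructureModel, cmap: ComponentMap,
                     monomer: int) -> np.ndarray:
    idx = []
    for chain, rng in cmap.monomers[monomer]:
        for resid in cmap.donor_residues:
            sel = structure.atom_indices(chain, rng, resid=resid, element="N")
            # side-chain nitrogen only (NZ for lysine); fall back to any N
            named = sel[np.isin(structure.names[sel], ["NZ"])]
            idx.extend((named if len(named) else sel).tolist())
    return np.array(sorted(set(idx)), dtype=int)


def _acceptor_selection(structure: StructureModel, cmap: ComponentMap,
                        strand: int) -> np.ndarray:
    idx = []
    for chain in cmap.strand_chains(strand):
        sel = np.flatnonzero(structure.chain_ids == chain)
        if cmap.acceptor_residues is not None:
            sel = sel[np.isin(structure.resids[sel], cmap.acceptor_residues)]
        else:
            sel = sel[np.isin(structure.resnames[sel], list(ACID_RESNAMES))]
        sel = sel[np.isin(structure.names[sel], list(ACID_ACCEPTOR_NAMES))]
        idx.extend(sel.tolist())
    return np.array(sorted(set(idx)), dtype=int)


def occupancy_lifetime(traj: FilamentTrajectory, cmap: ComponentMap,
                       criteria: HBondCriteria | None = None,
                       ) -> list[OccupancySeries]:
    """Per-(monomer, strand) hydrogen-bond occupancy over a trajectory.

    Each monomer is paired with the Tpm strand wrapping its own long
    helix.  Monomers whose strand has no mapped chains are skipped.
    """
    if criteria is None:
        criteria = HBondCriteria()
    structure = traj.structure
    has_h = bool(np.any(structure.elements == "H"))
    if not has_h and criteria.hydrogen_required:
        log.warning("structure has no hydrogens; falling back to the "
                    "distance-only hydrogen-bond criterion")
        criteria = HBondCriteria(max_distance=criteria.max_distance,
                                 max_angle=criteria.max_angle,
                                 hydrogen_required=False)

    cache = cmap.monomer_atom_indices(structure)
    # mean axial position from normalized COM geometry of the first frame
    from .normalization import normalize_frame
    nf0 = normalize_frame(traj.frames[0], structure, cmap, cache)

    out: list[OccupancySeries] = []
    for monomer in sorted(cmap.monomers):
        strand = cmap.long_helix[monomer]
        acceptors = _acceptor_selection(structure, cmap, strand)
        if len(acceptors) == 0:
            continue
        donors = _donor_selection(structure, cmap, monomer)
        if len(donors) == 0:
            raise ValueError(f"monomer {monomer}: no donor nitrogens for "
                             f"residues {cmap.donor_residues}")
        occ = np.zeros(traj.n_frames, dtype=int)
        for f in range(traj.n_frames):
            bonds = detect_hbonds(traj.frames[f], structure, donors, acceptors,
                                  criteria)
            occ[f] = 1 if bonds else 0
        out.append(OccupancySeries(monomer=monomer, strand=strand, occupancy=occ,
                                   mean_z_nm=float(nf0.z[monomer - 1])))
    return out


def occupancy_table(series: list[OccupancySeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        q = s.quarters
        rows.append({"monomer": s.monomer, "strand": s.strand,
                     "mean_z_nm": s.mean_z_nm, "lifetime": s.lifetime,
                     "q1": q[0], "q2": q[1], "q3": q[2], "q4": q[3]})
    return pd.DataFrame(rows)
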