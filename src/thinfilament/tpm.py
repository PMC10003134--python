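"""Long-helix regression and tropomyosin fluctuation profiles.

The two long actin pseudo-helices are tracked through the Lys328
Calpha markers of their monomers.  In every frame each helix is
approximated by an ordinary-least-squares line of the marker azimuth
on its axial position (azimuths unwrapped monotone over z).  Angular
fluctuations of the helices themselves and of the Tpm strands are then
measured as deviations from that per-frame regression line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ComponentMap, FilamentTrajectory
from .normalization import NormalizedFrame, normalize_frame, unwrap_degrees


@dataclass
class RegressionLine:
    """OLS fit of marker azimuth (deg) on axial position (nm)."""

    slope: float           # deg/nm
    intercept: float       # deg
    residuals: np.ndarray  # deg, one per marker, ordered by z
    helix_id: int
    z: np.ndarray          # nm, marker axial positions
    phi: np.ndarray        # deg, unwrapped marker azimuths

    def predict(self, z) -> np.ndarray:
        return self.slope * np.asarray(z) + self.intercept


def _marker_positions(nframe: NormalizedFrame, helix_id: int) -> np.ndarray:
    cmap, structure = nframe.cmap, nframe.structure
    idx = []
    for m in cmap.helix_monomers(helix_id):
        found = None
        for chain, rng in cmap.monomers[m]:
            cand = structure.atom_indices(chain, rng, resid=cmap.marker_residue,
                                          name="CA")
            if len(cand):
                found = cand[0]
                break
        if found is None:
            raise ValueError(f"monomer {m}: marker residue "
                             f"{cmap.marker_residue} CA not found")
        idx.append(found)
    return nframe.coords[np.array(idx)]


def long_helix_regression(nframe: NormalizedFrame, helix_id: int) -> RegressionLine:
    """Per-frame regression line phi(z) of one long actin helix.

    Markers are ordered by z and their azimuths unwrapped to the nearest
    branch along the helix before fitting, so the line is insensitive to
    where the +/-180 degree seam falls.
    """
    pos = _marker_positions(nframe, helix_id)
    if len(pos) < 3:
        raise ValueError("need at least 3 markers for the helix regression")
    order = np.argsort(pos[:, 2])
    pos = pos[order]
    z = pos[:, 2]
    phi = unwrap_degrees(np.degrees(np.arctan2(pos[:, 1], pos[:, 0])))
    slope, intercept = np.polyfit(z, phi, 1)
    residuals = phi - (slope * z + intercept)
    return RegressionLine(slope=float(slope), intercept=float(intercept),
                          residuals=residuals, helix_id=helix_id, z=z, phi=phi)


def actin_helix_angular_fluctuation(traj: FilamentTrajectory, cmap: ComponentMap,
                                    helix_id: int) -> pd.DataFrame:
    """Per-monomer RMS angular fluctuation of one long helix.

    For each frame the markers' residuals from that frame's own
    regression line are recorded; the root-mean-square over time is
    reported per monomer together with its mean axial position.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    cache = cmap.monomer_atom_indices(traj.structure)
    monomers = cmap.helix_monomers(helix_id)
    res = np.empty((traj.n_frames, len(monomers)))
    zbar = np.zeros(len(monomers))
    for f in range(traj.n_frames):
        nf = normalize_frame(traj.frames[f], traj.structure, cmap, cache)
        reg = long_helix_regression(nf, helix_id)
        res[f] = reg.residuals
        zbar += reg.z
    zbar /= traj.n_frames
    return pd.DataFrame({
        "monomer": monomers,
        "mean_z_nm": zbar,
        "rms_angle_deg": np.sqrt(np.mean(res**2, axis=0)),
        "sd_angle_deg": np.std(res, axis=0, ddof=0),
        "mean_angle_deg": np.mean(res, axis=0),
    })


def tpm_deviation_profiles(traj: FilamentTrajectory, cmap: ComponentMap,
                           strand: int) -> pd.DataFrame:
    """Angular and radial fluctuation profile of one Tpm strand.

    Per Tpm Calpha residue: the azimuthal deviation from the paired
    long helix's per-frame regression line (mean and SD over time) and
    the radial distance from the filament axis (mean and SD), indexed
    both by residue and by mean axial position.
    """
    chains = cmap.strand_chains(strand)
    if not chains:
        raise ValueError(f"no Tpm chains mapped for strand {strand}")
    structure = traj.structure
    ca_idx, res_keys = [], []
    for chain in chains:
        sel = np.flatnonzero((structure.chain_ids == chain) & (structure.names == "CA"))
        sel = sel[np.argsort(structure.resids[sel], kind="stable")]
        ca_idx.extend(sel.tolist())
        res_keys.extend((chain, int(structure.resids[s])) for s in sel)
    if not ca_idx:
        raise ValueError(f"strand {strand}: no Calpha atoms found")
    ca_idx = np.array(ca_idx)

    cache = cmap.monomer_atom_indices(structure)
    n_res = len(ca_idx)
    dphi = np.empty((traj.n_frames, n_res))
    rad = np.empty((traj.n_frames, n_res))
    zpos = np.empty((traj.n_frames, n_res))
    for f in range(traj.n_frames):
        nf = normalize_frame(traj.frames[f], structure, cmap, cache)
        reg = long_helix_regression(nf, strand)
        pos = nf.coords[ca_idx]
        r, phi_raw, z = nf.cylindrical_of(pos)
        phi = unwrap_degrees(phi_raw)
        d = phi - reg.predict(z)
        # the chain-wise unwrap leaves a global 360k ambiguity; snap it
        d -= 360.0 * np.round(np.mean(d) / 360.0)
        dphi[f] = d
        rad[f] = r
        zpos[f] = z
    return pd.DataFrame({
        "chain": [k[0] for k in res_keys],
        "residue": [k[1] for k in res_keys],
        "mean_z_nm": zpos.mean(axis=0),
        "mean_dphi_deg": dphi.mean(axis=0),
        "sd_angle_deg": dphi.std(axis=0, ddof=0),
        "rms_angle_deg": np.sqrt(np.mean(dphi**2, axis=0)),
        "mean_radius_nm": rad.mean(axis=0),
        "sd_radius_nm": rad.std(axis=0, ddof=0),
    })
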