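"""F-actin genetic-helix parameters d, phi and the apparent period P.

d is the mean axial distance between adjacent monomer COMs, phi the
mean magnitude of the azimuthal step between them (the genetic helix is
left-handed, so the signed step is negative), both computed per frame
after rigid-body removal and with a configurable number of end monomers
excluded.  The apparent helical period is P = d·pi/(pi - phi), i.e. the
crossover repeat of the two-start filament (~36-38.5 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import AnalysisConfig, ComponentMap, FilamentTrajectory
from .normalization import NormalizedFrame, normalize_frame


def helix_parameters(nframe: NormalizedFrame, exclude: int = 2) -> tuple[float, float]:
    """(d in nm, phi in degrees) over the included adjacent monomer pairs."""
    z = nframe.z
    phi = nframe.phi_deg
    n = len(z)
    if n - 2 * exclude < 2:
        raise ValueError("too few monomers after end exclusion")
    sl = slice(exclude, n - exclude) if exclude else slice(None)
    dz = np.diff(z[sl])
    dphi = np.diff(phi[sl])
    d = float(np.mean(dz))
    phi_step = float(abs(np.mean(dphi)))
    if d <= 0:
        raise ValueError("non-positive axial rise; check monomer ordering")
    return d, phi_step


def pairwise_helix_parameters(nframe: NormalizedFrame, exclude: int = 2,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-adjacent-pair (dz, |dphi|) arrays over the included monomers."""
    n = len(nframe.z)
    sl = slice(exclude, n - exclude) if exclude else slice(None)
    return np.diff(nframe.z[sl]), np.abs(np.diff(nframe.phi_deg[sl]))


def apparent_period(d: float, phi_deg: float) -> float:
    """Apparent F-actin helical period P = d·pi/(pi - phi) in nm.

    ``phi_deg`` is the helical angle between adjacent monomers in
    degrees (converted to radians inside the formula).
    """
    if not 0.0 < phi_deg < 180.0:
        raise ValueError("phi must lie in (0, 180) degrees")
    return d * 180.0 / (180.0 - phi_deg)


@dataclass
class HelixParams:
    """Per-frame helix parameters with trajectory summaries."""

    d_nm: np.ndarray
    phi_deg: np.ndarray
    period_nm: np.ndarray
    times_ps: np.ndarray
    exclude: int
    summary: dict = field(default_factory=dict)

    def frame_table(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times_ps, "d_nm": self.d_nm,
                             "phi_deg": self.phi_deg, "period_nm": self.period_nm})


def summarize_helix(traj: FilamentTrajectory, cmap: ComponentMap,
                    config: AnalysisConfig) -> HelixParams:
    """Helix parameters for every frame plus mean/SD summaries.

    Second-half statistics (frames in the later half of the trajectory
    by time) are reported alongside the full-trajectory ones to expose
    equilibration drifts.  The apparent period is computed per frame
    from that frame's mean (d, phi) by default, or as the mean of
    per-pair periods with ``config.period_averaging == "per_pair"``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    cache = cmap.monomer_atom_indices(traj.structure)
    excl = config.end_exclusion
    d = np.empty(traj.n_frames)
    phi = np.empty(traj.n_frames)
    period = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        nf = normalize_frame(traj.frames[f], traj.structure, cmap, cache)
        d[f], phi[f] = helix_parameters(nf, exclude=excl)
        if config.period_averaging == "per_pair":
            dz, dphi = pairwise_helix_parameters(nf, exclude=excl)
            # pairs whose instantaneous azimuthal step exceeds 180 degrees
            # (strongly bent frames) have no defined per-pair period
            ok = (dphi > 0) & (dphi < 180.0) & (dz > 0)
            if ok.any():
                period[f] = float(np.mean([apparent_period(a, b)
                                           for a, b in zip(dz[ok], dphi[ok])]))
            else:
                period[f] = apparent_period(d[f], phi[f])
        else:
            period[f] = apparent_period(d[f], phi[f])

    half = traj.second_half_mask()
    summary = {}
    for name, series in (("d_nm", d), ("phi_deg", phi), ("period_nm", period)):
        summary[name] = {
            "mean": float(series.mean()),
            "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
            "second_half_mean": float(series[half].mean()),
            "second_half_sd": (float(series[half].std(ddof=1))
                               if half.sum() > 1 else 0.0),
        }
    return HelixParams(d_nm=d, phi_deg=phi, period_nm=period,
                       times_ps=traj.times.copy(), exclude=excl, summary=summary)
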