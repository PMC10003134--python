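"""Core in-memory containers for filament trajectory analysis.

Internal units: lengths in nm, times in ps, angles in degrees unless a
function states otherwise.  Stiffness outputs are SI (N, N·m²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# CODATA value, J/K
BOLTZMANN = 1.380649e-23

#: standard atomic masses (Da) for the elements that occur in protein
#: structures and in the synthetic pseudo-filaments
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "MG": 24.305, "ZN": 65.38,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


def mass_of_element(element: str) -> float:
    """Standard atomic mass in Da; raises KeyError for unknown elements."""
    return ATOMIC_MASSES[element.upper()]


@dataclass
class StructureModel:
    """A static structure as parallel per-atom arrays.

    Residue numbers follow the author numbering of the source file; no
    renumbering is ever applied.
    """

    chain_ids: np.ndarray          # (n,) str
    resids: np.ndarray             # (n,) int, author numbering
    resnames: np.ndarray           # (n,) str
    names: np.ndarray              # (n,) str, atom names
    elements: np.ndarray           # (n,) str
    masses: np.ndarray             # (n,) float, Da
    positions: np.ndarray          # (n, 3) float, nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        for name in ("chain_ids", "resids", "resnames", "names", "elements"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("non-positive atom masses")
        keys = list(zip(self.chain_ids.tolist(), self.resids.tolist(),
                        self.names.tolist()))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, resid, atom name) triples not unique")

    def atom_indices(self, chain: str, resid_range: tuple[int, int] | None = None,
                     resid: int | None = None, name: str | None = None,
                     element: str | None = None) -> np.ndarray:
        """Indices of atoms matching a chain and optional residue/name filters."""
        sel = self.chain_ids == chain
        if resid_range is not None:
            lo, hi = resid_range
            sel &= (self.resids >= lo) & (self.resids <= hi)
        if resid is not None:
            sel &= self.resids == resid
        if name is not None:
            sel &= self.names == name
        if element is not None:
            sel &= self.elements == element
        return np.flatnonzero(sel)


@dataclass
class FilamentTrajectory:
    """Time-ordered coordinate frames sharing one :class:`StructureModel`."""

    structure: StructureModel
    frames: np.ndarray             # (n_frames, n_atoms, 3), nm
    times: np.ndarray              # (n_frames,), ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"structure atom count {self.structure.n_atoms}")
        if self.frames.shape[0] == 0:
            raise ValueError("empty trajectory")
        if len(self.times) != len(self.frames):
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_interval(self) -> float:
        """Sampling step in ps (uniform spacing assumed)."""
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def second_half_mask(self) -> np.ndarray:
        """Frames belonging to the second half of the trajectory by time."""
        midpoint = 0.5 * (self.times[0] + self.times[-1])
        return self.times >= midpoint


@dataclass
class ComponentMap:
    """Assignment of chains/residues to filament components.

    ``monomers`` maps 1-based monomer indices (ordered from the pointed end)
    to lists of (chain, (first_resid, last_resid)) blocks.  ``long_helix``
    assigns each monomer to long pseudo-helix 1 or 2; consecutive monomers
    of the genetic helix must alternate between the two.
    """

    monomers: dict[int, list[tuple[str, tuple[int, int]]]]
    long_helix: dict[int, int]
    tpm_chains: dict[str, tuple[int, int]] = field(default_factory=dict)   # chain -> (strand, molecule)
    tn_chains: dict[str, tuple[int, str]] = field(default_factory=dict)    # chain -> (complex, subunit)
    marker_residue: int = 328
    donor_residues: tuple[int, ...] = (326, 328)
    acceptor_residues: tuple[int, ...] | None = None   # None -> all Asp/Glu

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    def validate(self, structure: StructureModel | None = None) -> None:
        indices = sorted(self.monomers)
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("non-contiguous monomer indices (must be 1..N)")
        if set(self.long_helix) != set(indices):
            raise ValueError("long_helix must cover every monomer exactly once")
        if not set(self.long_helix.values()) <= {1, 2}:
            raise ValueError("long-helix membership must be 1 or 2")
        for i in indices[:-1]:
            if self.long_helix[i] == self.long_helix[i + 1]:
                raise ValueError(
                    f"monomers {i} and {i + 1} share a long helix; consecutive "
                    "monomers must alternate between helices 1 and 2")
        for chain, (strand, _mol) in self.tpm_chains.items():
            if strand not in (1, 2):
                raise ValueError(f"Tpm chain {chain!r}: strand must be 1 or 2")
        for chain, (_cx, subunit) in self.tn_chains.items():
            if subunit not in ("TnC", "TnI", "TnT"):
                raise ValueError(f"Tn chain {chain!r}: unknown subunit {subunit!r}")
        if structure is not None:
            for i, blocks in self.monomers.items():
                for chain, (lo, hi) in blocks:
                    if len(structure.atom_indices(chain, (lo, hi))) == 0:
                        raise ValueError(
                            f"monomer {i}: no atoms for chain {chain!r} "
                            f"residues {lo}-{hi} in structure")
            for chain in list(self.tpm_chains) + list(self.tn_chains):
                if not np.any(structure.chain_ids == chain):
                    raise ValueError(f"chain {chain!r} absent from structure")

    def helix_monomers(self, helix_id: int) -> list[int]:
        """Monomer indices of one long pseudo-helix, in filament order."""
        return [i for i in sorted(self.monomers) if self.long_helix[i] == helix_id]

    def strand_chains(self, strand: int) -> list[str]:
        return [c for c, (s, _m) in sorted(self.tpm_chains.items()) if s == strand]

    def monomer_atom_indices(self, structure: StructureModel) -> list[np.ndarray]:
        """Per-monomer atom index arrays, ordered by monomer index."""
        out = []
        for i in sorted(self.monomers):
            idx = [structure.atom_indices(chain, rng) for chain, rng in self.monomers[i]]
            idx = np.concatenate(idx) if idx else np.empty(0, dtype=int)
            if len(idx) == 0:
                raise ValueError(f"monomer {i} selects no atoms")
            out.append(idx)
        return out


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criterion (GROMACS ``hbond`` convention)."""

    max_distance: float = 0.35       # donor-acceptor, nm
    max_angle: float = 30.0          # hydrogen-donor-acceptor, degrees
    hydrogen_required: bool = True

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0 < self.max_angle <= 180:
            raise ValueError("max_angle must be in (0, 180]")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline."""

    temperature: float = 300.0       # K
    kB: float = BOLTZMANN            # J/K
    window_ns: float = 16.0          # sliding-window width for the equipartition variances
    end_exclusion: int = 2           # monomers dropped at each filament end
    segment_offset: int = 5          # central segment spans monomers {o,o+1}..{N-o,N+1-o}
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    seed: int = 0
    # "parabola": monomer azimuths for the twist observable are taken about the
    # per-frame bent centerline; "z": about the laboratory z-axis.
    azimuth_reference: str = "parabola"
    # "mean_params": apparent period from per-frame mean (d, phi);
    # "per_pair": average of per-adjacent-pair periods.
    period_averaging: str = "mean_params"
    # "monomer_mean": segment endpoint azimuth = mean of the two monomers'
    # unwrapped azimuths; "combined_com": azimuth of their combined COM.
    segment_endpoint: str = "monomer_mean"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.end_exclusion < 0:
            raise ValueError("end_exclusion must be non-negative")
        if self.azimuth_reference not in ("parabola", "z"):
            raise ValueError("azimuth_reference must be 'parabola' or 'z'")
        if self.period_averaging not in ("mean_params", "per_pair"):
            raise ValueError("period_averaging must be 'mean_params' or 'per_pair'")
        if self.segment_endpoint not in ("monomer_mean", "combined_com"):
            raise ValueError("segment_endpoint must be 'monomer_mean' or 'combined_com'")

    def window_frames(self, frame_interval_ps: float) -> int:
        """Sliding-window width in frames for a given sampling step."""
        if frame_interval_ps <= 0:
            raise ValueError("frame_interval must be positive")
        w = int(round(self.window_ns * 1000.0 / frame_interval_ps))
        return max(w, 2)
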