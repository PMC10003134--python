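"""Reading and writing of structures, trajectories, component maps and reports.

Structure and trajectory formats (PDB, GRO, multi-model PDB, XTC, DCD)
are handled through MDAnalysis; coordinates are converted to nm
internally (MDAnalysis works in Angstrom, PDB columns are Angstrom).
The component map and analysis configuration live together in one YAML
file.  Result tables are written as TSV with units in the column
headers, summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

from .models import (ATOMIC_MASSES, AnalysisConfig, ComponentMap,
                     FilamentTrajectory, HBondCriteria, StructureModel)

log = logging.getLogger(__name__)

A_PER_NM = 10.0


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot derive an element from atom name {name!r}")


def _resolve_elements(elements: np.ndarray | None, names: np.ndarray) -> np.ndarray:
    out = []
    for k, name in enumerate(names):
        el = ""
        if elements is not None:
            el = str(elements[k]).strip().upper()
        if el not in ATOMIC_MASSES:
            fallback = _element_from_name(str(name))
            if el:
                log.warning("unknown element %r for atom %r; using %r from the "
                            "atom name", el, name, fallback)
            out.append(fallback)
        else:
            out.append(el)
    return np.array(out)


def load_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or GRO file into a :class:`StructureModel` (nm units).

    Author residue numbering is preserved; masses are standard atomic
    masses assigned from the element (derived from the atom name, with
    a warning, when the element column is absent or unknown).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt, to_guess=())
    atoms = u.atoms
    names = atoms.names.astype(str)
    elements = None
    if hasattr(atoms, "elements"):
        elements = atoms.elements.astype(str)
    elements = _resolve_elements(elements, names)
    chain_ids = (atoms.chainIDs.astype(str) if hasattr(atoms, "chainIDs")
                 else atoms.segids.astype(str))
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    return StructureModel(
        chain_ids=chain_ids, resids=atoms.resids.copy(),
        resnames=atoms.resnames.astype(str), names=names, elements=elements,
        masses=masses, positions=atoms.positions.astype(float) / A_PER_NM)


def _universe_from_structure(structure: StructureModel) -> "mda.Universe":
    n = structure.n_atoms
    res_keys = list(dict.fromkeys(zip(structure.chain_ids.tolist(),
                                      structure.resids.tolist())))
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array([res_index[(c, r)] for c, r in
                              zip(structure.chain_ids, structure.resids)])
    seg_keys = list(dict.fromkeys(k[0] for k in res_keys))
    seg_index = {s: i for i, s in enumerate(seg_keys)}
    residue_segindex = np.array([seg_index[k[0]] for k in res_keys])
    u = mda.Universe.empty(n, n_residues=len(res_keys),
                           atom_resindex=atom_resindex,
                           residue_segindex=residue_segindex,
                           n_segments=len(seg_keys), trajectory=True)
    u.add_TopologyAttr("names", structure.names.astype(object))
    u.add_TopologyAttr("elements", structure.elements.astype(object))
    u.add_TopologyAttr("chainIDs", structure.chain_ids.astype(object))
    u.add_TopologyAttr("resids", np.array([k[1] for k in res_keys]))
    resname_of = {}
    for c, r, rn in zip(structure.chain_ids, structure.resids, structure.resnames):
        resname_of.setdefault((c, r), rn)
    u.add_TopologyAttr("resnames",
                       np.array([resname_of[k] for k in res_keys], dtype=object))
    u.add_TopologyAttr("segids", np.array(seg_keys, dtype=object))
    u.add_TopologyAttr("masses", structure.masses.copy())
    u.atoms.positions = structure.positions * A_PER_NM
    return u


def write_structure(structure: StructureModel, path: str | Path) -> Path:
    """Write a single-model PDB file (Angstrom columns)."""
    path = Path(path)
    u = _universe_from_structure(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def write_trajectory(traj: FilamentTrajectory, path: str | Path) -> Path:
    """Write a trajectory as multi-model PDB (.pdb) or XTC (.xtc)."""
    path = Path(path)
    u = _universe_from_structure(traj.structure)
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".pdb":
            with mda.Writer(str(path), n_atoms=traj.structure.n_atoms,
                            multiframe=True) as w:
                for frame in traj.frames:
                    u.atoms.positions = frame * A_PER_NM
                    w.write(u.atoms)
        elif suffix == ".xtc":
            with mda.Writer(str(path), n_atoms=traj.structure.n_atoms) as w:
                for k, frame in enumerate(traj.frames):
                    u.atoms.positions = frame * A_PER_NM
                    u.trajectory.ts.frame = k
                    u.trajectory.ts.time = float(traj.times[k])
                    w.write(u.atoms)
        else:
            raise ValueError(f"unsupported trajectory format {suffix!r}")
    return path


def load_trajectory(structure: StructureModel, path: str | Path,
                    format: str | None = None, stride: int = 1,
                    frame_interval: float = 200.0) -> FilamentTrajectory:
    """Read a multi-model PDB, XTC or DCD trajectory (nm, ps).

    ``frame_interval`` (ps) supplies the sampling step when the file
    format carries no usable time information (multi-model PDB, most
    DCDs); formats with embedded times (XTC) keep them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    fmt = (format or path.suffix.lstrip(".")).upper()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "PDB":
            u = mda.Universe(str(path), format="PDB", to_guess=())
            reader = u.trajectory
        elif fmt == "XTC":
            reader = XTCReader(str(path))
        elif fmt == "DCD":
            reader = DCDReader(str(path))
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")
        if reader.n_atoms != structure.n_atoms:
            raise ValueError(f"trajectory atom count {reader.n_atoms} does not "
                             f"match structure atom count {structure.n_atoms}")
        frames, times = [], []
        for k, ts in enumerate(reader):
            if k % stride:
                continue
            frames.append(ts.positions.astype(float) / A_PER_NM)
            times.append(float(ts.time))
    if not frames:
        raise ValueError("empty trajectory")
    times = np.array(times)
    if len(times) > 1 and (np.any(np.diff(times) <= 0) or fmt in ("PDB", "DCD")):
        # no trustworthy embedded times; synthesize from the file frame index
        times = np.arange(0, len(frames)) * frame_interval * stride
    return FilamentTrajectory(structure=structure, frames=np.array(frames),
                              times=times)


# ------------------------------------------------------------- component map

def load_component_map(path: str | Path,
                       structure: StructureModel | None = None) -> ComponentMap:
    """Read the component map from the YAML configuration file.

    Omitted marker/donor residues default to Lys328 and {Lys326, Lys328}.
    The map is validated (against the structure when one is supplied).
    """
    data = yaml.safe_load(Path(path).read_text())
    comp = data.get("components", data)
    monomers: dict[int, list[tuple[str, tuple[int, int]]]] = {}
    long_helix: dict[int, int] = {}
    for entry in comp["monomers"]:
        idx = int(entry["index"])
        if idx in monomers:
            raise ValueError(f"duplicate monomer index {idx}")
        monomers[idx] = [(str(b["chain"]), (int(b["first"]), int(b["last"])))
                         for b in entry["blocks"]]
        long_helix[idx] = int(entry["helix"])
    tpm = {str(c): (int(v["strand"]), int(v.get("molecule", 1)))
           for c, v in (comp.get("tpm_chains") or {}).items()}
    tn = {str(c): (int(v.get("complex", 1)), str(v["subunit"]))
          for c, v in (comp.get("tn_chains") or {}).items()}
    acceptors = comp.get("acceptor_residues")
    cmap = ComponentMap(
        monomers=monomers, long_helix=long_helix, tpm_chains=tpm, tn_chains=tn,
        marker_residue=int(comp.get("marker_residue", 328)),
        donor_residues=tuple(comp.get("donor_residues", (326, 328))),
        acceptor_residues=tuple(acceptors) if acceptors else None)
    if structure is not None:
        cmap.validate(structure)
    return cmap


def load_config(path: str | Path) -> AnalysisConfig:
    """Read the analysis section of the configuration file (defaults fill in)."""
    data = yaml.safe_load(Path(path).read_text())
    ana = dict(data.get("analysis") or {})
    hb = ana.pop("hbond", None)
    cfg = AnalysisConfig(**ana)
    if hb:
        cfg.hbond = HBondCriteria(**hb)
    return cfg


def write_component_map(cmap: ComponentMap, path: str | Path,
                        config: AnalysisConfig | None = None) -> Path:
    """Write the component map (and optional analysis section) as YAML."""
    comp = {
        "monomers": [
            {"index": i, "helix": cmap.long_helix[i],
             "blocks": [{"chain": c, "first": lo, "last": hi}
                        for c, (lo, hi) in cmap.monomers[i]]}
            for i in sorted(cmap.monomers)],
        "tpm_chains": {c: {"strand": s, "molecule": m}
                       for c, (s, m) in cmap.tpm_chains.items()},
        "tn_chains": {c: {"complex": x, "subunit": s}
                      for c, (x, s) in cmap.tn_chains.items()},
        "marker_residue": cmap.marker_residue,
        "donor_residues": list(cmap.donor_residues),
        "acceptor_residues": (list(cmap.acceptor_residues)
                              if cmap.acceptor_residues else None),
    }
    data: dict = {"components": comp}
    if config is not None:
        ana = dataclasses.asdict(config)
        ana["hbond"] = dataclasses.asdict(config.hbond)
        data["analysis"] = ana
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


# ------------------------------------------------------------------ reports

def write_report(results, path: str | Path, format: str | None = None) -> Path:
    """Write a result table (TSV) or summary (JSON).

    DataFrames go to TSV with a deterministic column order and enough
    digits to round-trip to at least 6 significant figures; dicts and
    dataclasses go to JSON.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if isinstance(results, pd.DataFrame):
        if fmt not in ("tsv", "txt"):
            raise ValueError("tables are written as TSV")
        results.to_csv(path, sep="\t", index=False, float_format="%.8g")
        return path
    if hasattr(results, "as_dict"):
        results = results.as_dict()
    elif dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = dataclasses.asdict(results)
    if fmt != "json":
        raise ValueError("summaries are written as JSON")

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(results, indent=2, default=_default) + "\n")
    return path
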