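#!/usr/bin/env python
"""Actin genetic-helix parameters d, phi and apparent period P.

Reads the synthetic study trajectory, removes rigid-body motion per
frame, excludes two monomers at each end, and reports trajectory
mean +/- SD (with second-half values) of the axial rise d, the helical
angle phi and the apparent period P = d·pi/(pi - phi).  Tables go to
results/.
"""

import sys
from pathlib import Path

from thinfilament import io
from thinfilament.helix import summarize_helix

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    structure = io.load_structure(DATA / "structure.pdb")
    cmap = io.load_component_map(DATA / "components.yaml", structure)
    config = io.load_config(DATA / "components.yaml")
    traj = io.load_trajectory(structure, DATA / "trajectory.xtc")

    hp = summarize_helix(traj, cmap, config)
    RESULTS.mkdir(exist_ok=True)
    io.write_report(hp.frame_table(), RESULTS / "helix_frames.tsv")
    io.write_report(hp.summary, RESULTS / "helix_summary.json")

    print(f"{traj.n_frames} frames, {cmap.n_monomers} monomers, "
          f"{hp.exclude} excluded per end")
    for name, label, unit in (("d_nm", "d", "nm"), ("phi_deg", "phi", "deg"),
                              ("period_nm", "P", "nm")):
        s = hp.summary[name]
        print(f"  {label:3s} = {s['mean']:8.3f} ± {s['sd']:.3f} {unit}   "
              f"(2nd half: {s['second_half_mean']:.3f})")
    print("generator truth: d = 2.750 nm, phi = 166.600 deg "
          "(P of the means: 36.94 nm)")


if __name__ == "__main__":
    sys.exit(main())
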