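#!/usr/bin/env python
"""Stiffness of the fluctuating filament: WLC bending + equipartition.

Per frame the monomer-COM centerline is fitted with parabolas and the
end-tangent cosine feeds the worm-like-chain persistence length; the
central-segment length L and twist Psi feed the equipartition
estimators with a 16 ns sliding window.  Recovered values are compared
against the generator's ground truth.
"""

import sys
from pathlib import Path

from thinfilament import io
from thinfilament.mechanics import summarize_mechanics
from thinfilament.synth import SyntheticParams

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    structure = io.load_structure(DATA / "structure.pdb")
    cmap = io.load_component_map(DATA / "components.yaml", structure)
    config = io.load_config(DATA / "components.yaml")
    traj = io.load_trajectory(structure, DATA / "trajectory.xtc")

    props, table = summarize_mechanics(traj, cmap, config)
    RESULTS.mkdir(exist_ok=True)
    io.write_report(table, RESULTS / "mechanics_frames.tsv")
    io.write_report(props, RESULTS / "mechanics_summary.json")

    truth = SyntheticParams()
    print(f"{traj.n_frames} frames; window {props.window_ns} ns; "
          f"half-length l = {props.half_length_nm:.2f} nm")
    rows = [
        ("xi", props.xi_m, truth.xi_true, "m"),
        ("Kb", props.Kb, truth.xi_true * 1.380649e-23 * 300.0, "N·m²"),
        ("K ", props.K, truth.K_true, "N"),
        ("G ", props.G, truth.G_true, "N·m²"),
    ]
    for label, got, want, unit in rows:
        print(f"  {label} = {got:10.4g} {unit:5s} (truth {want:.4g}, "
              f"ratio {got / want:.3f})")
    sh = props.second_half
    print(f"  2nd half: K = {sh['longitudinal_stiffness_N']:.4g} N, "
          f"G = {sh['torsional_stiffness_Nm2']:.4g} N·m²")


if __name__ == "__main__":
    sys.exit(main())
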