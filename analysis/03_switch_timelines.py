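#!/usr/bin/env python
"""Render per-window molecular-switch timelines for every ensemble run.

For each run: the three-level Q422-MgATP state, the binary D423 charge-pair
and coupling-loop states at both composite sites, and the R474 stacking
state along the symmetry axis, on the shared 1-ns window grid.  Output is a
compact letter-per-window text diagram written to results/timelines.txt.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from dimerswitch import build_timeline, default_site_pairing
from dimerswitch.io import load_manifest, load_motif_map, read_multimodel_pdb

ENSEMBLE = ROOT / "scratch" / "ensemble"
RESULTS = ROOT / "results"

LETTER = {"LOW": "L", "MID": "M", "HIGH": "H", "ON": "#", "OFF": ".",
          "A_closer_to_TMDs": "A", "B_closer_to_TMDs": "B",
          "side_by_side": "="}


def main() -> None:
    if not (ENSEMBLE / "manifest.yaml").exists():
        sys.exit("run analysis/01_generate_ensemble.py first")
    manifest = load_manifest(ENSEMBLE / "manifest.yaml")
    motif_map = load_motif_map(ENSEMBLE / "motifs.yaml")
    pairing = default_site_pairing(motif_map)

    lines = ["per-run switch timelines (one letter per 1-ns window)",
             "Q422: L/M/H contact level; binary switches: '#'=on '.'=off;",
             "stacking: A/B = that monomer's R474 closer to the TMDs, "
             "'=' side by side", ""]
    for entry in manifest.entries:
        traj = read_multimodel_pdb(
            entry.path, frame_interval_ps=entry.frame_interval_ps,
            run_id=entry.run_id, lipid=entry.lipid,
            nucleotide=entry.nucleotide, duration_ns=entry.duration_ns)
        tl = build_timeline(traj, pairing, motif_map, drop_partial=True)
        lines.append(f"run {entry.run_id} ({entry.lipid}/{entry.nucleotide}, "
                     f"{entry.duration_ns:g} ns)")
        for key in sorted(tl.states):
            seq = "".join(LETTER[s.state] for s in tl.states[key])
            lines.append(f"  {key[0]:<12} {key[1]}  {seq}")
        lines.append(f"  {'R474 stack':<12} axis   "
                     + "".join(LETTER[s] for s in tl.stacking_sequence()))
        lines.append("")
        print(lines[-len(tl.states) - 3])
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "timelines.txt").write_text("\n".join(lines))
    print(f"wrote {RESULTS / 'timelines.txt'}")


if __name__ == "__main__":
    main()
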