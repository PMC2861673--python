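"""Multi-model PDB reading/writing, manifests, motif maps, snapshot export.

Reading is delegated to gemmi; writing uses a fixed-column PDB v3.3 formatter
(occupancy 1.00, B-factor 0.00) so that exported snapshot files round-trip
coordinates at the 3-decimal precision of the format.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import yaml

from .model import (AtomSite, Frame, ManifestEntry, MotifMap, RunManifest,
                    SelectionSpec, Topology, Trajectory, TrajectoryError,
                    WATER_RESNAMES, resolve_selection)

#: default snapshot interval, ps
DEFAULT_FRAME_INTERVAL_PS = 50.0


class PdbParseError(ValueError):
    """Inconsistent or unreadable multi-model PDB content."""


def _model_sites_coords(model: "gemmi.Model") -> tuple[list[AtomSite], np.ndarray]:
    sites: list[AtomSite] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            for atom in res:
                sites.append(AtomSite(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    chain_id=chain.name,
                ))
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    return sites, np.array(coords, dtype=float).reshape(len(sites), 3)


def read_multimodel_pdb(path: str | Path,
                        times_ps: Optional[Sequence[float]] = None,
                        frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
                        run_id: Optional[str] = None,
                        lipid: str = "none",
                        nucleotide: str = "MgATP",
                        duration_ns: Optional[float] = None) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    The PDB format carries no time axis: pass an explicit ``times_ps`` list
    (one entry per MODEL) or accept a uniform stride of ``frame_interval_ps``
    starting at 0.  Every MODEL must contain the same atoms in the same
    order; a mismatch raises :class:`PdbParseError` naming the model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise PdbParseError(f"{path}: no models found")
    ref_sites, ref_coords = _model_sites_coords(st[0])
    if not ref_sites:
        raise PdbParseError(f"{path}: model 1 contains no atoms")
    topo = Topology(ref_sites)
    key = topo.identity_key()
    all_coords = [ref_coords]
    for mi in range(1, len(st)):
        sites, coords = _model_sites_coords(st[mi])
        model_number = mi + 1
        if len(sites) != len(ref_sites):
            raise PdbParseError(
                f"{path}: model {model_number} has {len(sites)} atoms, "
                f"expected {len(ref_sites)} (as in model 1)")
        if Topology(sites).identity_key() != key:
            raise PdbParseError(
                f"{path}: model {model_number} atom identities differ from model 1")
        all_coords.append(coords)
    n = len(all_coords)
    if times_ps is None:
        times = np.arange(n, dtype=float) * float(frame_interval_ps)
    else:
        if len(times_ps) != n:
            raise PdbParseError(
                f"{path}: {len(times_ps)} times given for {n} models")
        times = np.asarray(times_ps, dtype=float)
    return Trajectory(topo, np.stack(all_coords), times,
                      run_id=run_id or path.stem, lipid=lipid,
                      nucleotide=nucleotide, duration_ns=duration_ns)


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _atom_line(site: AtomSite, xyz: np.ndarray, serial: int) -> str:
    record = "ATOM  " if site.residue_name in _STANDARD_AA else "HETATM"
    name = site.name
    # PDB column convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:5d} {name_field:<4s} {site.residue_name:<3s} "
            f"{site.chain_id[0]}{site.residue_number:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {site.element:>2s}")


def canonical_atom_order(topology: Topology,
                         indices: Optional[Sequence[int]] = None) -> list[int]:
    """Chain-grouped, residue-contiguous atom ordering.

    PDB readers regroup atoms by chain and residue; writing in this
    canonical order (chains by first appearance, residues by first
    appearance within their chain, atoms in original order within their
    residue) makes write/read a true identity on atom ordering.
    """
    idx = list(range(len(topology))) if indices is None else [int(i) for i in indices]
    chain_rank: dict[str, int] = {}
    res_rank: dict[tuple[str, int], int] = {}
    for i in idx:
        s = topology[i]
        chain_rank.setdefault(s.chain_id, len(chain_rank))
        res_rank.setdefault((s.chain_id, s.residue_number), len(res_rank))
    return sorted(idx, key=lambda i: (
        chain_rank[topology[i].chain_id],
        res_rank[(topology[i].chain_id, topology[i].residue_number)], i))


def write_multimodel_pdb(path: str | Path, frames: Sequence[Frame],
                         atom_indices: Optional[Sequence[int]] = None) -> Path:
    """Write frames as MODEL/ENDMDL blocks in fixed-column PDB v3.3.

    Atoms are emitted in canonical chain-grouped order (see
    :func:`canonical_atom_order`), with sequential serials per model.
    """
    path = Path(path)
    lines: list[str] = []
    order: Optional[list[int]] = None
    for mi, fr in enumerate(frames, start=1):
        if order is None:
            order = canonical_atom_order(fr.topology, atom_indices)
        lines.append(f"MODEL     {mi:4d}")
        for serial, i in enumerate(order, start=1):
            lines.append(_atom_line(fr.topology[i], fr.coords[i], serial))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_trajectory_pdb(path: str | Path, traj: Trajectory) -> Path:
    return write_multimodel_pdb(path, traj.frames)


def nearest_water_residues(frame: Frame, ligand_idx: np.ndarray,
                           n_waters: int) -> list[tuple[str, int]]:
    """Rank whole water residues by minimum atom-atom distance to the ligand.

    Returns the ``(chain_id, residue_number)`` keys of the ``n_waters``
    closest waters; equal minimum distances are broken by ascending residue
    number (then chain) for determinism.
    """
    topo = frame.topology
    waters: dict[tuple[str, int], list[int]] = {}
    for i, s in enumerate(topo.sites):
        if s.is_water:
            waters.setdefault((s.chain_id, s.residue_number), []).append(i)
    if n_waters > len(waters):
        raise ValueError(
            f"requested {n_waters} waters but frame has only {len(waters)}")
    lig = frame.coords[ligand_idx]
    ranked = []
    for (chain, resnum), idx in waters.items():
        d = np.linalg.norm(frame.coords[idx][:, None, :] - lig[None, :, :], axis=-1)
        ranked.append((float(d.min()), resnum, chain, (chain, resnum)))
    ranked.sort(key=lambda t: (t[0], t[1], t[2]))
    return [key for _, _, _, key in ranked[:n_waters]]


def write_snapshots(traj: Trajectory, ligand: SelectionSpec,
                    times_ns: Sequence[float], n_waters: int,
                    path: str | Path) -> Path:
    """Export selected frames as a multi-model PDB of protein + ligand +
    the ``n_waters`` water residues closest to the ligand.

    Each requested time (ns) must match a frame within half a frame
    interval; the ligand's nearest waters are re-ranked per snapshot.
    """
    path = Path(path)
    interval = traj.frame_interval_ps if traj.n_frames > 1 else math.inf
    lines: list[str] = []
    for mi, t_ns in enumerate(times_ns, start=1):
        t_ps = float(t_ns) * 1000.0
        fi = int(np.argmin(np.abs(traj.times_ps - t_ps)))
        if abs(traj.times_ps[fi] - t_ps) > interval / 2 + 1e-9:
            available = ", ".join(f"{t/1000.0:g}" for t in traj.times_ps[:10])
            more = " ..." if traj.n_frames > 10 else ""
            raise ValueError(
                f"no frame within half an interval of {t_ns} ns; "
                f"available times (ns): {available}{more}")
        fr = traj.frame(fi)
        lig_idx = resolve_selection(ligand, fr)
        keep_waters = set(nearest_water_residues(fr, lig_idx, n_waters))
        # protein + ligand are the non-water atoms; add the ranked waters
        idx = canonical_atom_order(fr.topology, [
            i for i, s in enumerate(fr.topology.sites)
            if not s.is_water
            or (s.chain_id, s.residue_number) in keep_waters])
        lines.append(f"MODEL     {mi:4d}")
        for serial, i in enumerate(idx, start=1):
            lines.append(_atom_line(fr.topology[i], fr.coords[i], serial))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# manifests and motif maps (flat YAML)

def load_manifest(path: str | Path) -> RunManifest:
    """Load a run manifest: a YAML file with a ``runs`` list of entries."""
    raw = yaml.safe_load(Path(path).read_text())
    if not raw or "runs" not in raw:
        raise ValueError(f"{path}: manifest must contain a 'runs' list")
    entries = []
    for item in raw["runs"]:
        entries.append(ManifestEntry(
            run_id=str(item["run_id"]),
            lipid=str(item["lipid"]),
            nucleotide=str(item["nucleotide"]),
            duration_ns=float(item["duration_ns"]),
            path=str(item["path"]),
            frame_interval_ps=float(item.get("frame_interval_ps",
                                             DEFAULT_FRAME_INTERVAL_PS)),
        ))
    return RunManifest(entries)


def dump_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    data = {"runs": [{
        "run_id": e.run_id, "lipid": e.lipid, "nucleotide": e.nucleotide,
        "duration_ns": e.duration_ns, "path": e.path,
        "frame_interval_ps": e.frame_interval_ps,
    } for e in manifest.entries]}
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def _spec_from_cfg(cfg: dict) -> SelectionSpec:
    atoms = cfg.get("atoms")
    return SelectionSpec(
        chain_id=str(cfg["chain"]),
        residue_numbers=frozenset(int(r) for r in cfg["residues"]),
        atom_names=None if atoms is None else frozenset(atoms),
    )


def load_motif_map(path: str | Path) -> MotifMap:
    """Load a motif map: motif label -> monomer -> {chain, residues[, atoms]}."""
    raw = yaml.safe_load(Path(path).read_text())
    motifs = {label: {mono: _spec_from_cfg(cfg) for mono, cfg in per.items()}
              for label, per in raw["motifs"].items()}
    axis = np.asarray(raw.get("symmetry_axis", [0.0, 0.0, 1.0]), dtype=float)
    return MotifMap(motifs, axis, float(raw.get("tmd_direction", +1.0)))


def dump_motif_map(mm: MotifMap, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "symmetry_axis": [float(x) for x in mm.symmetry_axis],
        "tmd_direction": mm.tmd_direction,
        "motifs": {
            label: {mono: {
                "chain": spec.chain_id,
                "residues": sorted(spec.residue_numbers),
                **({"atoms": sorted(spec.atom_names)} if spec.atom_names else {}),
            } for mono, spec in per.items()}
            for label, per in mm.motifs.items()
        },
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
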