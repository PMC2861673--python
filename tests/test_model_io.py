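"""Structure model, selections, multi-model PDB IO and snapshot export."""

import math

import numpy as np
import pytest

from dimerswitch import (SelectionError, SelectionSpec, read_multimodel_pdb,
                         resolve_selection, write_snapshots,
                         write_trajectory_pdb)
from dimerswitch.io import (PdbParseError, dump_manifest, dump_motif_map,
                            load_manifest, load_motif_map,
                            nearest_water_residues)
from dimerswitch.model import ManifestEntry, RunManifest, Trajectory
from dimerswitch.synthetic import generate_trajectory, symmetric_schedule

from conftest import make_frame

SINGLE_MODEL = """MODEL        1
ATOM      1  CA  GLN A 422      10.000  20.000  30.000  1.00  0.00           C
ATOM      2  CB  GLN A 422      11.000  21.000  31.000  1.00  0.00           C
ATOM      3  CA  ASP A 423      12.000  22.000  32.000  1.00  0.00           C
ENDMDL
END
"""


def test_single_model_read(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(SINGLE_MODEL)
    traj = read_multimodel_pdb(p)
    assert traj.n_frames == 1
    assert len(traj.topology) == 3
    assert traj.times_ps[0] == 0.0
    assert traj.frame(0).coords[0, 0] == pytest.approx(10.0)


def test_missing_atom_names_model_index(tmp_path):
    broken = SINGLE_MODEL.replace("ENDMDL\nEND\n", "ENDMDL\n") + (
        "MODEL        2\n"
        "ATOM      1  CA  GLN A 422      10.000  20.000  30.000  1.00  0.00           C\n"
        "ATOM      2  CB  GLN A 422      11.000  21.000  31.000  1.00  0.00           C\n"
        "ENDMDL\nEND\n")
    p = tmp_path / "broken.pdb"
    p.write_text(broken)
    with pytest.raises(PdbParseError, match="model 2"):
        read_multimodel_pdb(p)


def test_sidecar_times_and_stride(tmp_path, dimer):
    traj = generate_trajectory(dimer, symmetric_schedule(0.2), 0.2)
    p = write_trajectory_pdb(tmp_path / "t.pdb", traj)
    by_stride = read_multimodel_pdb(p, frame_interval_ps=50.0)
    assert np.array_equal(by_stride.times_ps, np.arange(5) * 50.0)
    explicit = read_multimodel_pdb(p, times_ps=[0, 10, 20, 30, 40])
    assert np.array_equal(explicit.times_ps, [0, 10, 20, 30, 40])
    with pytest.raises(PdbParseError, match="times"):
        read_multimodel_pdb(p, times_ps=[0, 10])


def test_write_read_roundtrip_identity(tmp_path, dimer):
    """write o read is the identity on coordinates at PDB precision."""
    traj = generate_trajectory(dimer, symmetric_schedule(0.5, noise_sd=0.3),
                               0.5, run_id="rt")
    p = write_trajectory_pdb(tmp_path / "rt.pdb", traj)
    back = read_multimodel_pdb(p, frame_interval_ps=50.0)
    assert back.n_frames == traj.n_frames
    assert back.topology.identity_key() == traj.topology.identity_key()
    assert np.abs(back.coords - traj.coords).max() < 5.1e-4


def test_resolve_selection_basics(dimer):
    fr = dimer.frame
    idx = resolve_selection(SelectionSpec("A", frozenset({422})), fr)
    assert len(idx) > 0
    assert all(fr.topology[int(i)].residue_number == 422 for i in idx)
    assert all(fr.topology[int(i)].chain_id == "A" for i in idx)
    # deterministic and order-preserving
    assert np.array_equal(idx, np.sort(idx))
    with pytest.raises(SelectionError):
        resolve_selection(SelectionSpec("Z", frozenset({422})), fr)


def test_resolve_selection_atom_filter():
    fr = make_frame([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0],
                     [4, 0, 0], [5, 0, 0]],
                    names=["CA", "CB", "CA", "CB", "CA", "CB"],
                    resnums=[1, 1, 2, 2, 3, 3])
    idx = resolve_selection(
        SelectionSpec("A", frozenset({1, 2, 3}), frozenset({"CA"})), fr)
    assert len(idx) == 3


def test_nearest_waters_brute_force():
    """3 requested waters out of 5 equal exhaustive min-distance ranking."""
    rng = np.random.default_rng(4)
    lig = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    waters = rng.uniform(-12, 12, size=(5, 3))
    positions = np.vstack([lig, waters])
    fr = make_frame(positions,
                    names=["L1", "L2", "OW", "OW", "OW", "OW", "OW"],
                    resnums=[900, 900, 1, 2, 3, 4, 5],
                    chain=["A", "A", "W", "W", "W", "W", "W"],
                    resname=["ATP", "ATP", "SOL", "SOL", "SOL", "SOL", "SOL"])
    ligidx = np.array([0, 1])
    got = nearest_water_residues(fr, ligidx, 3)
    dists = {}
    for i, s in enumerate(fr.topology.sites):
        if s.is_water:
            d = min(math.dist(fr.coords[i], fr.coords[j]) for j in ligidx)
            dists[(s.chain_id, s.residue_number)] = d
    expect = sorted(dists, key=lambda k: (dists[k], k[1]))[:3]
    assert got == expect


def test_nearest_water_tie_breaks_by_residue_number():
    fr = make_frame([[0, 0, 0], [5, 0, 0], [-5, 0, 0], [0, 5, 0]],
                    names=["L", "OW", "OW", "OW"],
                    resnums=[900, 7, 3, 12],
                    chain=["A", "W", "W", "W"],
                    resname=["ATP", "SOL", "SOL", "SOL"])
    got = nearest_water_residues(fr, np.array([0]), 2)
    assert got == [("W", 3), ("W", 7)]


def test_write_snapshots_models_and_waters(tmp_path, dimer):
    traj = generate_trajectory(dimer, symmetric_schedule(2.0), 2.0)
    lig = dimer.motif_map.spec("ligand", "A")
    p = write_snapshots(traj, lig, [0, 0.5, 1.0, 2.0], 40,
                        tmp_path / "snap.pdb")
    snap = read_multimodel_pdb(p)
    assert snap.n_frames == 4
    waters = {(s.chain_id, s.residue_number)
              for s in snap.topology.sites if s.is_water}
    assert len(waters) == 40
    # all non-water atoms of the source survive in each model
    n_protein = sum(not s.is_water for s in traj.topology.sites)
    assert sum(not s.is_water for s in snap.topology.sites) == n_protein


def test_write_snapshots_bad_time_lists_available(tmp_path, dimer):
    traj = generate_trajectory(dimer, symmetric_schedule(1.0), 1.0)
    lig = dimer.motif_map.spec("ligand", "A")
    with pytest.raises(ValueError, match="available times"):
        write_snapshots(traj, lig, [3.0], 5, tmp_path / "x.pdb")


def test_write_snapshots_too_many_waters(tmp_path, dimer):
    traj = generate_trajectory(dimer, symmetric_schedule(1.0), 1.0)
    lig = dimer.motif_map.spec("ligand", "A")
    with pytest.raises(ValueError, match="waters"):
        write_snapshots(traj, lig, [0.0], 10_000, tmp_path / "x.pdb")


def test_manifest_roundtrip(tmp_path):
    m = RunManifest([
        ManifestEntry("r1", "DPPC", "MgATP", 40.0, "r1.pdb"),
        ManifestEntry("r2", "POPC", "MgATP", 30.0, "r2.pdb", 25.0),
    ])
    p = dump_manifest(m, tmp_path / "manifest.yaml")
    back = load_manifest(p)
    assert back.entries == m.entries


def test_manifest_rejects_duplicates_and_bad_values():
    with pytest.raises(ValueError, match="unique"):
        RunManifest([ManifestEntry("r", "DPPC", "MgATP", 1.0, "a.pdb"),
                     ManifestEntry("r", "DPPC", "ADP", 1.0, "b.pdb")])
    with pytest.raises(ValueError, match="duration"):
        ManifestEntry("r", "DPPC", "MgATP", -1.0, "a.pdb")
    with pytest.raises(ValueError, match="lipid"):
        ManifestEntry("r", "DMPC", "MgATP", 1.0, "a.pdb")


def test_motif_map_roundtrip(tmp_path, dimer):
    p = dump_motif_map(dimer.motif_map, tmp_path / "motifs.yaml")
    back = load_motif_map(p)
    assert back.monomers == dimer.motif_map.monomers
    for label, per in dimer.motif_map.motifs.items():
        for mono, spec in per.items():
            assert back.spec(label, mono) == spec
    assert np.allclose(back.symmetry_axis, dimer.motif_map.symmetry_axis)


def test_trajectory_invariants():
    fr = make_frame([[0, 0, 0]])
    with pytest.raises(Exception, match="increasing"):
        Trajectory(fr.topology, np.zeros((2, 1, 3)), np.array([50.0, 50.0]))
    with pytest.raises(Exception, match="duration"):
        Trajectory(fr.topology, np.zeros((2, 1, 3)), np.array([0.0, 2000.0]),
                   duration_ns=1.0)
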