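"""Synthetic homodimer structures and trajectories with planted dynamics.

The generator builds a toy two-chain homodimer whose two composite sites
are exact mirror images (180 deg rotation about the z symmetry axis, with
chain labels swapped), so the structure is perfectly symmetric before any
schedule is planted.  Each tracked interaction occupies an isolated
*station*: a grid of slot-atom pairs in which the two partners of slot m
sit at the same (x, y) and differ only in z.  A slot realizes a contact by
moving its partner atom to 3 A vertical separation (inside the 4 A cutoff)
and breaks it at 6 A, so contact counts are controlled geometrically and
the full counting pipeline - including cutoff strictness - is exercised.

Planted dynamics follow a :class:`SwitchSchedule`: per switch and per
site, a list of (start_ns, end_ns, target) segments.  Targets may be
state names (mapped to counts safely inside the discretization bins:
LOW->2, MID->9, HIGH->17 for the three-level Q422 switch) or raw integer
counts.  Per-frame counts are the target plus integer-rounded Gaussian
noise (standard deviation ``noise_sd``), clipped to the available slots.
All randomness derives from one seed through numpy ``SeedSequence``
spawning, one child stream per (switch, site), so sub-streams are
independently reproducible.

Geometry is kinematic only: residues scattered over several stations have
no physical shape, and no force field or energetics is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (AtomSite, Frame, MotifMap, SelectionSpec, Topology,
                    Trajectory)

#: planted contact levels for the three-level Q422 switch, safely inside
#: the <5 / 5-14 / >14 discretization bins
Q422_LEVELS = {"LOW": 2, "MID": 9, "HIGH": 17}

#: planted on/off contact levels per binary switch (threshold in parentheses)
BINARY_LEVELS = {
    "D423-K483": {"OFF": 0, "ON": 3},    # threshold 1
    "D423-R474": {"OFF": 0, "ON": 3},    # threshold 1
    "D423-CL2": {"OFF": 4, "ON": 12},    # threshold 8
    "E503-H534": {"OFF": 0, "ON": 6},
    "H534-Dloop": {"OFF": 0, "ON": 3},
    "MgATP-Q422": Q422_LEVELS,
}

#: slot capacity of each interaction station
N_SLOTS = {
    "MgATP-Q422": 20,
    "D423-K483": 6,
    "D423-R474": 6,
    "D423-CL2": 18,
    "E503-H534": 12,
    "H534-Dloop": 6,
}

STACKING_LABEL = "R474_stacking"

_CONTACT_DZ = 3.0   # slot partner z-offset realizing a contact (A)
_BROKEN_DZ = 6.0    # slot partner z-offset breaking a contact (A)
_GRID_SPACING = 6.0
_GRID_COLS = 5
_SITE_X = 90.0      # site centres at (+-_SITE_X, 0, 0)
_STATION_RADIUS = 40.0
_STACK_BASE_Z = 20.0
_TMD_Z = 30.0       # decorative TMD-residue plane


class ScheduleError(ValueError):
    """A schedule segment is inconsistent or unrealizable."""


@dataclass
class SwitchSchedule:
    """Planted per-window targets for every switch at every site.

    ``segments[(switch, site)]`` is a list of ``(start_ns, end_ns, target)``
    covering the trajectory without gaps.  The stacking switch uses the key
    ``("R474_stacking", "axis")`` with targets ``"A"``, ``"B"`` or
    ``"side"``.
    """

    segments: Mapping[tuple[str, str], list[tuple[float, float, object]]]
    noise_sd: float = 0.0
    seed: int = 0
    stacking_delta: float = 3.0   # planted |z_A - z_B| when stacked, A
    jitter_sd: float = 0.1        # water / stacking positional jitter, A

    def target_at(self, key: tuple[str, str], t_ns: float):
        segs = self.segments[key]
        for start, end, target in segs:
            if start - 1e-9 <= t_ns < end - 1e-9:
                return target
        # the final segment is closed at its end so the inclusive last
        # frame of a trajectory is covered
        last = max(segs, key=lambda s: s[1])
        if t_ns <= last[1] + 1e-9:
            return last[2]
        raise ScheduleError(
            f"schedule for {key} does not cover t = {t_ns} ns")

    def validate(self, duration_ns: float) -> None:
        for key, segs in self.segments.items():
            segs = sorted(segs)
            if not segs:
                raise ScheduleError(f"empty schedule for {key}")
            if abs(segs[0][0]) > 1e-9 or segs[-1][1] < duration_ns - 1e-9:
                raise ScheduleError(
                    f"schedule for {key} does not cover [0, {duration_ns}) ns")
            for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
                if abs(e0 - s1) > 1e-9:
                    raise ScheduleError(
                        f"schedule for {key} has a gap/overlap at {e0} ns")
            label = key[0]
            if label == STACKING_LABEL:
                for _, _, tgt in segs:
                    if tgt not in ("A", "B", "side"):
                        raise ScheduleError(
                            f"unknown stacking target {tgt!r}")
            else:
                for _, _, tgt in segs:
                    count = resolve_target(label, tgt)
                    if count > N_SLOTS[label]:
                        raise ScheduleError(
                            f"switch {label}: target {tgt!r} ({count} contacts) "
                            f"exceeds the {N_SLOTS[label]} available atom pairs")


def resolve_target(label: str, target) -> int:
    if isinstance(target, str):
        try:
            return int(BINARY_LEVELS[label][target])
        except KeyError as e:
            raise ScheduleError(
                f"switch {label}: unknown state {target!r}") from e
    count = int(target)
    if count < 0:
        raise ScheduleError(f"switch {label}: negative target {target}")
    return count


@dataclass
class ToyDimerSpec:
    """Geometry parameters of the toy homodimer."""

    n_monomers: int = 2
    n_waters: int = 60
    water_min_radius: float = 5.0
    # radius step well above the positional jitter, so the nearest-water
    # ranking is stable across frames of one trajectory
    water_radius_step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_monomers != 2:
            raise ValueError("the toy generator builds dimers (n_monomers = 2)")


@dataclass
class _SlotBlock:
    """Topology indices of the movable partner atoms of one station."""

    j_indices: np.ndarray    # one per slot, ordered
    plane_z: float           # z of the static row


@dataclass
class ToyDimer:
    """A generated symmetric dimer frame plus the bookkeeping needed to
    plant schedules on it."""

    spec: ToyDimerSpec
    frame: Frame
    motif_map: MotifMap
    slot_blocks: Mapping[tuple[str, str], _SlotBlock]   # (label, site)
    stacking_indices: Mapping[str, np.ndarray]          # monomer -> R474 terminal
    water_indices: np.ndarray
    seed: int


# station order around each site centre (60 deg apart)
_STATION_ORDER = ("MgATP-Q422", "D423-K483", "D423-R474",
                  "D423-CL2", "E503-H534", "H534-Dloop")

# (chain of group_i, residue/resname/atom-prefix of i, same for j) at site A;
# chains are monomer-relative: "self" = A, "other" = B at site A
_STATION_ATOMS = {
    #                 group_i                      group_j (movable)
    "MgATP-Q422": (("self", 901, "ATP", "P"), ("self", 422, "GLN", "Q")),
    "D423-K483":  (("self", 423, "ASP", "K"), ("other", 483, "LYS", "K")),
    "D423-R474":  (("self", 423, "ASP", "R"), ("other", 474, "ARG", "R")),
    "D423-CL2":   (("self", 423, "ASP", "L"), ("other", 260, "GLY", "L")),
    "E503-H534":  (("self", 503, "GLU", "W"), ("self", 534, "HIS", "D")),
    "H534-Dloop": (("self", 534, "HIS", "S"), ("other", 509, "ASP", "S")),
}


def _grid_xy(center: np.ndarray, n_slots: int) -> np.ndarray:
    rows = math.ceil(n_slots / _GRID_COLS)
    pts = []
    for m in range(n_slots):
        r, c = divmod(m, _GRID_COLS)
        pts.append([center[0] + (c - (_GRID_COLS - 1) / 2) * _GRID_SPACING,
                    center[1] + (r - (rows - 1) / 2) * _GRID_SPACING,
                    0.0])
    return np.array(pts)


def _mirror(xyz: np.ndarray) -> np.ndarray:
    """180 deg rotation about the z axis."""
    out = np.array(xyz, dtype=float)
    out[..., 0] *= -1
    out[..., 1] *= -1
    return out


def build_toy_dimer(spec: ToyDimerSpec = ToyDimerSpec(),
                    seed: int = 0) -> ToyDimer:
    """Build the symmetric toy dimer frame and its motif map.

    Deterministic for a given (spec, seed); the two chains are exact
    mirror images about the z axis at generation time.
    """
    mono = ("A", "B")
    site_labels = ("NBS_A", "NBS_B")
    site_centers = {"NBS_A": np.array([_SITE_X, 0.0, 0.0]),
                    "NBS_B": np.array([-_SITE_X, 0.0, 0.0])}

    sites: list[AtomSite] = []
    coords: list[np.ndarray] = []
    serial = [0]

    def add_atom(chain: str, resnum: int, resname: str, name: str,
                 xyz: np.ndarray, element: str = "C") -> int:
        serial[0] += 1
        sites.append(AtomSite(serial[0], name, element, resnum, resname, chain))
        coords.append(np.asarray(xyz, dtype=float))
        return len(sites) - 1

    slot_blocks: dict[tuple[str, str], _SlotBlock] = {}

    # --- interaction stations, mirrored across the two sites ------------
    for si, label in enumerate(_STATION_ORDER):
        n_slots = N_SLOTS[label]
        angle = math.radians(60.0 * si)
        offset = _STATION_RADIUS * np.array([math.cos(angle), math.sin(angle), 0.0])
        (ci, resi, rni, pi), (cj, resj, rnj, pj) = _STATION_ATOMS[label]
        for site_label, mono_self in zip(site_labels, mono):
            mono_other = mono[1] if mono_self == mono[0] else mono[0]
            chain_i = mono_self if ci == "self" else mono_other
            chain_j = mono_self if cj == "self" else mono_other
            center = site_centers[site_label] + (
                offset if site_label == "NBS_A" else _mirror(offset))
            grid = _grid_xy(center, n_slots)
            if site_label == "NBS_B":
                # mirror the grid layout itself so the two sites are exact images
                grid = _mirror(_grid_xy(site_centers["NBS_A"] + offset, n_slots))
            j_idx = []
            for m in range(n_slots):
                xi = grid[m].copy()
                add_atom(chain_i, resi, rni, f"{pi}I{m:02d}", xi)
                xj = grid[m].copy()
                xj[2] = _BROKEN_DZ
                j_idx.append(add_atom(chain_j, resj, rnj, f"{pj}J{m:02d}", xj))
            slot_blocks[(label, site_label)] = _SlotBlock(
                np.array(j_idx, dtype=int), plane_z=0.0)
            if label == "MgATP-Q422":
                add_atom(chain_i, 902, "MG", "MG",
                         center + np.array([0.0, 0.0, -8.0]), element="MG")

    # --- near-axis residues (per monomer, mirrored) ----------------------
    stacking_indices: dict[str, np.ndarray] = {}
    arg_names = ("CZ", "NH1", "NH2")
    his_names = ("ND1", "CE1", "NE2")
    for mono_label, sgn in zip(mono, (+1.0, -1.0)):
        base = np.array([0.0, sgn * 6.0, _STACK_BASE_Z])
        idx = [add_atom(mono_label, 474, "ARG", nm,
                        base + np.array([0.8 * k, 0.0, 0.0]), element="N" if k else "C")
               for k, nm in enumerate(arg_names)]
        stacking_indices[mono_label] = np.array(idx, dtype=int)
        h_base = np.array([0.0, sgn * 3.0, _TMD_Z])
        for k, nm in enumerate(his_names):
            add_atom(mono_label, 204, "HIS", nm,
                     h_base + np.array([0.8 * k, 0.0, 0.0]),
                     element="N" if nm.startswith("N") else "C")
        for resnum, z in ((200, _TMD_Z - 4.0), (208, _TMD_Z + 4.0)):
            for k, nm in enumerate(("OE1", "NE2")):
                add_atom(mono_label, resnum, "GLN", nm,
                         np.array([1.0 * k, sgn * 5.0, z]),
                         element="O" if nm.startswith("O") else "N")
        # remaining motif residues, static and isolated
        misc = np.array([sgn * 55.0, sgn * 55.0, 0.0])
        for k in range(2):
            add_atom(mono_label, 502, "ASP", ("OD1", "OD2")[k],
                     misc + np.array([k * 1.2, 0.0, 0.0]), element="O")
        for k in range(2):
            add_atom(mono_label, 473, "GLU", ("OE1", "OE2")[k],
                     misc + np.array([k * 1.2, 5.0, 0.0]), element="O")
        for resnum in (230, 231):
            for k in range(2):
                add_atom(mono_label, resnum, "GLY", ("N", "CA")[k],
                         misc + np.array([k * 1.2, 10.0 + (resnum - 230) * 3, 0.0]),
                         element="N" if k == 0 else "C")
        # second CL2 loop residue (static; slot atoms live on residue 260)
        for k in range(2):
            add_atom(mono_label, 261, "GLY", ("N", "CA")[k],
                     misc + np.array([k * 1.2, 16.0, 0.0]),
                     element="N" if k == 0 else "C")

    # --- waters around the site-A ligand station -------------------------
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lig_center = site_centers["NBS_A"] + _STATION_RADIUS * np.array([1.0, 0.0, 0.0])
    water_idx = []
    for w in range(spec.n_waters):
        radius = spec.water_min_radius + spec.water_radius_step * w
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        ow = lig_center + radius * v
        water_idx.append(add_atom("W", w + 1, "SOL", "OW", ow, element="O"))
        water_idx.append(add_atom("W", w + 1, "SOL", "HW1",
                                  ow + np.array([0.6, 0.0, 0.3]), element="H"))
        water_idx.append(add_atom("W", w + 1, "SOL", "HW2",
                                  ow + np.array([-0.6, 0.0, 0.3]), element="H"))

    # reorder into canonical chain-grouped form so the in-memory topology,
    # the written PDB and a re-read trajectory all share one atom order
    from .io import canonical_atom_order
    perm = canonical_atom_order(Topology(sites))
    remap = {old: new for new, old in enumerate(perm)}
    sites = [AtomSite(new + 1, sites[old].name, sites[old].element,
                      sites[old].residue_number, sites[old].residue_name,
                      sites[old].chain_id)
             for new, old in enumerate(perm)]
    coords = [coords[old] for old in perm]
    slot_blocks = {
        key: _SlotBlock(np.array([remap[int(i)] for i in blk.j_indices]),
                        blk.plane_z)
        for key, blk in slot_blocks.items()}
    stacking_indices = {
        mono: np.array([remap[int(i)] for i in idx])
        for mono, idx in stacking_indices.items()}
    water_idx = [remap[int(i)] for i in water_idx]

    topo = Topology(sites)
    frame = Frame(topo, np.array(coords), time_ps=0.0)

    def sel(chain: str, *res: int, atoms: Optional[set] = None) -> SelectionSpec:
        return SelectionSpec(chain, frozenset(res),
                             None if atoms is None else frozenset(atoms))

    motifs = {
        "Q_loop_Q": {"A": sel("A", 422), "B": sel("B", 422)},
        "Q_loop_D": {"A": sel("A", 423), "B": sel("B", 423)},
        "WalkerB_E": {"A": sel("A", 503), "B": sel("B", 503)},
        "WalkerB_D": {"A": sel("A", 502), "B": sel("B", 502)},
        "signature_K": {"A": sel("A", 483), "B": sel("B", 483)},
        "xloop_E": {"A": sel("A", 473), "B": sel("B", 473)},
        "xloop_R": {"A": sel("A", 474), "B": sel("B", 474)},
        "switch_H": {"A": sel("A", 534), "B": sel("B", 534)},
        "Dloop_D": {"A": sel("A", 509), "B": sel("B", 509)},
        "CL1": {"A": sel("A", 230, 231), "B": sel("B", 230, 231)},
        "CL2": {"A": sel("A", 260, 261), "B": sel("B", 260, 261)},
        "H204": {"A": sel("A", 204), "B": sel("B", 204)},
        "Q200": {"A": sel("A", 200), "B": sel("B", 200)},
        "Q208": {"A": sel("A", 208), "B": sel("B", 208)},
        "ligand": {"A": sel("A", 901, 902), "B": sel("B", 901, 902)},
        "Mg": {"A": sel("A", 902), "B": sel("B", 902)},
    }
    motif_map = MotifMap(motifs)
    return ToyDimer(spec, frame, motif_map, slot_blocks, stacking_indices,
                    np.array(water_idx, dtype=int), seed)


def generate_trajectory(dimer: ToyDimer, schedule: SwitchSchedule,
                        duration_ns: float, frame_interval_ps: float = 50.0,
                        run_id: str = "toy", lipid: str = "DPPC",
                        nucleotide: str = "MgATP") -> Trajectory:
    """Realize a planted switch schedule as a trajectory.

    Motif slot atoms are displaced along z so that the contact count of each
    scheduled interaction equals the segment target plus integer-rounded
    Gaussian noise (clipped to the station's slots); the stacking schedule
    is realized by +-delta/2 z-offsets of the two arginine terminal groups;
    waters are jittered.  A target exceeding a station's slot capacity
    raises :class:`ScheduleError` naming the switch.
    """
    schedule.validate(duration_ns)
    n_intervals = int(round(duration_ns * 1000.0 / frame_interval_ps))
    if abs(n_intervals * frame_interval_ps - duration_ns * 1000.0) > 1e-6:
        raise ValueError("duration must be a whole number of frame intervals")
    # inclusive endpoint: a 40-ns run sampled at 50 ps has 801 frames,
    # so snapshots at t = duration exist
    n_frames = n_intervals + 1
    times = np.arange(n_frames, dtype=float) * frame_interval_ps
    t_ns = times / 1000.0

    coords = np.broadcast_to(dimer.frame.coords,
                             (n_frames, *dimer.frame.coords.shape)).copy()

    root = np.random.SeedSequence(schedule.seed)
    keys = sorted(k for k in dimer.slot_blocks)
    children = root.spawn(len(keys) + 2)
    streams = {k: np.random.default_rng(c) for k, c in zip(keys, children)}
    stack_rng = np.random.default_rng(children[-2])
    water_rng = np.random.default_rng(children[-1])

    for key in keys:
        label, site = key
        block = dimer.slot_blocks[key]
        if key in schedule.segments:
            targets = np.array([resolve_target(label,
                                               schedule.target_at(key, t))
                                for t in t_ns], dtype=float)
        else:
            targets = np.zeros(n_frames)
        counts = targets
        if schedule.noise_sd > 0:
            counts = targets + np.round(
                streams[key].normal(0.0, schedule.noise_sd, size=n_frames))
        counts = np.clip(counts, 0, len(block.j_indices)).astype(int)
        slot_rank = np.arange(len(block.j_indices))
        dz = np.where(slot_rank[None, :] < counts[:, None],
                      _CONTACT_DZ, _BROKEN_DZ)
        coords[:, block.j_indices, 2] = block.plane_z + dz

    stack_key = (STACKING_LABEL, "axis")
    if stack_key in schedule.segments:
        half = schedule.stacking_delta / 2.0
        off = {"A": (+half, -half), "B": (-half, +half), "side": (0.0, 0.0)}
        oa = np.empty(n_frames)
        ob = np.empty(n_frames)
        for f, t in enumerate(t_ns):
            tgt = schedule.target_at(stack_key, t)
            oa[f], ob[f] = off[tgt]
        if schedule.jitter_sd > 0:
            oa = oa + stack_rng.normal(0, schedule.jitter_sd, n_frames)
            ob = ob + stack_rng.normal(0, schedule.jitter_sd, n_frames)
        ia = dimer.stacking_indices["A"]
        ib = dimer.stacking_indices["B"]
        coords[:, ia, 2] = _STACK_BASE_Z + oa[:, None]
        coords[:, ib, 2] = _STACK_BASE_Z + ob[:, None]

    if schedule.jitter_sd > 0 and len(dimer.water_indices):
        coords[:, dimer.water_indices, :] += water_rng.normal(
            0, schedule.jitter_sd, size=(n_frames, len(dimer.water_indices), 3))

    return Trajectory(dimer.frame.topology, coords, times, run_id=run_id,
                      lipid=lipid, nucleotide=nucleotide,
                      duration_ns=duration_ns)


# ---------------------------------------------------------------------------
# canned schedules

def symmetric_schedule(duration_ns: float, noise_sd: float = 0.0,
                       seed: int = 0, level: str = "ON") -> SwitchSchedule:
    """All switches in the same state at both sites: nothing breaks symmetry."""
    segs = {}
    for label in N_SLOTS:
        tgt = "MID" if label == "MgATP-Q422" else level
        for site in ("NBS_A", "NBS_B"):
            segs[(label, site)] = [(0.0, duration_ns, tgt)]
    segs[(STACKING_LABEL, "axis")] = [(0.0, duration_ns, "side")]
    return SwitchSchedule(segs, noise_sd=noise_sd, seed=seed, jitter_sd=0.0)


def all_off_schedule(duration_ns: float, seed: int = 0) -> SwitchSchedule:
    segs = {}
    for label in N_SLOTS:
        tgt = "LOW" if label == "MgATP-Q422" else "OFF"
        for site in ("NBS_A", "NBS_B"):
            segs[(label, site)] = [(0.0, duration_ns, tgt)]
    segs[(STACKING_LABEL, "axis")] = [(0.0, duration_ns, "side")]
    return SwitchSchedule(segs, noise_sd=0.0, seed=seed, jitter_sd=0.0)


def reference_schedule(duration_ns: float = 40.0, noise_sd: float = 0.5,
                       seed: int = 0) -> SwitchSchedule:
    """An asymmetric-switching scenario: the high-contact MgATP binding
    mode, the D423 charge-pair alternation, the CL2 engagement and the
    arginine stacking all settle on one site while the other site stays
    disengaged - the behaviour the analysis stack is meant to resolve."""
    d = duration_ns
    segs = {
        ("MgATP-Q422", "NBS_A"): [(0.0, d / 4, "LOW"), (d / 4, d / 2, "MID"),
                                  (d / 2, d, "HIGH")],
        ("MgATP-Q422", "NBS_B"): [(0.0, d, "LOW")],
        ("D423-K483", "NBS_A"): [(0.0, d / 2, "ON"), (d / 2, d, "OFF")],
        ("D423-K483", "NBS_B"): [(0.0, d / 2, "OFF"), (d / 2, d, "ON")],
        ("D423-R474", "NBS_A"): [(0.0, d / 8, "ON"), (d / 8, d, "OFF")],
        ("D423-R474", "NBS_B"): [(0.0, d / 4, "ON"), (d / 4, d, "OFF")],
        ("D423-CL2", "NBS_A"): [(0.0, d, "OFF")],
        ("D423-CL2", "NBS_B"): [(0.0, 3 * d / 8, "OFF"), (3 * d / 8, d, "ON")],
        ("E503-H534", "NBS_A"): [(0.0, d, "ON")],
        ("E503-H534", "NBS_B"): [(0.0, d, "ON")],
        ("H534-Dloop", "NBS_A"): [(0.0, d, "ON")],
        ("H534-Dloop", "NBS_B"): [(0.0, d, "OFF")],
        (STACKING_LABEL, "axis"): [(0.0, d / 2, "side"), (d / 2, d, "B")],
    }
    return SwitchSchedule(segs, noise_sd=noise_sd, seed=seed)


def exclusivity_schedule(alpha: float, duration_ns: float,
                         label: str = "D423-K483", seed: int = 0,
                         window_ns: float = 1.0) -> SwitchSchedule:
    """Plant an exclusivity fraction ``alpha`` for one interaction.

    Each 1-ns window is independently exclusive (one site ON, the other
    OFF, side chosen at random) with probability ``alpha``, else
    symmetric (both ON); the realized asymmetry index of the series is the
    realized fraction of exclusive windows.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_win = int(round(duration_ns / window_ns))
    seg_a, seg_b = [], []
    for k in range(n_win):
        t0, t1 = k * window_ns, (k + 1) * window_ns
        if rng.random() < alpha:
            if rng.random() < 0.5:
                seg_a.append((t0, t1, "ON"))
                seg_b.append((t0, t1, "OFF"))
            else:
                seg_a.append((t0, t1, "OFF"))
                seg_b.append((t0, t1, "ON"))
        else:
            seg_a.append((t0, t1, "ON"))
            seg_b.append((t0, t1, "ON"))
    segs = {(label, "NBS_A"): seg_a, (label, "NBS_B"): seg_b}
    return SwitchSchedule(segs, noise_sd=0.0, seed=seed, jitter_sd=0.0)
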