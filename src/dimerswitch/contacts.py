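"""Geometric primitives: contact counting, H-bond detection, axis
projections and superposition RMSD.

A *contact* between two residue groups is the number of atom pairs whose
distance is strictly below the cutoff (default 4 A), evaluated per frame.
Hydrogen bonds follow the geometric criterion of a maximum donor-acceptor
distance of 3.5 A together with a maximum acceptor-donor-hydrogen angle of
30 deg (both inclusive), the angle measured at the donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model import Frame, SelectionSpec, Trajectory, resolve_selection

#: above this many candidate atom pairs, contact counting switches from an
#: all-pairs distance matrix to a KD-tree neighbour query (identical result:
#: both apply the same strict-inequality test to the same distances)
BRUTE_FORCE_PAIR_LIMIT = 10_000


@dataclass(frozen=True)
class ContactCount:
    pair_label: str
    site_label: str
    time_ps: float
    count: int


@dataclass
class ContactSeries:
    """Per-frame contact counts of one residue pair at one site."""

    pair_label: str
    site_label: str
    times_ps: np.ndarray
    counts: np.ndarray
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times_ps.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def records(self) -> list[ContactCount]:
        return [ContactCount(self.pair_label, self.site_label, float(t), int(c))
                for t, c in zip(self.times_ps, self.counts)]


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float   # donor-acceptor, A
    angle_deg: float  # acceptor-donor-hydrogen, deg


@dataclass
class RmsdSeries:
    domain_label: str
    times_ps: np.ndarray
    rmsd: np.ndarray
    atom_subset: str = "CA"


def _as_index_array(group, frame: Frame) -> np.ndarray:
    if isinstance(group, SelectionSpec):
        return resolve_selection(group, frame)
    return np.asarray(sorted(set(int(i) for i in group)), dtype=int)


def count_contacts(frame: Frame, group_i, group_j, cutoff: float = 4.0,
                   heavy_only: bool = False) -> int:
    """Count atom pairs between two disjoint groups strictly closer than
    ``cutoff`` (A).  Symmetric in group order.

    ``heavy_only`` drops hydrogen atoms from both groups before counting.
    """
    gi = _as_index_array(group_i, frame)
    gj = _as_index_array(group_j, frame)
    if gi.size == 0 or gj.size == 0:
        raise ValueError("contact groups must be non-empty")
    if np.intersect1d(gi, gj).size:
        raise ValueError("contact groups overlap; self-pairs would inflate counts")
    if heavy_only:
        el = frame.topology.elements
        gi = gi[el[gi] != "H"]
        gj = gj[el[gj] != "H"]
        if gi.size == 0 or gj.size == 0:
            return 0
    xi, xj = frame.coords[gi], frame.coords[gj]
    if gi.size * gj.size <= BRUTE_FORCE_PAIR_LIMIT:
        return int(np.count_nonzero(cdist(xi, xj) < cutoff))
    # the ball query is inclusive at r; re-test every candidate strictly so
    # the tree path agrees bit-exactly with the all-pairs path
    pairs = cKDTree(xi).query_ball_tree(cKDTree(xj), r=cutoff)
    count = 0
    for a, neigh in enumerate(pairs):
        if not neigh:
            continue
        d = np.linalg.norm(xj[neigh] - xi[a], axis=1)
        count += int(np.count_nonzero(d < cutoff))
    return count


def contact_timeseries(traj: Trajectory, spec_i: SelectionSpec,
                       spec_j: SelectionSpec, stride_ps: float = 50.0,
                       pair_label: str = "pair", site_label: str = "site",
                       cutoff: float = 4.0) -> ContactSeries:
    """Contact counts over frames sampled on a ``stride_ps`` grid.

    A frame is kept for a stride tick when its time lies within half a
    frame interval of the tick; each tick contributes at most one frame.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    interval = traj.frame_interval_ps if traj.n_frames > 1 else stride_ps
    if stride_ps < interval - 1e-9:
        raise ValueError(
            f"stride {stride_ps} ps is smaller than the frame interval "
            f"{interval} ps")
    gi = resolve_selection(spec_i, traj.topology)
    gj = resolve_selection(spec_j, traj.topology)
    keep = _sample_frames(traj.times_ps, stride_ps, interval)
    times, counts = [], []
    for fi in keep:
        fr = traj.frame(fi)
        counts.append(count_contacts(fr, gi, gj, cutoff=cutoff))
        times.append(fr.time_ps)
    return ContactSeries(pair_label, site_label, np.array(times),
                         np.array(counts), run_id=traj.run_id)


def _sample_frames(times_ps: np.ndarray, stride_ps: float,
                   interval_ps: float) -> list[int]:
    keep = []
    n_ticks = int(np.floor(times_ps[-1] / stride_ps + 0.5)) + 1
    for k in range(n_ticks):
        tick = k * stride_ps
        fi = int(np.argmin(np.abs(times_ps - tick)))
        if abs(times_ps[fi] - tick) <= interval_ps / 2 + 1e-9:
            if not keep or keep[-1] != fi:
                keep.append(fi)
    return keep


def detect_hbonds(frame: Frame, donors: Sequence[tuple[int, int]],
                  acceptors, max_da: float = 3.5,
                  max_angle_deg: float = 30.0) -> list[HBond]:
    """All (donor, hydrogen, acceptor) triples satisfying the geometric
    H-bond criterion: d(D,A) <= ``max_da`` and angle(A-D-H) <= ``max_angle_deg``,
    the angle at the donor between the D->A and D->H vectors.
    """
    acc = _as_index_array(acceptors, frame)
    n = len(frame.topology)
    out: list[HBond] = []
    for d_idx, h_idx in donors:
        if not (0 <= h_idx < n):
            raise IndexError(
                f"hydrogen index {h_idx} for donor {d_idx} is not in the frame")
        if not (0 <= d_idx < n):
            raise IndexError(f"donor index {d_idx} is not in the frame")
        D = frame.coords[d_idx]
        H = frame.coords[h_idx]
        dh = H - D
        if np.linalg.norm(dh) == 0:
            raise ValueError(
                f"donor {d_idx} and its hydrogen {h_idx} coincide")
        for a_idx in acc:
            if a_idx == d_idx or a_idx == h_idx:
                continue
            A = frame.coords[a_idx]
            da = A - D
            dist = float(np.linalg.norm(da))
            if dist == 0 or dist > max_da:
                continue
            cosang = float(np.dot(da, dh) / (dist * np.linalg.norm(dh)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang <= max_angle_deg:
                out.append(HBond(int(d_idx), int(h_idx), int(a_idx), dist, ang))
    return out


#: side-chain terminal atom groups used for axis projections; selections with
#: residues absent from this table fall back to all selected atoms
TERMINAL_ATOMS = {
    "ARG": {"CZ", "NH1", "NH2"},
    "HIS": {"ND1", "CE1", "NE2"},
    "LYS": {"NZ"},
    "GLN": {"OE1", "NE2"},
    "GLU": {"OE1", "OE2"},
    "ASP": {"OD1", "OD2"},
}


def z_projection(traj: Trajectory, spec: SelectionSpec,
                 axis: Optional[np.ndarray] = None,
                 mode: str = "terminal") -> tuple[np.ndarray, np.ndarray]:
    """Per-frame projection onto ``axis`` of the geometric centre of the
    selection's side-chain terminal atoms (``mode='terminal'``, default) or
    of all selected atoms (``mode='all'``).

    Returns ``(times_ps, projections)``.
    """
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("projection axis must have non-zero norm")
    if abs(norm - 1.0) > 1e-8:
        raise ValueError("projection axis must be a unit vector")
    idx = resolve_selection(spec, traj.topology)
    if mode == "terminal":
        sub = [i for i in idx
               if frame_site_is_terminal(traj, int(i))]
        if sub:
            idx = np.array(sub, dtype=int)
    elif mode != "all":
        raise ValueError(f"unknown projection mode {mode!r}")
    centers = traj.coords[:, idx, :].mean(axis=1)
    return traj.times_ps.copy(), centers @ axis


def frame_site_is_terminal(traj: Trajectory, i: int) -> bool:
    s = traj.topology[i]
    names = TERMINAL_ATOMS.get(s.residue_name)
    return names is not None and s.name in names


def rmsd_vs_start(traj: Trajectory, spec: SelectionSpec,
                  atom_names: frozenset[str] | set[str] = frozenset({"CA"}),
                  fit_spec: Optional[SelectionSpec] = None,
                  domain_label: str = "domain") -> RmsdSeries:
    """Per-frame RMSD to frame 0 after least-squares rigid superposition.

    The measured set is the C-alpha subset of ``spec`` (configurable via
    ``atom_names``).  By default the superposition is fitted on the measured
    set itself; pass ``fit_spec`` to fit on a different selection (e.g. the
    whole protein) before measuring per-domain deviations.
    """
    def _ca_idx(s: SelectionSpec) -> np.ndarray:
        idx = resolve_selection(s, traj.topology)
        sub = [i for i in idx if traj.topology[int(i)].name in atom_names]
        if len(sub) < 3:
            raise ValueError(
                f"selection yields {len(sub)} {sorted(atom_names)} atoms; "
                "need at least 3 for superposition")
        return np.array(sub, dtype=int)

    meas = _ca_idx(spec)
    fit = meas if fit_spec is None else _ca_idx(fit_spec)
    ref_fit = traj.coords[0, fit, :]
    ref_meas = traj.coords[0, meas, :]
    centered = ref_fit - ref_fit.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("reference atoms are collinear; superposition is degenerate")
    rmsds = []
    for f in range(traj.n_frames):
        if f == 0:
            # the reference superposes onto itself exactly
            rmsds.append(0.0)
            continue
        mob_fit = traj.coords[f, fit, :]
        mob_meas = traj.coords[f, meas, :]
        rot, _ = Rotation.align_vectors(centered, mob_fit - mob_fit.mean(axis=0))
        moved = rot.apply(mob_meas - mob_fit.mean(axis=0)) + ref_fit.mean(axis=0)
        rmsds.append(float(np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))))
    return RmsdSeries(domain_label, traj.times_ps.copy(), np.array(rmsds))
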