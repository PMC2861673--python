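"""In-memory model of structures, trajectories and residue selections.

The containers follow the usual MD-analysis split between a static
*topology* (atom identities, shared by all frames of one trajectory) and
per-frame coordinate arrays, so that frame-wise geometry reduces to numpy
operations on ``(n_atoms, 3)`` arrays.  Coordinates are stored in Angstrom
and frame times in picoseconds throughout; nanoseconds are accepted at the
public interfaces and converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

#: residue names recognised as water (common force-field dialects)
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT"})

LIPIDS = ("DPPC", "POPC", "none")
NUCLEOTIDES = ("MgATP", "ADP")


class SelectionError(KeyError):
    """A residue/atom selection resolved to no atoms."""


class TrajectoryError(ValueError):
    """A structural-consistency invariant of a trajectory was violated."""


@dataclass(frozen=True)
class AtomSite:
    """Identity of one atom, without coordinates (shared across frames)."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus Cartesian coordinates (A)."""

    site: AtomSite
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.site.serial}")

    # convenience pass-throughs
    @property
    def serial(self) -> int:
        return self.site.serial

    @property
    def name(self) -> str:
        return self.site.name

    @property
    def element(self) -> str:
        return self.site.element

    @property
    def residue_number(self) -> int:
        return self.site.residue_number

    @property
    def residue_name(self) -> str:
        return self.site.residue_name

    @property
    def chain_id(self) -> str:
        return self.site.chain_id

    @property
    def is_water(self) -> bool:
        return self.site.is_water


class Topology:
    """Ordered, immutable collection of :class:`AtomSite`."""

    def __init__(self, sites: Iterable[AtomSite]):
        self.sites: tuple[AtomSite, ...] = tuple(sites)
        serials = [s.serial for s in self.sites]
        if len(set(serials)) != len(serials):
            raise TrajectoryError("duplicate atom serials in topology")
        self._elements = np.array([s.element for s in self.sites])
        self._water_mask = np.array([s.is_water for s in self.sites], dtype=bool)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[AtomSite]:
        return iter(self.sites)

    def __getitem__(self, i: int) -> AtomSite:
        return self.sites[i]

    @property
    def water_mask(self) -> np.ndarray:
        return self._water_mask

    @property
    def elements(self) -> np.ndarray:
        return self._elements

    def identity_key(self) -> tuple:
        """Hashable atom-identity sequence, used to verify frame compatibility."""
        return tuple((s.serial, s.name, s.residue_number, s.residue_name, s.chain_id)
                     for s in self.sites)


class Frame:
    """One snapshot: a topology plus coordinates, at a time in ps."""

    def __init__(self, topology: Topology, coords: np.ndarray, time_ps: float = 0.0):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(topology), 3):
            raise TrajectoryError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(topology)} topology atoms")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("non-finite coordinates in frame")
        if time_ps < 0:
            raise TrajectoryError(f"negative frame time {time_ps} ps")
        self.topology = topology
        self.coords = coords
        self.time_ps = float(time_ps)

    def __len__(self) -> int:
        return len(self.topology)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(site, tuple(xyz))
                for site, xyz in zip(self.topology.sites, self.coords)]

    @classmethod
    def from_records(cls, records: Sequence[AtomRecord], time_ps: float = 0.0) -> "Frame":
        topo = Topology(r.site for r in records)
        coords = np.array([r.xyz for r in records], dtype=float)
        return cls(topo, coords, time_ps)


class Trajectory:
    """An ordered series of frames over one shared topology, plus run metadata."""

    def __init__(self, topology: Topology, coords: np.ndarray, times_ps: np.ndarray,
                 run_id: str = "run", lipid: str = "none", nucleotide: str = "MgATP",
                 duration_ns: Optional[float] = None):
        coords = np.asarray(coords, dtype=float)
        times_ps = np.asarray(times_ps, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(topology), 3):
            raise TrajectoryError(f"bad trajectory coordinate shape {coords.shape}")
        if len(times_ps) != coords.shape[0]:
            raise TrajectoryError("times and coordinate frames differ in length")
        if len(times_ps) and np.any(np.diff(times_ps) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if lipid not in LIPIDS:
            raise ValueError(f"unknown lipid {lipid!r}; expected one of {LIPIDS}")
        if nucleotide not in NUCLEOTIDES:
            raise ValueError(
                f"unknown nucleotide {nucleotide!r}; expected one of {NUCLEOTIDES}")
        if duration_ns is None:
            duration_ns = float(times_ps[-1]) / 1000.0 if len(times_ps) else 0.0
        if len(times_ps) and duration_ns * 1000.0 < times_ps[-1] - 1e-6:
            raise TrajectoryError(
                f"duration {duration_ns} ns is shorter than last frame time "
                f"{times_ps[-1]} ps")
        self.topology = topology
        self.coords = coords
        self.times_ps = times_ps
        self.run_id = run_id
        self.lipid = lipid
        self.nucleotide = nucleotide
        self.duration_ns = float(duration_ns)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], self.times_ps[i])

    @property
    def frames(self) -> list[Frame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @property
    def frame_interval_ps(self) -> float:
        if self.n_frames < 2:
            raise TrajectoryError("frame interval undefined for <2 frames")
        return float(np.median(np.diff(self.times_ps)))

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], **meta) -> "Trajectory":
        if not frames:
            raise TrajectoryError("cannot build a trajectory from zero frames")
        topo = frames[0].topology
        key = topo.identity_key()
        for i, fr in enumerate(frames[1:], start=2):
            if len(fr.topology) != len(topo):
                raise TrajectoryError(
                    f"frame {i} has {len(fr.topology)} atoms, expected {len(topo)}")
            if fr.topology.identity_key() != key:
                raise TrajectoryError(f"frame {i} atom identities differ from frame 1")
        coords = np.stack([fr.coords for fr in frames])
        times = np.array([fr.time_ps for fr in frames])
        return cls(topo, coords, times, **meta)


@dataclass(frozen=True)
class SelectionSpec:
    """A chain + residue-number (+ optional atom-name) selection."""

    chain_id: str
    residue_numbers: frozenset[int]
    atom_names: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_numbers", frozenset(self.residue_numbers))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if not self.residue_numbers:
            raise ValueError("SelectionSpec requires a non-empty residue set")

    def describe(self) -> str:
        res = ",".join(str(r) for r in sorted(self.residue_numbers))
        names = "" if self.atom_names is None else f" atoms {sorted(self.atom_names)}"
        return f"chain {self.chain_id} residues {res}{names}"


def resolve_selection(spec: SelectionSpec, frame: Frame | Topology) -> np.ndarray:
    """Resolve a selection to topology-ordered atom indices.

    Deterministic and order-preserving; an empty resolution raises
    :class:`SelectionError` echoing the spec.
    """
    topo = frame.topology if isinstance(frame, Frame) else frame
    idx = [i for i, s in enumerate(topo.sites)
           if s.chain_id == spec.chain_id
           and s.residue_number in spec.residue_numbers
           and (spec.atom_names is None or s.name in spec.atom_names)]
    if not idx:
        raise SelectionError(f"selection matched no atoms: {spec.describe()}")
    return np.array(idx, dtype=int)


MOTIF_LABELS = (
    "Q_loop_Q", "Q_loop_D", "WalkerB_E", "WalkerB_D", "signature_K",
    "xloop_E", "xloop_R", "switch_H", "Dloop_D", "CL1", "CL2",
    "H204", "Q200", "Q208", "ligand", "Mg",
)


@dataclass
class MotifMap:
    """Functional-motif selections per monomer, plus the symmetry axis.

    ``motifs[label][monomer]`` is the :class:`SelectionSpec` of that motif as
    encoded by that monomer's own chain; composite-site pairing (signature and
    D-loop contributed by the opposite monomer) is applied downstream when
    interactions are assembled.
    """

    motifs: Mapping[str, Mapping[str, SelectionSpec]]
    symmetry_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    tmd_direction: float = +1.0

    def __post_init__(self) -> None:
        self.symmetry_axis = np.asarray(self.symmetry_axis, dtype=float)
        n = np.linalg.norm(self.symmetry_axis)
        if not np.isfinite(n) or n == 0:
            raise ValueError("symmetry axis must have non-zero norm")
        self.symmetry_axis = self.symmetry_axis / n
        if len(self.monomers) < 2:
            raise ValueError("MotifMap requires at least two monomers")
        for label in MOTIF_LABELS:
            if label not in self.motifs:
                raise ValueError(f"MotifMap is missing motif {label!r}")
            for mono in self.monomers:
                if mono not in self.motifs[label]:
                    raise ValueError(f"motif {label!r} missing for monomer {mono!r}")

    @property
    def monomers(self) -> tuple[str, ...]:
        first = next(iter(self.motifs.values()))
        return tuple(first.keys())

    def spec(self, label: str, monomer: str) -> SelectionSpec:
        return self.motifs[label][monomer]

    def relabeled(self) -> "MotifMap":
        """Swap the two monomer labels (A<->B); used by symmetry tests."""
        a, b = self.monomers[:2]
        swapped = {
            label: {a: per[b], b: per[a],
                    **{m: per[m] for m in per if m not in (a, b)}}
            for label, per in self.motifs.items()
        }
        return MotifMap(swapped, self.symmetry_axis.copy(), self.tmd_direction)


@dataclass(frozen=True)
class ManifestEntry:
    run_id: str
    lipid: str
    nucleotide: str
    duration_ns: float
    path: str
    frame_interval_ps: float = 50.0

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ValueError(f"run {self.run_id}: duration must be positive")
        if self.lipid not in LIPIDS:
            raise ValueError(f"run {self.run_id}: unknown lipid {self.lipid!r}")
        if self.nucleotide not in NUCLEOTIDES:
            raise ValueError(
                f"run {self.run_id}: unknown nucleotide {self.nucleotide!r}")


@dataclass
class RunManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.run_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("run_ids in manifest must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def group(self, nucleotide: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.nucleotide == nucleotide]
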