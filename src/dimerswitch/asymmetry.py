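"""Paired-site contact analysis: aligned series for the two composite
nucleotide-binding sites, 2D scatter densities with contour lines, and a
normalized asymmetry index.

The two NBSs of a homodimeric ABC exporter are domain-swapped composites:
the Walker motifs and Q-loop of one monomer pair with the signature-adjacent
lysine and D-loop of the other.  Symmetry breaking shows up as off-diagonal
mass when the per-frame contact counts of the two sites are plotted against
each other; the asymmetry index below condenses that into a number in
[0, 1] (0 = identical series, 1 = strictly mutually exclusive contacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

from .contacts import ContactSeries, contact_timeseries, count_contacts
from .model import Frame, MotifMap, SelectionSpec, Trajectory, resolve_selection

#: contour levels as descending fractions of the density maximum
CONTOUR_FRACTIONS = (0.8, 0.6, 0.4, 0.2, 0.1)

#: the interactions tracked at each composite site; the second motif is taken
#: from the opposite monomer where the composite-site rule demands it
INTERACTIONS = (
    # label,            motif_i,     motif_j,       j from opposite monomer
    ("MgATP-Q422",      "ligand",    "Q_loop_Q",    False),
    ("E503-H534",       "WalkerB_E", "switch_H",    False),
    ("H534-Dloop",      "switch_H",  "Dloop_D",     True),
    ("D423-K483",       "Q_loop_D",  "signature_K", True),
    ("D423-R474",       "Q_loop_D",  "xloop_R",     True),
    ("D423-CL2",        "Q_loop_D",  "CL2",         True),
)


@dataclass
class SitePairing:
    """For each interaction label, the (spec_i, spec_j) realization at the
    two composite sites, keyed by site label."""

    sites: tuple[str, str]
    interactions: Mapping[str, Mapping[str, tuple[SelectionSpec, SelectionSpec]]]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.interactions.keys())

    def realization(self, label: str, site: str) -> tuple[SelectionSpec, SelectionSpec]:
        return self.interactions[label][site]


def default_site_pairing(motif_map: MotifMap) -> SitePairing:
    """Assemble the standard interaction set from a motif map, applying the
    composite-site rule (signature/D-loop/CL2 partner from the opposite
    monomer)."""
    a, b = motif_map.monomers[:2]
    opposite = {a: b, b: a}
    sites = (f"NBS_{a}", f"NBS_{b}")
    interactions: dict[str, dict[str, tuple[SelectionSpec, SelectionSpec]]] = {}
    for label, mi, mj, swapped in INTERACTIONS:
        per_site = {}
        for mono, site in zip((a, b), sites):
            partner = opposite[mono] if swapped else mono
            per_site[site] = (motif_map.spec(mi, mono), motif_map.spec(mj, partner))
        interactions[label] = per_site
    return SitePairing(sites, interactions)


@dataclass
class PairedSeries:
    label: str
    times_ps: np.ndarray
    counts_A: np.ndarray
    counts_B: np.ndarray
    sites: tuple[str, str] = ("NBS_A", "NBS_B")
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.counts_A = np.asarray(self.counts_A, dtype=int)
        self.counts_B = np.asarray(self.counts_B, dtype=int)
        if not (len(self.times_ps) == len(self.counts_A) == len(self.counts_B)):
            raise ValueError("paired series must be frame-aligned")
        if np.any(self.counts_A < 0) or np.any(self.counts_B < 0):
            raise ValueError("contact counts must be non-negative")

    def __len__(self) -> int:
        return len(self.times_ps)


def build_paired_series(traj: Trajectory, pairing: SitePairing, label: str,
                        stride_ps: float = 50.0, cutoff: float = 4.0) -> PairedSeries:
    """Frame-aligned contact counts of one interaction at both sites."""
    site_a, site_b = pairing.sites
    series = {}
    for site in (site_a, site_b):
        spec_i, spec_j = pairing.realization(label, site)
        series[site] = contact_timeseries(traj, spec_i, spec_j, stride_ps,
                                          pair_label=label, site_label=site,
                                          cutoff=cutoff)
    sa, sb = series[site_a], series[site_b]
    if not np.array_equal(sa.times_ps, sb.times_ps):
        raise ValueError("site series sampled on different time grids")
    return PairedSeries(label, sa.times_ps, sa.counts, sb.counts,
                        sites=(site_a, site_b), run_id=traj.run_id)


@dataclass
class ScatterDensity:
    label: str
    bin_values: np.ndarray          # integer contact counts along each axis
    histogram: np.ndarray           # raw 2D counts, A along axis 0
    density: np.ndarray             # smoothed, normalized to sum 1
    levels: np.ndarray              # absolute density levels, descending
    contours: dict[float, list[np.ndarray]]  # level -> polylines in count units
    reference_point: Optional[tuple[int, int]] = None

    @property
    def n_frames(self) -> int:
        return int(self.histogram.sum())


def reference_point(frame: Frame, pairing: SitePairing,
                    label: str, cutoff: float = 4.0) -> tuple[int, int]:
    """Contact counts of one interaction at both sites in a single reference
    frame (e.g. a crystal structure)."""
    out = []
    for site in pairing.sites:
        spec_i, spec_j = pairing.realization(label, site)
        out.append(count_contacts(frame, resolve_selection(spec_i, frame),
                                  resolve_selection(spec_j, frame), cutoff=cutoff))
    return tuple(out)  # type: ignore[return-value]


def scatter_density(ps: PairedSeries, smoothing_bins: float = 1.0,
                    n_contours: int = 5,
                    reference: Optional[Frame] = None,
                    pairing: Optional[SitePairing] = None,
                    reference_counts: Optional[tuple[int, int]] = None,
                    ) -> ScatterDensity:
    """Integer-binned 2D histogram of (count_A, count_B) with a Gaussian-
    smoothed density and contour polylines at descending fractions of the
    density maximum."""
    if len(ps) == 0:
        raise ValueError("cannot build a scatter density from an empty series")
    if reference is not None:
        if pairing is None:
            raise ValueError("a reference frame requires the site pairing")
        reference_counts = reference_point(reference, pairing, ps.label)
    m = int(max(ps.counts_A.max(), ps.counts_B.max(),
                *(reference_counts or (0, 0)))) + 1
    edges = np.arange(m + 2) - 0.5
    hist, _, _ = np.histogram2d(ps.counts_A, ps.counts_B, bins=(edges, edges))
    density = gaussian_filter(hist, sigma=smoothing_bins, mode="constant")
    total = density.sum()
    if total > 0:
        density = density / total
    fractions = CONTOUR_FRACTIONS[:n_contours]
    levels = np.array([f * density.max() for f in fractions])
    contours: dict[float, list[np.ndarray]] = {}
    for lev in levels:
        polylines = measure.find_contours(density, lev) if lev > 0 else []
        contours[float(lev)] = [pl for pl in polylines]
    return ScatterDensity(ps.label, np.arange(m + 1), hist.astype(int), density,
                          levels, contours, reference_counts)


@dataclass(frozen=True)
class AsymmetryIndex:
    label: str
    value: float
    n_informative_frames: int
    run_id: str = "run"


def asymmetry_index(ps: PairedSeries) -> AsymmetryIndex:
    """Mean of |a - b| / (a + b) over frames with a + b > 0.

    Frames where both sites have zero contacts carry no information about
    asymmetry and are excluded; an all-zero series yields 0 with
    ``n_informative_frames == 0``.
    """
    a = ps.counts_A.astype(float)
    b = ps.counts_B.astype(float)
    informative = (a + b) > 0
    n = int(informative.sum())
    if n == 0:
        return AsymmetryIndex(ps.label, 0.0, 0, ps.run_id)
    val = float(np.mean(np.abs(a[informative] - b[informative])
                        / (a[informative] + b[informative])))
    return AsymmetryIndex(ps.label, val, n, ps.run_id)


def pooled_asymmetry_index(series: list[PairedSeries], label: str,
                           run_id: str = "pooled") -> AsymmetryIndex:
    """Asymmetry index over the concatenation of several runs' series."""
    if not series:
        raise ValueError("no series to pool")
    a = np.concatenate([ps.counts_A for ps in series])
    b = np.concatenate([ps.counts_B for ps in series])
    t = np.arange(len(a), dtype=float)
    pooled = PairedSeries(label, t, a, b, sites=series[0].sites, run_id=run_id)
    return asymmetry_index(pooled)


def pooled_paired_series(series: list[PairedSeries], label: str,
                         run_id: str = "pooled") -> PairedSeries:
    if not series:
        raise ValueError("no series to pool")
    a = np.concatenate([ps.counts_A for ps in series])
    b = np.concatenate([ps.counts_B for ps in series])
    t = np.arange(len(a), dtype=float)
    return PairedSeries(label, t, a, b, sites=series[0].sites, run_id=run_id)


def classify_inter_intra(pairing: SitePairing) -> dict[str, str]:
    """Label each interaction ``inter_monomer`` iff its two selections lie
    on different chains (consistently at both sites)."""
    out = {}
    for label in pairing.labels():
        kinds = set()
        for site in pairing.sites:
            spec_i, spec_j = pairing.realization(label, site)
            kinds.add("inter_monomer" if spec_i.chain_id != spec_j.chain_id
                      else "intra_monomer")
        if len(kinds) != 1:
            raise ValueError(
                f"interaction {label!r} classifies differently at the two sites")
        out[label] = kinds.pop()
    return out
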