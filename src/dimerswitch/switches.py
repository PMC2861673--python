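"""Windowed discretization of interactions into molecular-switch states.

Contact series are averaged over 1-ns windows and mapped to discrete
states: the MgATP-sensing glutamine (Q422) to three levels (below 5 mean
contacts, between 5 and 14, above 14), the aspartate charge pairs to
binary on/off levels (thresholds 1 and 8), and the x-loop arginine pair to
a stacking state along the symmetry axis (stacked when the two z-positions
differ by more than 2 A).  Means exactly at a threshold are assigned to
the middle level (three-level switches) or to the on state (binary
switches); the stacking comparison is strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .asymmetry import SitePairing, build_paired_series
from .contacts import ContactSeries, z_projection
from .model import MotifMap, Trajectory

Q422_LOW_THRESHOLD = 5.0
Q422_HIGH_THRESHOLD = 14.0
BINARY_THRESHOLDS = {"D423-R474": 1.0, "D423-K483": 1.0, "D423-CL2": 8.0}
STACKING_DELTA = 2.0
WINDOW_NS = 1.0


@dataclass(frozen=True)
class WindowMean:
    window_index: int
    start_ns: float
    end_ns: float
    mean: float
    n_frames: int
    partial: bool = False


@dataclass(frozen=True)
class SwitchState:
    switch: str
    window_index: int
    state: str


@dataclass(frozen=True)
class StackingState:
    window_index: int
    state: str        # A_closer_to_TMDs | B_closer_to_TMDs | side_by_side
    delta_z: float    # z_A - z_B, A


def window_means(times_ps: np.ndarray, values: np.ndarray,
                 window_ns: float = WINDOW_NS) -> list[WindowMean]:
    """Arithmetic means over half-open windows [k*w, (k+1)*w) ns.

    Windows tile the sampled time range; a trailing window that the
    trajectory does not fill completely is kept and flagged ``partial``.
    """
    times_ps = np.asarray(times_ps, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times_ps) == 0:
        raise ValueError("empty series")
    w_ps = window_ns * 1000.0
    interval = float(np.median(np.diff(times_ps))) if len(times_ps) > 1 else w_ps
    if w_ps < interval - 1e-9:
        raise ValueError("window must be at least one frame interval")
    n_windows = int(np.floor(times_ps[-1] / w_ps)) + 1
    frames_per_full = int(round(w_ps / interval))
    out = []
    for k in range(n_windows):
        mask = (times_ps >= k * w_ps - 1e-9) & (times_ps < (k + 1) * w_ps - 1e-9)
        n = int(mask.sum())
        if n == 0:
            continue
        partial = (k == n_windows - 1) and (n < frames_per_full)
        out.append(WindowMean(k, k * window_ns, (k + 1) * window_ns,
                              float(values[mask].mean()), n, partial))
    return out


def window_means_series(series: ContactSeries,
                        window_ns: float = WINDOW_NS) -> list[WindowMean]:
    return window_means(series.times_ps, series.counts, window_ns)


def discretize_q422(mean: float, low: float = Q422_LOW_THRESHOLD,
                    high: float = Q422_HIGH_THRESHOLD) -> str:
    """Three-level state of the Q422-MgATP interaction from a window mean."""
    if mean < 0:
        raise ValueError(f"negative mean contact count {mean}")
    if mean < low:
        return "LOW"
    if mean > high:
        return "HIGH"
    return "MID"


def discretize_binary(mean: float, threshold: float) -> str:
    """Two-level state; a mean exactly at the threshold is ON."""
    if mean < 0:
        raise ValueError(f"negative mean contact count {mean}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "ON" if mean >= threshold else "OFF"


def stacking_state(z_a: float, z_b: float, window_index: int = 0,
                   delta: float = STACKING_DELTA,
                   tmd_direction: float = +1.0) -> StackingState:
    """Which monomer's residue sits closer to the TMDs along the axis.

    Stacked only when |z_A - z_B| strictly exceeds ``delta`` (2 A); the
    monomer whose z lies further toward ``tmd_direction`` is the closer one.
    """
    if not (np.isfinite(z_a) and np.isfinite(z_b)):
        raise ValueError("z positions must be finite")
    dz = float(z_a - z_b)
    if abs(dz) > delta:
        state = ("A_closer_to_TMDs" if dz * tmd_direction > 0
                 else "B_closer_to_TMDs")
    else:
        state = "side_by_side"
    return StackingState(window_index, state, dz)


@dataclass
class SwitchTimeline:
    """Per-window discrete states of every tracked switch, on a shared grid."""

    windows: list[WindowMean]                      # grid (from one reference switch)
    states: Mapping[tuple[str, str], list[SwitchState]]   # (switch, site) -> states
    stacking: list[StackingState]
    run_id: str = "run"

    def state_sequence(self, switch: str, site: str) -> list[str]:
        return [s.state for s in self.states[(switch, site)]]

    def stacking_sequence(self) -> list[str]:
        return [s.state for s in self.stacking]


def build_timeline(traj: Trajectory, pairing: SitePairing, motif_map: MotifMap,
                   stride_ps: float = 50.0, window_ns: float = WINDOW_NS,
                   cutoff: float = 4.0,
                   drop_partial: bool = False) -> SwitchTimeline:
    """Assemble the full switch timeline of one run.

    Per 1-ns window and per site: the three-level Q422-MgATP state, the
    binary D423-R474 / D423-K483 / D423-CL2 states; plus the R474 stacking
    state from the window-mean axis positions of the two monomers' x-loop
    arginines.
    """
    site_a, site_b = pairing.sites
    states: dict[tuple[str, str], list[SwitchState]] = {}
    grid: Optional[list[WindowMean]] = None

    def _per_window(label: str):
        nonlocal grid
        ps = build_paired_series(traj, pairing, label, stride_ps, cutoff=cutoff)
        wm_a = window_means(ps.times_ps, ps.counts_A, window_ns)
        wm_b = window_means(ps.times_ps, ps.counts_B, window_ns)
        if drop_partial:
            wm_a = [w for w in wm_a if not w.partial]
            wm_b = [w for w in wm_b if not w.partial]
        if grid is None:
            grid = wm_a
        return wm_a, wm_b

    wm_a, wm_b = _per_window("MgATP-Q422")
    states[("MgATP-Q422", site_a)] = [
        SwitchState("MgATP-Q422", w.window_index, discretize_q422(w.mean))
        for w in wm_a]
    states[("MgATP-Q422", site_b)] = [
        SwitchState("MgATP-Q422", w.window_index, discretize_q422(w.mean))
        for w in wm_b]

    for label, thr in BINARY_THRESHOLDS.items():
        wa, wb = _per_window(label)
        states[(label, site_a)] = [
            SwitchState(label, w.window_index, discretize_binary(w.mean, thr))
            for w in wa]
        states[(label, site_b)] = [
            SwitchState(label, w.window_index, discretize_binary(w.mean, thr))
            for w in wb]

    # stacking of the x-loop arginine pair along the symmetry axis
    mono_a, mono_b = motif_map.monomers[:2]
    axis = motif_map.symmetry_axis
    t, z_a = z_projection(traj, motif_map.spec("xloop_R", mono_a), axis)
    _, z_b = z_projection(traj, motif_map.spec("xloop_R", mono_b), axis)
    wz_a = window_means(t, z_a, window_ns)
    wz_b = window_means(t, z_b, window_ns)
    if drop_partial:
        wz_a = [w for w in wz_a if not w.partial]
        wz_b = [w for w in wz_b if not w.partial]
    stacking = [stacking_state(wa.mean, wb.mean, wa.window_index,
                               tmd_direction=motif_map.tmd_direction)
                for wa, wb in zip(wz_a, wz_b)]
    return SwitchTimeline(grid or [], states, stacking, run_id=traj.run_id)
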