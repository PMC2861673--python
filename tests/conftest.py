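"""Shared fixtures: toy dimers, planted trajectories, tiny hand-built frames."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dimerswitch import (Frame, SelectionSpec, Topology, build_toy_dimer,
                         default_site_pairing, generate_trajectory,
                         symmetric_schedule)
from dimerswitch.model import AtomSite
from dimerswitch.synthetic import ToyDimerSpec, reference_schedule


@pytest.fixture(scope="session")
def dimer():
    return build_toy_dimer(ToyDimerSpec(), seed=11)


@pytest.fixture(scope="session")
def pairing(dimer):
    return default_site_pairing(dimer.motif_map)


@pytest.fixture(scope="session")
def symmetric_traj(dimer):
    """4-ns perfectly symmetric trajectory (no noise, no jitter)."""
    return generate_trajectory(dimer, symmetric_schedule(4.0), 4.0,
                               run_id="sym")


@pytest.fixture(scope="session")
def asymmetric_traj(dimer):
    """8-ns noiseless trajectory with the reference switching scenario."""
    sched = reference_schedule(8.0, noise_sd=0.0, seed=7)
    sched.jitter_sd = 0.0
    return generate_trajectory(dimer, sched, 8.0, run_id="asym")


def make_frame(positions, names=None, resnums=None, chain="A",
               resname="ALA", elements=None, time_ps=0.0):
    """Small hand-built frame: one atom per row of ``positions``."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    names = names or [f"X{i}" for i in range(n)]
    resnums = resnums or list(range(1, n + 1))
    elements = elements or ["C"] * n
    chains = [chain] * n if isinstance(chain, str) else chain
    resnames = [resname] * n if isinstance(resname, str) else resname
    topo = Topology([AtomSite(i + 1, names[i], elements[i], resnums[i],
                              resnames[i], chains[i]) for i in range(n)])
    return Frame(topo, positions, time_ps)


@pytest.fixture
def two_atom_frame_factory():
    def _make(distance):
        return make_frame([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return _make
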