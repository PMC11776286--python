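"""Shared fixtures: desk-scale contraction runs reused across test modules.

The contraction runs emulate the study conditions at desk scale: the
published pattern geometries (500 μm pairs, 500/1000 μm double pairs,
600 μm hexagons), 200 μm cluster wells contracting 5% per increment for 25
increments, on a 60×60-unit anchored fiber network. Each configuration is
replicated over 5 independent network/noise seeds.
"""

import dataclasses

import numpy as np
import pytest

from fibremesh.dynamics import ContractionSchedule, LangevinParams, RemodelRule, run
from fibremesh.geometry import PatternSpec, make_layout, pair_graph, two_pairs
from fibremesh.metrics import bundle_scores
from fibremesh.netgen import NetworkSpec, build_network, choose_scale, embed_clusters

#: desk-scale schedule: the paper's 5%-per-increment rate with shortened
#: relaxation blocks (quasi-static at the jitted integrator's timestep)
DESK_SCHEDULE = ContractionSchedule(steps_per_increment=2500, n_increments=25)
DESK_RULE = RemodelRule(check_interval=250)
DESK_TIMESTEP = 0.2
N_REPLICATES = 5


def contraction_run(layout, seed):
    """One full desk-scale contraction run; returns (network, trajectory)."""
    spec = dataclasses.replace(
        NetworkSpec(), rng_seed=seed, um_per_unit=choose_scale(layout)
    )
    net = build_network(spec)
    emb = embed_clusters(net, layout)
    traj = run(
        emb,
        schedule=DESK_SCHEDULE,
        rule=DESK_RULE,
        params=LangevinParams(rng_seed=seed + 100, timestep=DESK_TIMESTEP),
    )
    return emb, traj


def score_frames(emb, traj, layout):
    """Bundle-score tables at t=0 and the final frame (contracted radius)."""
    graph = pair_graph(layout)
    s0 = bundle_scores(traj.initial["positions"], emb, graph)
    s1 = bundle_scores(
        traj.final["positions"], emb, graph, radius=float(traj.final["radii"][0])
    )
    return s0, s1


def _replicates(layout):
    out = []
    for seed in range(1, N_REPLICATES + 1):
        emb, traj = contraction_run(layout, seed)
        out.append((emb, traj) + score_frames(emb, traj, layout))
    return out


@pytest.fixture(scope="session")
def pair_layout():
    return make_layout(PatternSpec(kind="pair", side_spacing=500))


@pytest.fixture(scope="session")
def two_pairs_layout():
    return two_pairs(500.0, 1000.0)


@pytest.fixture(scope="session")
def hexagon_layout():
    return make_layout(PatternSpec(kind="hexagon", side_spacing=600))


@pytest.fixture(scope="session")
def pair_replicates(pair_layout):
    return _replicates(pair_layout)


@pytest.fixture(scope="session")
def two_pairs_replicates(two_pairs_layout):
    return _replicates(two_pairs_layout)


@pytest.fixture(scope="session")
def hexagon_replicates(hexagon_layout):
    return _replicates(hexagon_layout)
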