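"""Overdamped Langevin dynamics of the fiber network under cell contraction.

The model couples three ingredients:

* **Tension–compression asymmetric bonds.** Each spring bond is piecewise
  harmonic about its rest length l0 with tensile stiffness 100× the
  compressive stiffness, so fibers strongly resist stretch but buckle
  cheaply under compression.
* **Prescribed cluster contraction.** Cell nodes are boundary-driven: every
  increment the cluster radius shrinks by a fixed fraction (5% by default)
  and cell nodes are moved radially onto the new circle. They never respond
  to forces.
* **Irreversible cross-link remodeling.** Whenever a bond's strain relative
  to its rest length exceeds a threshold (50% by default), the rest length
  is reset to the current length — plasticity that locks in the deformed
  geometry and lets the matrix flow toward the contracting clusters.

Matrix nodes follow first-order overdamped dynamics
``dx = (F/γ) dt + sqrt(2 kT dt / γ) ξ`` — the appropriate regime for
hydrogel-embedded fibers, where inertia is negligible. With small thermal
noise, remodeling is contraction-driven rather than noise-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netgen import FiberNetwork

try:  # jitted integrator; a pure-numpy path covers environments without numba
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "BondPotential",
    "ContractionSchedule",
    "RemodelRule",
    "LangevinParams",
    "SimState",
    "Trajectory",
    "bond_energy",
    "bond_force",
    "init_state",
    "step",
    "apply_contraction",
    "remodel",
    "run",
    "total_energy",
]


class SimulationError(RuntimeError):
    """Numerical failure (NaN/overflow) during integration."""


@dataclass(frozen=True)
class BondPotential:
    """Piecewise-harmonic spring: stiff in tension, soft in compression.

    E(l) = ½ k_t (l − l0)²  for l ≥ l0,  ½ k_c (l − l0)²  for l < l0.
    The default compression stiffness is k_tension / 100.
    """

    k_tension: float = 1.0
    k_compression: float | None = None

    def __post_init__(self) -> None:
        if self.k_compression is None:
            object.__setattr__(self, "k_compression", self.k_tension / 100.0)
        if self.k_tension <= 0 or self.k_compression <= 0:
            raise ValueError("stiffnesses must be positive")


@dataclass(frozen=True)
class ContractionSchedule:
    """Stepwise cluster shrinkage: 5% of the radius per 50,000 steps."""

    shrink_fraction_per_increment: float = 0.05
    steps_per_increment: int = 50_000
    n_increments: int = 25

    def __post_init__(self) -> None:
        if not 0.0 <= self.shrink_fraction_per_increment < 1.0:
            raise ValueError("shrink fraction must be in [0, 1)")
        if self.steps_per_increment < 1 or self.n_increments < 0:
            raise ValueError("invalid schedule counts")


@dataclass(frozen=True)
class RemodelRule:
    """Irreversible rest-length reset for bonds strained beyond threshold.

    Remodeling is a property of fiber cross-links; cell–matrix tether bonds
    (the adhesion interface) keep their rest lengths unless
    ``include_tethers`` is set.
    """

    strain_threshold: float = 0.5
    check_interval: int = 1000
    include_tethers: bool = False

    def __post_init__(self) -> None:
        if self.strain_threshold <= 0:
            raise ValueError("strain_threshold must be > 0")
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1")


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped integrator parameters (dimensionless units)."""

    timestep: float = 0.05
    friction: float = 1.0
    temperature: float = 1e-5  # kT; thermal energy << bond energy scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")

    def validate_stability(self, pot: BondPotential) -> None:
        if self.timestep >= 2.0 * self.friction / pot.k_tension:
            raise ValueError(
                f"timestep {self.timestep} violates overdamped stability bound "
                f"2·friction/k_tension = {2.0 * self.friction / pot.k_tension}"
            )


@dataclass
class SimState:
    """Mutable simulation state: network geometry plus runtime bookkeeping."""

    network: FiberNetwork
    positions: np.ndarray
    rest_lengths: np.ndarray
    potential: BondPotential
    cluster_radii: np.ndarray  # current radius per cluster
    cell_angles: np.ndarray  # fixed polar angle of each cell node
    step_index: int = 0
    remodel_events: int = 0

    def copy(self) -> "SimState":
        return SimState(
            network=self.network,
            positions=self.positions.copy(),
            rest_lengths=self.rest_lengths.copy(),
            potential=self.potential,
            cluster_radii=self.cluster_radii.copy(),
            cell_angles=self.cell_angles.copy(),
            step_index=self.step_index,
            remodel_events=self.remodel_events,
        )


def bond_energy(l, l0, pot: BondPotential):
    """Piecewise-harmonic bond energy; elementwise on arrays."""
    l = np.asarray(l, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if np.any(l <= 0) or np.any(l0 <= 0):
        raise ValueError("bond lengths must be positive")
    dl = l - l0
    k = np.where(dl >= 0, pot.k_tension, pot.k_compression)
    return 0.5 * k * dl * dl


def bond_force(l, l0, pot: BondPotential):
    """Restoring force magnitude −dE/dl; zero at the rest length."""
    l = np.asarray(l, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if np.any(l <= 0) or np.any(l0 <= 0):
        raise ValueError("bond lengths must be positive")
    dl = l - l0
    k = np.where(dl >= 0, pot.k_tension, pot.k_compression)
    return -k * dl


def _node_forces(
    positions: np.ndarray,
    bonds: np.ndarray,
    rest: np.ndarray,
    pot: BondPotential,
) -> np.ndarray:
    """Net bond force vector on every node."""
    i, j = bonds[:, 0], bonds[:, 1]
    d = positions[j] - positions[i]
    l = np.hypot(d[:, 0], d[:, 1])
    l = np.maximum(l, 1e-12)
    dl = l - rest
    k = np.where(dl >= 0, pot.k_tension, pot.k_compression)
    # tension (dl>0) pulls i toward j
    coef = k * dl / l
    fx = coef * d[:, 0]
    fy = coef * d[:, 1]
    n = len(positions)
    out = np.empty((n, 2))
    out[:, 0] = np.bincount(i, weights=fx, minlength=n) - np.bincount(j, weights=fx, minlength=n)
    out[:, 1] = np.bincount(i, weights=fy, minlength=n) - np.bincount(j, weights=fy, minlength=n)
    return out


if _HAVE_NUMBA:

    @njit(cache=False)
    def _integrate_jit(pos, bonds, rest, kt, kc, mobile_idx, dt_over_g,
                       n_steps, noise_amp, noise):  # pragma: no cover - jitted
        n = pos.shape[0]
        nb = bonds.shape[0]
        fx = np.empty(n)
        fy = np.empty(n)
        for s in range(n_steps):
            for a in range(n):
                fx[a] = 0.0
                fy[a] = 0.0
            for b in range(nb):
                i = bonds[b, 0]
                j = bonds[b, 1]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                l = np.sqrt(dx * dx + dy * dy)
                if l < 1e-12:
                    l = 1e-12
                dl = l - rest[b]
                k = kt if dl >= 0.0 else kc
                coef = k * dl / l
                fx[i] += coef * dx
                fy[i] += coef * dy
                fx[j] -= coef * dx
                fy[j] -= coef * dy
            for m in range(mobile_idx.shape[0]):
                a = mobile_idx[m]
                pos[a, 0] += dt_over_g * fx[a]
                pos[a, 1] += dt_over_g * fy[a]
                if noise_amp > 0.0:
                    pos[a, 0] += noise_amp * noise[s, m, 0]
                    pos[a, 1] += noise_amp * noise[s, m, 1]


def total_energy(state: SimState) -> float:
    i, j = state.network.bonds[:, 0], state.network.bonds[:, 1]
    d = state.positions[j] - state.positions[i]
    l = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)
    return float(bond_energy(l, state.rest_lengths, state.potential).sum())


def init_state(network: FiberNetwork, potential: BondPotential | None = None) -> SimState:
    """Wrap an embedded network into a runtime state (zero initial stress)."""
    if potential is None:
        potential = BondPotential()
    pos = network.positions.copy()
    n_clusters = len(network.cluster_centers)
    radii = np.full(n_clusters, network.cluster_radius, dtype=float)
    cell_angles = np.zeros(network.n_nodes)
    if n_clusters:
        cid = network.cell_cluster_id
        mask = network.is_cell
        rel = pos[mask] - network.cluster_centers[cid[mask]]
        cell_angles_vals = np.arctan2(rel[:, 1], rel[:, 0])
        cell_angles[mask] = cell_angles_vals
    return SimState(
        network=network,
        positions=pos,
        rest_lengths=network.rest_lengths.copy(),
        potential=potential,
        cluster_radii=radii,
        cell_angles=cell_angles,
    )


def step(state: SimState, params: LangevinParams, rng: np.random.Generator | None = None,
         n_steps: int = 1) -> SimState:
    """Advance matrix nodes by ``n_steps`` overdamped Langevin updates.

    Cell nodes are position-prescribed and do not respond to forces. Mutates
    and returns ``state``. Aborts with :class:`SimulationError` on NaN or
    overflow.
    """
    params.validate_stability(state.potential)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    net = state.network
    mobile = ~net.is_cell & ~net.is_pinned
    dt_over_g = params.timestep / params.friction
    noise_amp = np.sqrt(2.0 * params.temperature * params.timestep / params.friction)
    pos = state.positions
    mobile_idx = np.flatnonzero(mobile)
    if noise_amp > 0:
        noise = rng.standard_normal((n_steps, len(mobile_idx), 2))
    else:
        noise = np.zeros((1, 1, 2))
    if _HAVE_NUMBA:
        _integrate_jit(
            pos, net.bonds, state.rest_lengths,
            state.potential.k_tension, state.potential.k_compression,
            mobile_idx, dt_over_g, n_steps, float(noise_amp), noise,
        )
        state.step_index += n_steps
    else:
        for s in range(n_steps):
            forces = _node_forces(pos, net.bonds, state.rest_lengths, state.potential)
            dx = dt_over_g * forces[mobile]
            if noise_amp > 0:
                dx = dx + noise_amp * noise[s]
            pos[mobile] += dx
            state.step_index += 1
    if not np.all(np.isfinite(pos)):
        raise SimulationError(
            f"non-finite positions at step {state.step_index}; "
            "reduce the timestep or contraction rate"
        )
    return state


def apply_contraction(state: SimState, schedule: ContractionSchedule) -> SimState:
    """Shrink every cluster radius by one increment and reseat cell nodes.

    After m increments the radius is r0·(1 − f)^m; cell nodes keep their
    polar angle and move radially onto the new circle.
    """
    f = schedule.shrink_fraction_per_increment
    if f == 0.0 or len(state.cluster_radii) == 0:
        return state
    state.cluster_radii *= 1.0 - f
    net = state.network
    mask = net.is_cell
    cid = net.cell_cluster_id[mask]
    r = state.cluster_radii[cid]
    ang = state.cell_angles[mask]
    centers = net.cluster_centers[cid]
    state.positions[mask, 0] = centers[:, 0] + r * np.cos(ang)
    state.positions[mask, 1] = centers[:, 1] + r * np.sin(ang)
    return state


def remodel(state: SimState, rule: RemodelRule) -> int:
    """Reset rest lengths of bonds strained beyond the threshold.

    Strain is measured relative to the current rest length,
    |l − l0| / l0. Remodeled bonds carry zero force immediately after.
    Returns the number of bonds remodeled at this call.
    """
    bonds = state.network.bonds
    d = state.positions[bonds[:, 1]] - state.positions[bonds[:, 0]]
    l = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)
    strain = np.abs(l - state.rest_lengths) / state.rest_lengths
    mask = strain > rule.strain_threshold
    if not rule.include_tethers:
        mask &= state.network.fiber_id >= 0
    n_events = int(mask.sum())
    if n_events:
        state.rest_lengths[mask] = l[mask]
        state.remodel_events += n_events
    return n_events


@dataclass
class Trajectory:
    """Recorded snapshots and per-frame scalars of one simulation run."""

    network: FiberNetwork
    frames: list = field(default_factory=list)

    def record(self, state: SimState) -> None:
        forces = _node_forces(
            state.positions, state.network.bonds, state.rest_lengths, state.potential
        )
        self.frames.append(
            {
                "step": state.step_index,
                "positions": state.positions.copy(),
                "rest_lengths": state.rest_lengths.copy(),
                "radii": state.cluster_radii.copy(),
                "energy": total_energy(state),
                "remodel_events": state.remodel_events,
                "force_mag": np.hypot(forces[:, 0], forces[:, 1]),
            }
        )

    @property
    def final(self) -> dict:
        return self.frames[-1]

    @property
    def initial(self) -> dict:
        return self.frames[0]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.frames:
            row = {
                "step": fr["step"],
                "energy": fr["energy"],
                "remodel_events": fr["remodel_events"],
            }
            for ci, r in enumerate(fr["radii"]):
                row[f"radius_{ci}"] = r
            rows.append(row)
        return pd.DataFrame(rows)

    def write_xyz(self, path: str | Path) -> None:
        """Multi-frame extended-XYZ text: x, y, per-node force magnitude."""
        with open(path, "w") as fh:
            for fr in self.frames:
                n = len(fr["positions"])
                fh.write(f"{n}\n")
                radii = " ".join(f"{r:.6f}" for r in fr["radii"])
                fh.write(
                    f"step={fr['step']} energy={fr['energy']:.9e} "
                    f"remodel_events={fr['remodel_events']} radii={radii}\n"
                )
                for (x, y), fm in zip(fr["positions"], fr["force_mag"]):
                    fh.write(f"{x:.9e} {y:.9e} {fm:.9e}\n")


def run(
    network: FiberNetwork,
    schedule: ContractionSchedule | None = None,
    rule: RemodelRule | None = None,
    params: LangevinParams | None = None,
    potential: BondPotential | None = None,
    snapshot_every: int = 1,
) -> Trajectory:
    """Full contraction run: alternate contraction, integration, remodeling.

    Per increment: contract the clusters once, then integrate
    ``schedule.steps_per_increment`` Langevin steps, evaluating the
    remodeling criterion every ``rule.check_interval`` steps. Snapshots are
    recorded at t=0 and after every ``snapshot_every``-th increment.
    """
    schedule = schedule or ContractionSchedule()
    rule = rule or RemodelRule()
    params = params or LangevinParams()
    state = init_state(network, potential)
    params.validate_stability(state.potential)
    rng = np.random.default_rng(params.rng_seed)

    traj = Trajectory(network=network)
    traj.record(state)
    for m in range(schedule.n_increments):
        apply_contraction(state, schedule)
        done = 0
        while done < schedule.steps_per_increment:
            chunk = min(rule.check_interval, schedule.steps_per_increment - done)
            step(state, params, rng=rng, n_steps=chunk)
            done += chunk
            remodel(state, rule)
        if (m + 1) % snapshot_every == 0 or m == schedule.n_increments - 1:
            traj.record(state)
    if schedule.n_increments == 0 and len(traj.frames) == 1:
        traj.record(state)  # trivially constant trajectory
    return traj
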