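"""Langevin NVT dynamics with periodic boundaries.

The integrator is the BAOAB splitting of Langevin dynamics, which reduces
to velocity Verlet when the friction is zero.  Neighbor search uses a
Verlet list with a skin, backed by a cell list when the box is at least
three list-cutoffs wide and by an all-pairs scan otherwise.  The
equilibration protocol ramps the timestep by a factor of ten per stage
from 0.01 fs up to the production 10 fs, relaxing the random packing
before production dynamics.

Reduced units throughout (see :mod:`cookesim.units`); the trajectory
object carries box and positions in reduced lengths plus per-snapshot
energy/temperature records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams, BondOverextensionError
from .topology import Topology

__all__ = [
    "SystemState", "EngineConfig", "Trajectory", "neighbor_list",
    "total_energy_forces", "minimize", "equilibrate", "run_langevin",
    "make_rng",
    "kinetic_temperature_K", "draw_maxwell_boltzmann",
]


@dataclass
class SystemState:
    """Positions/velocities in a cubic periodic box (reduced units)."""

    positions: np.ndarray            # (N, 3), sigma
    velocities: np.ndarray           # (N, 3), sigma/tau
    box_edge: float                  # sigma
    time: float = 0.0                # tau

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box_edge, self.time)

    def wrapped(self) -> "SystemState":
        pos = self.positions - self.box_edge * np.floor(
            self.positions / self.box_edge)
        return SystemState(pos, self.velocities.copy(), self.box_edge,
                           self.time)


@dataclass
class EngineConfig:
    """Integration parameters (physical units on the surface)."""

    timestep_fs: float = 10.0
    friction_per_ps: float = 1.0
    temperature_K: float = 310.0
    seed: int = 0
    skin: float = 0.5                # sigma
    snapshot_interval: int = 100_000  # steps (1 ns at 10 fs)
    mass: float = 1.0                # reduced (= 100 amu)

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.friction_per_ps < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class Trajectory:
    """Snapshots plus energy/temperature time series."""

    times: list[float] = field(default_factory=list)          # tau
    positions: list[np.ndarray] = field(default_factory=list)  # wrapped
    velocities: list[np.ndarray] = field(default_factory=list)
    box_edge: float = 0.0
    potential_energy: list[float] = field(default_factory=list)
    kinetic_energy: list[float] = field(default_factory=list)
    temperature_K: list[float] = field(default_factory=list)
    final_state: "SystemState | None" = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame_state(self, i: int) -> SystemState:
        vel = (self.velocities[i].copy() if i < len(self.velocities)
               else np.zeros_like(self.positions[i]))
        return SystemState(self.positions[i].copy(), vel,
                           self.box_edge, self.times[i])


# ----------------------------------------------------------------------
# array preparation
# ----------------------------------------------------------------------

class _Arrays:
    """Flat per-bead and per-bond arrays for the kernels."""

    def __init__(self, topology: Topology, params: ForceFieldParams):
        self.types = topology.bead_types()
        self.b_tab, self.wc_tab = params.pair_tables()
        self.eps = params.epsilon
        fene = np.array(topology.fene_bonds, dtype=np.int32).reshape(-1, 2)
        self.fene_i = np.ascontiguousarray(fene[:, 0])
        self.fene_j = np.ascontiguousarray(fene[:, 1])
        harm = list(topology.harmonic_bonds)
        elast = list(topology.elastic_bonds)
        hi, hj, hr0, hk = [], [], [], []
        for i, j, r0 in harm:
            hi.append(i); hj.append(j); hr0.append(r0)
            hk.append(params.k_bend)
        for i, j, r0 in elast:
            hi.append(i); hj.append(j); hr0.append(r0)
            hk.append(params.k_elastic)
        self.harm_i = np.array(hi, dtype=np.int32)
        self.harm_j = np.array(hj, dtype=np.int32)
        self.harm_r0 = np.array(hr0, dtype=np.float64)
        self.harm_k = np.array(hk, dtype=np.float64)
        # nonbonded exclusions: all intra-peptide pairs.  The stiff elastic
        # network holds the peptide at its reference geometry, where every
        # non-network pair is beyond the WCA cutoff and peptide-peptide
        # attraction is zero, so intramolecular nonbonded terms are inert;
        # dropping them keeps the neighbor list small.  Lipid intramolecular
        # WCA stays on (FENE bonds combine with WCA as usual).
        self.mol_ids = topology.molecule_ids()
        self.excl_intra = (topology.bead_kinds() == 1).astype(np.int8)
        self.cutoff = params.max_interaction_range
        self.k_fene = params.k_bond
        self.r_inf = params.r_inf
        self.r_floor_frac = params.r_floor_frac
        # neighbor workspaces, sized lazily per (box, rlist)
        self._ws: dict = {}

    def workspace(self, n_beads: int, box: float, rlist: float):
        """Preallocated neighbor-list buffers for a given box/cutoff."""
        m = max(int(box / rlist), 1)
        key = (n_beads, m)
        if key not in self._ws:
            cap = max(128 * n_beads, 4096)
            self._ws[key] = dict(
                pi=np.empty(cap, dtype=np.int32),
                pj=np.empty(cap, dtype=np.int32),
                pb=np.empty(cap, dtype=np.float64),
                pwc=np.empty(cap, dtype=np.float64),
                cell_counts=np.zeros(m ** 3 + 1, dtype=np.int64),
                cell_order=np.empty(n_beads, dtype=np.int32),
                cell_of=np.empty(n_beads, dtype=np.int64),
            )
        return self._ws[key]


def _build_pairs(pos, box, rlist, arrays):
    """Fill the workspace pair buffers; returns (workspace, n_pairs,
    use_cell)."""
    ws = arrays.workspace(pos.shape[0], box, rlist)
    use_cell = box >= 3.0 * rlist
    if use_cell:
        npairs = _kernels.build_pairs_cell(
            pos, box, rlist, arrays.mol_ids, arrays.excl_intra,
            arrays.types, arrays.b_tab, arrays.wc_tab,
            ws["cell_counts"], ws["cell_order"], ws["cell_of"],
            ws["pi"], ws["pj"], ws["pb"], ws["pwc"])
    else:
        npairs = _kernels.build_pairs_n2(
            pos, box, rlist, arrays.mol_ids, arrays.excl_intra,
            arrays.types, arrays.b_tab, arrays.wc_tab,
            ws["pi"], ws["pj"], ws["pb"], ws["pwc"])
    if npairs < 0:
        raise RuntimeError("neighbor-list buffer overflow: system far "
                           "denser than physical packing")
    return ws, npairs, use_cell


def neighbor_list(state: SystemState, cutoff: float, skin: float = 0.0,
                  topology: Topology | None = None,
                  params: ForceFieldParams | None = None
                  ) -> list[tuple[int, int]]:
    """Candidate pairs within ``cutoff + skin`` under minimum image.

    Falls back from the cell decomposition to an all-pairs scan (with a
    warning) when the box is too small for at least 3 cells per edge.
    """
    if params is None:
        params = ForceFieldParams()
    if topology is None:
        topology = Topology()
        n = state.positions.shape[0]
        arrays = _Arrays(topology, params)
        arrays.types = np.zeros(n, dtype=np.int8)
        arrays.mol_ids = np.arange(n, dtype=np.int32)
        arrays.excl_intra = np.zeros(n, dtype=np.int8)
    else:
        arrays = _Arrays(topology, params)
    rlist = cutoff + skin
    pos = np.ascontiguousarray(state.wrapped().positions, dtype=np.float64)
    if state.box_edge < 3.0 * rlist:
        warnings.warn("box too small for cell decomposition; "
                      "using all-pairs search")
    ws, npairs, _ = _build_pairs(pos, state.box_edge, rlist, arrays)
    return list(zip(ws["pi"][:npairs].tolist(), ws["pj"][:npairs].tolist()))


def total_energy_forces(state: SystemState, topology: Topology,
                        params: ForceFieldParams
                        ) -> tuple[float, np.ndarray]:
    """Total potential energy and per-bead forces of a configuration."""
    arrays = _Arrays(topology, params)
    pos = np.ascontiguousarray(state.wrapped().positions, dtype=np.float64)
    ws, npairs, _ = _build_pairs(pos, state.box_edge, arrays.cutoff, arrays)
    forces = np.zeros_like(pos)
    energy, err = _kernels.compute_forces(
        pos, state.box_edge, arrays.eps, ws["pi"], ws["pj"], ws["pb"],
        ws["pwc"], npairs, arrays.fene_i, arrays.fene_j, arrays.k_fene,
        arrays.r_inf, arrays.harm_i, arrays.harm_j, arrays.harm_r0,
        arrays.harm_k, arrays.r_floor_frac, forces)
    if err == _kernels.ERR_FENE:
        raise BondOverextensionError("FENE bond beyond divergence length")
    return energy, forces


# ----------------------------------------------------------------------
# minimization (FIRE)
# ----------------------------------------------------------------------

def minimize(state: SystemState, topology: Topology,
             params: ForceFieldParams, max_steps: int = 2000,
             f_tol: float = 1e-3, dt_start: float = 1e-4
             ) -> SystemState:
    """FIRE energy minimization; never returns a higher-energy state.

    Step sizes are capped at 0.05 sigma per bead per iteration so FENE
    bonds cannot jump past their divergence length.
    """
    arrays = _Arrays(topology, params)
    pos = np.ascontiguousarray(state.wrapped().positions, dtype=np.float64)
    box = state.box_edge
    vel = np.zeros_like(pos)
    dt = dt_start
    dt_max = 50 * dt_start
    alpha = 0.1
    n_pos = 0
    best_pos = pos.copy()

    def energy_forces(p):
        ws, npairs, _ = _build_pairs(p, box, arrays.cutoff, arrays)
        f = np.zeros_like(p)
        e, err = _kernels.compute_forces(
            p, box, arrays.eps, ws["pi"], ws["pj"], ws["pb"], ws["pwc"],
            npairs, arrays.fene_i, arrays.fene_j, arrays.k_fene,
            arrays.r_inf, arrays.harm_i, arrays.harm_j, arrays.harm_r0,
            arrays.harm_k, arrays.r_floor_frac, f)
        return e, f, err

    energy, forces, _ = energy_forces(pos)
    if not np.isfinite(energy):
        raise RuntimeError("initial energy not finite; cannot minimize")
    best_energy = energy
    for _ in range(max_steps):
        fmax = np.max(np.abs(forces)) if forces.size else 0.0
        if fmax < f_tol:
            break
        power = float(np.sum(forces * vel))
        if power > 0:
            n_pos += 1
            fnorm = np.linalg.norm(forces)
            vnorm = np.linalg.norm(vel)
            if fnorm > 0:
                vel = (1 - alpha) * vel + alpha * vnorm * forces / fnorm
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            vel[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        vel += dt * forces
        step = dt * vel
        np.clip(step, -0.05, 0.05, out=step)
        pos = pos + step
        energy, forces, err = energy_forces(pos)
        if not np.isfinite(energy):
            raise RuntimeError("minimization diverged (energy not finite)")
        if energy < best_energy:
            best_energy = energy
            best_pos = pos.copy()
    out = SystemState(best_pos, state.velocities.copy(), box, state.time)
    return out.wrapped()


# ----------------------------------------------------------------------
# Langevin dynamics
# ----------------------------------------------------------------------

def kinetic_temperature_K(ke: float, n_beads: int,
                          params: ForceFieldParams) -> float:
    """Instantaneous kinetic temperature from total KE (reduced)."""
    return params.units.kelvin_from_kinetic(ke / (3.0 * n_beads))


def draw_maxwell_boltzmann(n_beads: int, params: ForceFieldParams,
                           rng: np.random.Generator,
                           mass: float = 1.0) -> np.ndarray:
    """Velocities from the Maxwell-Boltzmann distribution (reduced)."""
    sd = math.sqrt(params.kT / mass)
    return rng.normal(0.0, sd, size=(n_beads, 3))


def _run_chunks(state, arrays, params, config, n_steps, rng,
                record_every=None, collect=None):
    """Drive the jitted chunk integrator; optionally record snapshots."""
    units = params.units
    dt = units.fs_to_tau(config.timestep_fs)
    gamma = units.per_ps_to_per_tau(config.friction_per_ps)
    kT = units.kT(config.temperature_K)
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1) / config.mass) if gamma > 0 else 0.0
    rlist = arrays.cutoff + config.skin

    pos = np.array(state.wrapped().positions, dtype=np.float64, copy=True)
    vel = np.array(state.velocities, dtype=np.float64, copy=True)
    box = state.box_edge
    ws, npairs, use_cell = _build_pairs(pos, box, rlist, arrays)
    pos0 = pos.copy()
    forces = np.zeros_like(pos)
    _, err = _kernels.compute_forces(
        pos, box, arrays.eps, ws["pi"], ws["pj"], ws["pb"], ws["pwc"],
        npairs, arrays.fene_i, arrays.fene_j, arrays.k_fene, arrays.r_inf,
        arrays.harm_i, arrays.harm_j, arrays.harm_r0, arrays.harm_k,
        arrays.r_floor_frac, forces)
    if err == _kernels.ERR_FENE:
        raise BondOverextensionError("FENE bond overextended at start")

    chunk = record_every if record_every else min(n_steps, 2000)
    chunk = max(1, min(chunk, 2000))
    done = 0
    time = state.time
    n = pos.shape[0]
    noise_buf = np.empty((chunk, n, 3))
    ke_buf = np.empty(chunk)
    pe_buf = np.empty(chunk)
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        if record_every:
            todo = min(todo, record_every - (done % record_every) or
                       record_every)
        noise = noise_buf[:todo]
        if c2 != 0.0:
            rng.standard_normal(out=noise_buf.reshape(-1)[:todo * n * 3])
        else:
            noise[:] = 0.0
        ke_out = ke_buf[:todo]
        pe_out = pe_buf[:todo]
        npairs, err, _ = _kernels.integrate_chunk(
            pos, vel, forces, pos0, box, arrays.types, arrays.b_tab,
            arrays.wc_tab, arrays.eps, ws["pi"], ws["pj"], ws["pb"],
            ws["pwc"], npairs,
            arrays.fene_i, arrays.fene_j, arrays.k_fene, arrays.r_inf,
            arrays.harm_i, arrays.harm_j, arrays.harm_r0, arrays.harm_k,
            arrays.mol_ids, arrays.excl_intra,
            ws["cell_counts"], ws["cell_order"], ws["cell_of"],
            noise, dt, c1, c2, config.mass, rlist, config.skin,
            arrays.r_floor_frac, use_cell, ke_out, pe_out)
        done += todo
        time = state.time + done * dt
        if err == _kernels.ERR_OVERFLOW:
            raise RuntimeError("neighbor-list buffer overflow during "
                               f"dynamics after {done} steps")
        if err == _kernels.ERR_FENE:
            raise BondOverextensionError(
                f"FENE bond overextended after {done} steps "
                f"(t = {time:.3f} tau)")
        if not np.all(np.isfinite(pos)):
            raise RuntimeError(f"non-finite positions after {done} steps")
        if collect is not None:
            collect(done, time, pos, vel, ke_out, pe_out)
    return SystemState(pos.copy(), vel.copy(), box, time).wrapped()


def equilibrate(state: SystemState, topology: Topology,
                params: ForceFieldParams, seed: int = 0,
                steps_per_stage: int = 10_000,
                stage_timesteps_fs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
                config: EngineConfig | None = None) -> SystemState:
    """Staged Langevin relaxation with a 10x timestep ramp (0.01 -> 10 fs)."""
    if config is None:
        config = EngineConfig(seed=seed)
    rng = np.random.Generator(np.random.SFC64(seed))
    cur = state.copy()
    if not cur.velocities.any():
        cur.velocities = draw_maxwell_boltzmann(
            cur.positions.shape[0], params, rng, config.mass)
    arrays = _Arrays(topology, params)
    for stage, dt_fs in enumerate(stage_timesteps_fs):
        stage_cfg = replace(config, timestep_fs=dt_fs)
        try:
            cur = _run_chunks(cur, arrays, params, stage_cfg,
                              steps_per_stage, rng)
        except (BondOverextensionError, RuntimeError) as exc:
            raise RuntimeError(
                f"equilibration unstable at stage {stage} "
                f"(dt = {dt_fs} fs): {exc}") from exc
    return cur


def make_rng(seed: int) -> np.random.Generator:
    """The engine's noise generator (SFC64; fast gaussian throughput)."""
    return np.random.Generator(np.random.SFC64(seed))


def run_langevin(state: SystemState, topology: Topology,
                 params: ForceFieldParams, config: EngineConfig,
                 n_steps: int,
                 rng: np.random.Generator | None = None) -> Trajectory:
    """Production Langevin run; snapshots every ``snapshot_interval`` steps.

    Pass an explicit ``rng`` (e.g. restored from a checkpoint) to continue
    a noise stream across segmented runs; by default a fresh generator is
    seeded from ``config.seed``.
    """
    if rng is None:
        rng = make_rng(config.seed)
    arrays = _Arrays(topology, params)
    traj = Trajectory(box_edge=state.box_edge)
    n = state.positions.shape[0]
    interval = max(1, config.snapshot_interval)

    def collect(done, time, pos, vel, ke_out, pe_out):
        if done % interval == 0 or done == n_steps:
            p = pos - state.box_edge * np.floor(pos / state.box_edge)
            traj.times.append(time)
            traj.positions.append(p.copy())
            traj.velocities.append(vel.copy())
            traj.potential_energy.append(float(pe_out[-1]))
            traj.kinetic_energy.append(float(ke_out[-1]))
            traj.temperature_K.append(
                kinetic_temperature_K(float(ke_out[-1]), n, params))

    traj.final_state = _run_chunks(state, arrays, params, config, n_steps,
                                   rng, record_every=interval,
                                   collect=collect)
    return traj
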