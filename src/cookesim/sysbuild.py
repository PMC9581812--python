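"""Initial-configuration construction at target composition/concentration.

The box edge follows from the lipid molarity alone (peptides are added on
top and do not count toward the concentration).  Molecules are placed by
rejection sampling: random position and orientation, accepted when no bead
comes within a floor distance of any previously placed molecule under
minimum image.  Replica seeds derive from a base seed by offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .engine import SystemState
from .topology import Topology, assemble_system
from .units import N_AVOGADRO, Units, DEFAULT_UNITS

__all__ = ["SystemSpec", "box_edge_from_concentration", "random_pack",
           "build_initial_state"]


@dataclass
class SystemSpec:
    """Composition and conditions of one simulated system."""

    n_lipids: int
    n_peptides: int = 0
    lipid_concentration_mM: float = 10.0
    replicas: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids < 0 or self.n_peptides < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.n_lipids + self.n_peptides == 0:
            raise ValueError("empty system")
        if self.lipid_concentration_mM <= 0:
            raise ValueError("concentration must be positive")

    @property
    def p_over_l(self) -> float:
        return self.n_peptides / self.n_lipids if self.n_lipids else math.inf

    def replica_seed(self, replica_index: int) -> int:
        return self.base_seed + replica_index


def box_edge_from_concentration(n_lipids: int, concentration_mM: float,
                                ) -> float:
    """Cubic box edge in nm such that n/(N_A V) equals the molarity."""
    if n_lipids < 1 or concentration_mM <= 0:
        raise ValueError("need n_lipids >= 1 and positive concentration")
    conc_mol_per_L = concentration_mM * 1e-3
    volume_L = n_lipids / (N_AVOGADRO * conc_mol_per_L)
    volume_nm3 = volume_L * 1e24  # 1 L = 1 dm^3 = 1e24 nm^3
    return volume_nm3 ** (1.0 / 3.0)


def concentration_mM_from_count(count: int, box_edge_sigma: float,
                                units: Units = DEFAULT_UNITS) -> float:
    """Molar concentration of ``count`` molecules in a cubic reduced box."""
    volume_nm3 = (units.sigma_to_nm(box_edge_sigma)) ** 3
    volume_L = volume_nm3 * 1e-24
    return count / (N_AVOGADRO * volume_L) * 1e3


def random_pack(spec: SystemSpec, topology: Topology, seed: int | None = None,
                min_distance: float = 0.8, box_edge: float | None = None,
                units: Units = DEFAULT_UNITS,
                max_retries_per_molecule: int = 2000) -> SystemState:
    """Place rigid molecules at random positions/orientations without clashes.

    ``min_distance`` (sigma) is the inter-molecular bead-bead floor; bonded
    geometry within each molecule is the build reference.  Raises when a
    molecule cannot be placed, suggesting a larger box.
    """
    if seed is None:
        seed = spec.base_seed
    if box_edge is None:
        box_edge = units.nm_to_sigma(box_edge_from_concentration(
            max(spec.n_lipids, 1), spec.lipid_concentration_mM))
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tree = None
    for mol_beads in topology.molecule_slices():
        ref = topology.reference_coords[mol_beads]
        ref = ref - ref.mean(axis=0)
        ok = False
        for _ in range(max_retries_per_molecule):
            rot = Rotation.from_quat(_random_quat(rng))
            cand = rot.apply(ref) + rng.uniform(0.0, box_edge, size=3)
            cand -= box_edge * np.floor(cand / box_edge)
            if tree is None:
                ok = True
            else:
                d, _ = tree.query(cand, k=1)
                ok = bool(np.min(d) >= min_distance)
            if ok:
                break
        if not ok:
            raise RuntimeError(
                f"could not place molecule after {max_retries_per_molecule} "
                "attempts; increase the box (lower concentration) or reduce "
                "min_distance")
        placed.append(cand)
        allpos = np.vstack(placed)
        tree = cKDTree(allpos, boxsize=box_edge)
    positions = np.vstack(placed)
    velocities = np.zeros_like(positions)
    return SystemState(positions, velocities, float(box_edge))


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    return np.array([
        math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
        math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
        math.sqrt(u1) * math.sin(2 * math.pi * u3),
        math.sqrt(u1) * math.cos(2 * math.pi * u3),
    ])


def build_initial_state(spec: SystemSpec, seed: int | None = None,
                        units: Units = DEFAULT_UNITS
                        ) -> tuple[SystemState, Topology]:
    """Topology plus randomly packed state for a system spec."""
    topology = assemble_system(spec.n_lipids, spec.n_peptides)
    state = random_pack(spec, topology, seed=seed, units=units)
    return state, topology
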