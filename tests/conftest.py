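"""Shared fixtures and independent reference implementations.

The oracles here (explicit pairwise energy sums, union-find clustering)
are deliberately written from the model definition, independent of the
package's kernels, so kernel results can be checked against them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cookesim.forcefield import ForceFieldParams, CLASS_T

RT2 = 2.0 ** (1.0 / 6.0)


@pytest.fixture
def params() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ----------------------------------------------------------------------
# brute-force energy/force oracle (all-pairs double loop, explicit forms)
# ----------------------------------------------------------------------

def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def oracle_energy_forces(pos: np.ndarray, box: float, topology,
                         params: ForceFieldParams):
    """O(N^2) reference: WCA + attraction + FENE + harmonic/elastic.

    Mirrors the model definition directly: nonbonded terms act between all
    bead pairs except pairs within the same peptide molecule; FENE pairs
    keep their WCA term.
    """
    n = pos.shape[0]
    classes = topology.bead_classes()
    kinds = topology.bead_kinds()
    mols = topology.molecule_ids()
    eps = params.epsilon
    energy = 0.0
    forces = np.zeros_like(pos)

    def add_pair_force(i, j, g, d):
        forces[i] += g * d
        forces[j] -= g * d

    for i in range(n):
        for j in range(i + 1, n):
            if kinds[i] == 1 and mols[i] == mols[j]:
                continue  # intra-peptide exclusion
            d = _min_image(pos[i] - pos[j], box)
            r = np.linalg.norm(d)
            b = params.b_pair(classes[i], classes[j])
            wc = params.wc_pair(classes[i], classes[j], kinds[i], kinds[j])
            rc = RT2 * b
            r_eval = max(r, params.r_floor_frac * b)
            dvdr = 0.0
            if r_eval <= rc:
                x6 = (b / r_eval) ** 6
                energy += 4 * eps * (x6 * x6 - x6 + 0.25)
                dvdr += 4 * eps * (6 * x6 - 12 * x6 * x6) / r_eval
                if wc > 0:
                    energy -= eps
            elif wc > 0 and r_eval <= rc + wc:
                u = np.pi * (r_eval - rc) / (2 * wc)
                energy -= eps * np.cos(u) ** 2
                dvdr += eps * np.pi / (2 * wc) * np.sin(2 * u)
            if dvdr != 0.0:
                add_pair_force(i, j, -dvdr / r_eval, d)

    for i, j in topology.fene_bonds:
        d = _min_image(pos[i] - pos[j], box)
        r = np.linalg.norm(d)
        x = r / params.r_inf
        assert x < 1.0, "oracle: FENE overextension"
        energy += -0.5 * params.k_bond * params.r_inf ** 2 * np.log(1 - x * x)
        dvdr = params.k_bond * r / (1 - x * x)
        add_pair_force(i, j, -dvdr / r, d)

    for i, j, r0 in topology.harmonic_bonds:
        d = _min_image(pos[i] - pos[j], box)
        r = np.linalg.norm(d)
        energy += 0.5 * params.k_bend * (r - r0) ** 2
        add_pair_force(i, j, -params.k_bend * (r - r0) / r, d)

    for i, j, r0 in topology.elastic_bonds:
        d = _min_image(pos[i] - pos[j], box)
        r = np.linalg.norm(d)
        energy += 0.5 * params.k_elastic * (r - r0) ** 2
        add_pair_force(i, j, -params.k_elastic * (r - r0) / r, d)

    return energy, forces


# ----------------------------------------------------------------------
# union-find clustering oracle
# ----------------------------------------------------------------------

def oracle_clusters(state, topology, cutoff_sigma: float):
    """Single-linkage molecule clusters by all-pairs union-find."""
    pos = state.wrapped().positions
    box = state.box_edge
    classes = topology.bead_classes()
    mols = topology.molecule_ids()
    hydro = np.flatnonzero(classes == CLASS_T)
    n_mol = topology.n_molecules
    parent = list(range(n_mol))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for ii in range(len(hydro)):
        for jj in range(ii + 1, len(hydro)):
            i, j = hydro[ii], hydro[jj]
            d = _min_image(pos[i] - pos[j], box)
            if np.dot(d, d) <= cutoff_sigma ** 2:
                union(int(mols[i]), int(mols[j]))
    groups: dict[int, set] = {}
    for m in range(n_mol):
        groups.setdefault(find(m), set()).add(m)
    return {frozenset(g) for g in groups.values()}


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of b onto a after optimal superposition."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = b0 @ rot - a0
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))
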