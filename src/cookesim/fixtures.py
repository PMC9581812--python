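"""Deterministic pre-assembled configurations for analysis testing.

Self-assembly takes microseconds of simulated time; the analysis stack is
instead exercised on idealized constructs whose cluster structure, labels
and sizes are known by design:

* ``micelle`` — lipids radially arranged on a sphere, tails inward;
* ``disc``   — a flat circular bilayer patch, optional peptides standing
  on the rim (amphipathic peptides coat disc edges, "picket fence" style);
* ``bilayer`` — a planar patch spanning the box;
* ``dispersed`` — isolated monomers far beyond the cluster cutoff;
* ``mixture`` — planted micelles and discs with known per-aggregate
  composition and labels.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import SystemState
from .sysbuild import box_edge_from_concentration
from .topology import Topology, assemble_system
from .units import Units, DEFAULT_UNITS

__all__ = ["generate_fixture", "micelle_coords", "disc_coords"]

#: surface spacing between lipid anchor points, sigma
_LATTICE = 1.15


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def micelle_coords(n_lipids: int, center: np.ndarray,
                   spacing: float = _LATTICE) -> np.ndarray:
    """Lipid coordinates for a spherical micelle, tails pointing inward.

    The inner-tail radius is set so the tail-bead surface density keeps
    nearest neighbors within the cluster cutoff.  Bead order per lipid is
    H, T1, T2 (matching the lipid builder).
    """
    dirs = _fibonacci_sphere(n_lipids)
    r_t1 = max(0.8, spacing * math.sqrt(n_lipids / (4.0 * math.pi)))
    coords = np.empty((3 * n_lipids, 3))
    for i, d in enumerate(dirs):
        coords[3 * i + 0] = center + (r_t1 + 2.0) * d   # head, outermost
        coords[3 * i + 1] = center + (r_t1 + 1.0) * d
        coords[3 * i + 2] = center + r_t1 * d
    return coords


def disc_coords(n_lipids: int, n_peptides: int, center: np.ndarray,
                spacing: float = 1.3, normal_axis: int = 2
                ) -> tuple[np.ndarray, np.ndarray]:
    """A flat circular bilayer patch with peptides standing on the rim.

    Returns (lipid bead coords, peptide placement frames); each peptide
    frame is (rim anchor point, outward unit vector).  Lipids split evenly
    between leaflets on a hexagonal lattice clipped to a circle.
    """
    n_leaf = (n_lipids + 1) // 2
    # hexagonal lattice points, nearest-first
    pts = []
    m = int(math.ceil(math.sqrt(n_leaf))) + 3
    for a in range(-m, m + 1):
        for b in range(-m, m + 1):
            x = spacing * (a + 0.5 * b)
            y = spacing * (math.sqrt(3) / 2.0) * b
            pts.append((x * x + y * y, x, y))
    pts.sort()
    lat = np.array([(x, y) for _, x, y in pts])
    radius = math.sqrt(lat[n_leaf - 1, 0] ** 2 + lat[n_leaf - 1, 1] ** 2)

    coords = []
    count = 0
    for leaf, zsign in ((0, 1.0), (1, -1.0)):
        n_this = n_leaf if leaf == 0 else n_lipids - n_leaf
        for k in range(n_this):
            x, y = lat[k]
            # H outer, T1 middle, T2 inner
            for z in (2.5 * zsign, 1.5 * zsign, 0.5 * zsign):
                p = np.array([x, y, z])
                coords.append(p)
            count += 1
    coords = np.array(coords)
    if normal_axis != 2:
        coords = np.roll(coords, shift=normal_axis - 2, axis=1)
    coords = coords + center

    frames = []
    rim_r = radius + 1.2
    for k in range(n_peptides):
        ang = 2.0 * math.pi * k / max(n_peptides, 1)
        anchor = np.array([rim_r * math.cos(ang), rim_r * math.sin(ang), 0.0])
        if normal_axis != 2:
            anchor = np.roll(anchor, shift=normal_axis - 2)
        frames.append((center + anchor, anchor / np.linalg.norm(anchor)))
    return coords, frames


def _place_peptide(ref: np.ndarray, anchor: np.ndarray,
                   outward: np.ndarray) -> np.ndarray:
    """Stand a peptide on a disc rim: axis along the disc normal.

    The hydrophobic stripe (vertices 0-1, +x side of the reference frame)
    is rotated to face inward, toward the disc center.
    """
    c = ref - ref.mean(axis=0)
    # reference axis is z; stripe face is +x.  Build a rotation taking
    # z -> z (peptide standing) and +x -> -outward (stripe inward).
    inward = -outward
    inward = inward - inward[2] * np.array([0.0, 0.0, 1.0])
    nrm = np.linalg.norm(inward)
    if nrm < 1e-9:
        inward = np.array([1.0, 0.0, 0.0])
    else:
        inward = inward / nrm
    zhat = np.array([0.0, 0.0, 1.0])
    yhat = np.cross(zhat, inward)
    rot = np.column_stack([inward, yhat, zhat])
    return c @ rot.T + anchor


def generate_fixture(kind: str, n_lipids: int, n_peptides: int = 0,
                     concentration_mM: float = 10.0, seed: int = 0,
                     n_micelles: int = 1, units: Units = DEFAULT_UNITS
                     ) -> tuple[SystemState, Topology, dict]:
    """Build an idealized configuration plus its ground-truth description.

    Returns (state, topology, truth) where ``truth`` records the planted
    aggregates as {"aggregates": [(molecule id set, label)], ...}.
    """
    rng = np.random.default_rng(seed)
    box = units.nm_to_sigma(box_edge_from_concentration(
        max(n_lipids, 1), concentration_mM))
    topo = assemble_system(n_lipids, n_peptides)
    truth: dict = {"kind": kind, "aggregates": []}
    center = np.full(3, box / 2.0)

    if kind == "micelle":
        per = [n_lipids // n_micelles + (1 if i < n_lipids % n_micelles
                                         else 0) for i in range(n_micelles)]
        if n_peptides:
            raise ValueError("micelle fixture is lipid-only; "
                             "use 'mixture' for mixed aggregates")
        coords = []
        mol = 0
        centers = _spread_centers(n_micelles, box, rng)
        for c, n_this in zip(centers, per):
            coords.append(micelle_coords(n_this, c))
            truth["aggregates"].append(
                (frozenset(range(mol, mol + n_this)), "micelle"))
            mol += n_this
        pos = np.vstack(coords)

    elif kind in ("disc", "bilayer"):
        if kind == "bilayer":
            lip, frames = disc_coords(n_lipids, 0, center)
        else:
            lip, frames = disc_coords(n_lipids, n_peptides, center)
        parts = [lip]
        for k, (anchor, outward) in enumerate(frames):
            ref = topo.reference_coords[3 * n_lipids + 42 * k:
                                        3 * n_lipids + 42 * (k + 1)]
            parts.append(_place_peptide(ref, anchor, outward))
        pos = np.vstack(parts)
        truth["aggregates"].append(
            (frozenset(range(n_lipids + n_peptides)),
             "disc" if kind == "disc" else "bilayer"))

    elif kind == "dispersed":
        mols = topo.molecule_slices()
        centers = _spread_centers(len(mols), box, rng, min_sep=6.0)
        parts = []
        for c, idx in zip(centers, mols):
            ref = topo.reference_coords[idx]
            parts.append(ref - ref.mean(axis=0) + c)
        pos = np.vstack(parts)

    elif kind == "mixture":
        # a small micelle (with the peptides on its surface) plus one disc
        # big enough that its all-bead Rg clears the 2.5 nm threshold
        n_mic_lip = min(40, max(n_lipids // 5, 5))
        n_disc_lip = n_lipids - n_mic_lip
        if n_disc_lip < 140:
            raise ValueError(
                "mixture fixture needs >= ~180 lipids so the planted disc "
                f"exceeds the Rg label threshold (got {n_lipids})")
        lip_disc, _ = disc_coords(n_disc_lip, 0, center)
        mic_center = center + np.array([box * 0.3, 0.0, 0.0])
        lip_mic = micelle_coords(n_mic_lip, mic_center)
        parts = [lip_mic, lip_disc]
        r_t1 = max(0.8, _LATTICE * math.sqrt(n_mic_lip / (4.0 * math.pi)))
        for k in range(n_peptides):
            ref = topo.reference_coords[3 * n_lipids + 42 * k:
                                        3 * n_lipids + 42 * (k + 1)]
            ang = 2.0 * math.pi * k / max(n_peptides, 1)
            radial = np.array([math.cos(ang), math.sin(ang), 0.0])
            anchor = mic_center + (r_t1 + 0.9) * radial
            parts.append(_place_peptide(ref, anchor, radial))
        pos = np.vstack(parts)
        truth["aggregates"].append(
            (frozenset(list(range(n_mic_lip)) +
                       list(range(n_lipids, n_lipids + n_peptides))),
             "micelle"))
        truth["aggregates"].append(
            (frozenset(range(n_mic_lip, n_lipids)), "disc"))

    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")

    pos = pos - box * np.floor(pos / box)
    state = SystemState(pos, np.zeros_like(pos), box)
    return state, topo, truth


def _spread_centers(n: int, box: float, rng: np.random.Generator,
                    min_sep: float = 0.0) -> list[np.ndarray]:
    """n well-separated centers in the box (grid with jitter)."""
    m = int(math.ceil(n ** (1.0 / 3.0)))
    cell = box / m
    if min_sep and cell < min_sep:
        raise ValueError("box too small to separate fixture components")
    slots = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]
    rng.shuffle(slots)
    out = []
    for i, j, k in slots[:n]:
        jitter = rng.uniform(-0.05, 0.05, size=3) * cell
        out.append((np.array([i, j, k]) + 0.5) * cell + jitter)
    return out
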