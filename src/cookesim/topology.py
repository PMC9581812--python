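"""Molecular topologies: the 3-bead lipid and the 42-bead rigid peptide.

The lipid is a linear H-T-T trimer: two FENE bonds chain the beads and a
harmonic spring between the head and the second tail bead (rest length
4 sigma, which the chain can never reach) keeps it straight.

The peptide is a coarse amphipathic helix mimic: 42 beads arranged as a
stack of 6 filled hexagons (one center + six vertices per layer), held
nearly rigid by a fully connected elastic network — every intra-layer pair
and every pair of beads in adjacent layers is bonded, so an end-layer bead
has 13 bonds and a middle-layer bead 20.  Eight beads are hydrophobic,
forming a contiguous 2-wide stripe on one face of the middle four layers;
the two end layers are entirely hydrophilic caps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import CLASS_H, CLASS_T, KIND_LIPID, KIND_PEPTIDE

LIPID_N_BEADS = 3
PEPTIDE_N_LAYERS = 6
PEPTIDE_BEADS_PER_LAYER = 7
PEPTIDE_N_BEADS = PEPTIDE_N_LAYERS * PEPTIDE_BEADS_PER_LAYER

#: hexagon vertex-ring radius and inter-layer spacing, in sigma.  Chosen to
#: match the hydrophilic bead size so the network is near zero strain.
PEPTIDE_RING_RADIUS = 0.95
PEPTIDE_LAYER_SPACING = 0.95
#: default hydrophobic stripe: vertex slots 0 and 1 on layers 1..4 (0-based)
DEFAULT_STRIPE_VERTICES = (0, 1)
DEFAULT_STRIPE_LAYERS = (1, 2, 3, 4)

#: lipid build spacing along the molecular axis, in sigma
LIPID_BOND_SPACING = 1.0


@dataclass(frozen=True)
class BeadSpec:
    index: int
    bead_class: int          # CLASS_H or CLASS_T
    molecule_id: int
    molecule_kind: int       # KIND_LIPID or KIND_PEPTIDE
    layer: int = -1          # hexagon layer for peptides, -1 for lipids


@dataclass
class Topology:
    """Beads plus typed bond lists and the build-time reference geometry."""

    beads: list[BeadSpec] = field(default_factory=list)
    fene_bonds: list[tuple[int, int]] = field(default_factory=list)
    harmonic_bonds: list[tuple[int, int, float]] = field(default_factory=list)
    elastic_bonds: list[tuple[int, int, float]] = field(default_factory=list)
    reference_coords: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_molecules(self) -> int:
        return 0 if not self.beads else self.beads[-1].molecule_id + 1

    def bead_classes(self) -> np.ndarray:
        return np.array([b.bead_class for b in self.beads], dtype=np.int8)

    def bead_kinds(self) -> np.ndarray:
        return np.array([b.molecule_kind for b in self.beads], dtype=np.int8)

    def bead_types(self) -> np.ndarray:
        """Combined (class, kind) type index per bead, for the kernels."""
        return (2 * self.bead_classes() + self.bead_kinds()).astype(np.int8)

    def molecule_ids(self) -> np.ndarray:
        return np.array([b.molecule_id for b in self.beads], dtype=np.int32)

    def molecule_kind_of(self, mol_id: int) -> int:
        for b in self.beads:
            if b.molecule_id == mol_id:
                return b.molecule_kind
        raise KeyError(mol_id)

    def molecule_slices(self) -> list[np.ndarray]:
        """Bead indices per molecule, in molecule-id order."""
        mol = self.molecule_ids()
        return [np.flatnonzero(mol == m) for m in range(self.n_molecules)]

    def hydrophobic_mask(self) -> np.ndarray:
        return self.bead_classes() == CLASS_T

    def bond_degree(self, index: int) -> int:
        """Total bonds (all types) incident on a bead."""
        n = 0
        for i, j in self.fene_bonds:
            n += (i == index) + (j == index)
        for i, j, _ in self.harmonic_bonds:
            n += (i == index) + (j == index)
        for i, j, _ in self.elastic_bonds:
            n += (i == index) + (j == index)
        return n

    def validate(self) -> None:
        """Check for self-bonds and duplicate bonds across all bond lists."""
        seen: set[tuple[int, int]] = set()
        all_pairs = [(i, j) for i, j in self.fene_bonds]
        all_pairs += [(i, j) for i, j, _ in self.harmonic_bonds]
        all_pairs += [(i, j) for i, j, _ in self.elastic_bonds]
        for i, j in all_pairs:
            if i == j:
                raise ValueError(f"self-bond on bead {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    # --- export -------------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "beads": [
                {"index": b.index, "class": "HT"[b.bead_class],
                 "molecule_id": b.molecule_id,
                 "kind": ("lipid", "peptide")[b.molecule_kind],
                 "layer": b.layer}
                for b in self.beads
            ],
            "fene_bonds": [list(b) for b in self.fene_bonds],
            "harmonic_bonds": [[i, j, r0] for i, j, r0 in self.harmonic_bonds],
            "elastic_bonds": [[i, j, r0] for i, j, r0 in self.elastic_bonds],
            "reference_coords": self.reference_coords.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def from_json_dict(cls, d: dict) -> "Topology":
        beads = [BeadSpec(index=b["index"],
                          bead_class={"H": CLASS_H, "T": CLASS_T}[b["class"]],
                          molecule_id=b["molecule_id"],
                          molecule_kind={"lipid": KIND_LIPID,
                                         "peptide": KIND_PEPTIDE}[b["kind"]],
                          layer=b.get("layer", -1))
                 for b in d["beads"]]
        return cls(
            beads=beads,
            fene_bonds=[tuple(b) for b in d["fene_bonds"]],
            harmonic_bonds=[(i, j, r0) for i, j, r0 in d["harmonic_bonds"]],
            elastic_bonds=[(i, j, r0) for i, j, r0 in d["elastic_bonds"]],
            reference_coords=np.asarray(d["reference_coords"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))

    def to_pdb(self, path, coords_nm: np.ndarray | None = None) -> None:
        """Minimal PDB export for visualization.

        One residue per molecule; the element field encodes the bead class
        (N for hydrophilic, C for hydrophobic).
        """
        coords = self.reference_coords * 10.0 if coords_nm is None \
            else np.asarray(coords_nm) * 10.0  # nm -> Angstrom
        with open(path, "w") as fh:
            for b, (x, y, z) in zip(self.beads, coords):
                res = ("LIP", "PEP")[b.molecule_kind]
                elem = "N" if b.bead_class == CLASS_H else "C"
                name = ("H" if b.bead_class == CLASS_H else "T")
                fh.write(
                    f"ATOM  {b.index + 1:>5d} {name:<4s}{res:>4s} A"
                    f"{(b.molecule_id % 9999) + 1:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {elem:>2s}\n")
            fh.write("END\n")


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------

def build_lipid(molecule_id: int = 0, first_index: int = 0) -> Topology:
    """One H-T-T lipid: 2 FENE bonds plus the 4-sigma straightening spring."""
    beads = [
        BeadSpec(first_index + 0, CLASS_H, molecule_id, KIND_LIPID),
        BeadSpec(first_index + 1, CLASS_T, molecule_id, KIND_LIPID),
        BeadSpec(first_index + 2, CLASS_T, molecule_id, KIND_LIPID),
    ]
    i0 = first_index
    coords = np.array([[0.0, 0.0, 0.0],
                       [0.0, 0.0, -LIPID_BOND_SPACING],
                       [0.0, 0.0, -2.0 * LIPID_BOND_SPACING]])
    return Topology(
        beads=beads,
        fene_bonds=[(i0, i0 + 1), (i0 + 1, i0 + 2)],
        harmonic_bonds=[(i0, i0 + 2, 4.0)],
        elastic_bonds=[],
        reference_coords=coords,
    )


def peptide_reference_coords(
        ring_radius: float = PEPTIDE_RING_RADIUS,
        layer_spacing: float = PEPTIDE_LAYER_SPACING) -> np.ndarray:
    """Reference geometry: 6 aligned hexagon layers stacked along z.

    Bead order per layer: center first, then the 6 vertices at 60-degree
    increments starting on the +x axis.
    """
    coords = np.zeros((PEPTIDE_N_BEADS, 3))
    for layer in range(PEPTIDE_N_LAYERS):
        z = layer * layer_spacing
        base = layer * PEPTIDE_BEADS_PER_LAYER
        coords[base] = (0.0, 0.0, z)
        for v in range(6):
            ang = math.pi / 3.0 * v
            coords[base + 1 + v] = (ring_radius * math.cos(ang),
                                    ring_radius * math.sin(ang), z)
    return coords


def build_peptide(molecule_id: int = 0, first_index: int = 0,
                  stripe_vertices: tuple[int, ...] = DEFAULT_STRIPE_VERTICES,
                  stripe_layers: tuple[int, ...] = DEFAULT_STRIPE_LAYERS,
                  ring_radius: float = PEPTIDE_RING_RADIUS,
                  layer_spacing: float = PEPTIDE_LAYER_SPACING) -> Topology:
    """The 42-bead hexagonal-stack peptide with its elastic network.

    ``stripe_vertices`` / ``stripe_layers`` place the 8 hydrophobic beads;
    the default is a contiguous 2-wide stripe on one face of the middle
    four layers, mimicking the hydrophobic face of an amphipathic helix
    with hydrophilic end caps.
    """
    coords = peptide_reference_coords(ring_radius, layer_spacing)
    stripe = {(layer, v) for layer in stripe_layers for v in stripe_vertices}
    beads = []
    for k in range(PEPTIDE_N_BEADS):
        layer, slot = divmod(k, PEPTIDE_BEADS_PER_LAYER)
        is_t = slot >= 1 and (layer, slot - 1) in stripe
        beads.append(BeadSpec(first_index + k,
                              CLASS_T if is_t else CLASS_H,
                              molecule_id, KIND_PEPTIDE, layer=layer))

    elastic: list[tuple[int, int, float]] = []

    def add(a: int, b: int) -> None:
        r0 = float(np.linalg.norm(coords[a] - coords[b]))
        elastic.append((first_index + a, first_index + b, r0))

    for layer in range(PEPTIDE_N_LAYERS):
        base = layer * PEPTIDE_BEADS_PER_LAYER
        members = range(base, base + PEPTIDE_BEADS_PER_LAYER)
        # all 21 intra-layer pairs
        for a in members:
            for b in members:
                if a < b:
                    add(a, b)
        # all 49 pairs with the next layer
        if layer + 1 < PEPTIDE_N_LAYERS:
            nxt = range(base + PEPTIDE_BEADS_PER_LAYER,
                        base + 2 * PEPTIDE_BEADS_PER_LAYER)
            for a in members:
                for b in nxt:
                    add(a, b)

    return Topology(beads=beads, fene_bonds=[], harmonic_bonds=[],
                    elastic_bonds=elastic, reference_coords=coords)


def assemble_system(n_lipids: int, n_peptides: int, **peptide_kwargs
                    ) -> Topology:
    """Concatenate ``n_lipids`` lipids followed by ``n_peptides`` peptides."""
    if n_lipids < 0 or n_peptides < 0:
        raise ValueError("molecule counts must be >= 0")
    topo = Topology()
    coords = []
    index = 0
    mol = 0
    for _ in range(n_lipids):
        frag = build_lipid(molecule_id=mol, first_index=index)
        topo.beads += frag.beads
        topo.fene_bonds += frag.fene_bonds
        topo.harmonic_bonds += frag.harmonic_bonds
        coords.append(frag.reference_coords)
        index += frag.n_beads
        mol += 1
    for _ in range(n_peptides):
        frag = build_peptide(molecule_id=mol, first_index=index,
                             **peptide_kwargs)
        topo.beads += frag.beads
        topo.elastic_bonds += frag.elastic_bonds
        coords.append(frag.reference_coords)
        index += frag.n_beads
        mol += 1
    topo.reference_coords = (np.vstack(coords) if coords
                             else np.zeros((0, 3)))
    return topo
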