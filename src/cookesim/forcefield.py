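"""Interaction potentials of the implicit-solvent coarse-grained model.

The force field has four terms:

* a Weeks-Chandler-Andersen (WCA) repulsion setting bead excluded volume,
  with bead-class dependent diameters ``b_HH = b_HT = 0.95 sigma`` and
  ``b_TT = sigma``;
* a broadened cosine-squared attraction of depth ``epsilon`` and width
  ``w_c`` acting only between hydrophobic (T) beads when at least one of
  the pair belongs to a lipid — this is how hydrophobicity is encoded
  without explicit water;
* FENE bonds (stiffness ``30 eps/sigma^2``, divergence length
  ``1.5 sigma``) chaining the three lipid beads;
* harmonic bonds: the lipid straightening spring between head and second
  tail bead (stiffness ``10 eps/sigma^2``, rest length ``4 sigma``, which
  is unreachable and therefore acts as a pure straightening bias), and the
  stiff elastic network (``30 eps/sigma^2``) that keeps the peptide rigid.

All functions operate in reduced units (sigma = epsilon = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .units import Units

# bead class codes
CLASS_H = 0  # hydrophilic
CLASS_T = 1  # hydrophobic
# molecule kind codes
KIND_LIPID = 0
KIND_PEPTIDE = 1

#: number of combined (class, kind) bead types
N_TYPES = 4


def bead_type(bead_class: int, kind: int) -> int:
    """Combined type index: H/lipid=0, H/peptide=1, T/lipid=2, T/peptide=3."""
    return 2 * bead_class + kind


class OverlapError(ValueError):
    """Two beads are closer than the numerical-overflow guard distance."""


class BondOverextensionError(RuntimeError):
    """A FENE bond reached its divergence length; the run is unstable."""


@dataclass
class ForceFieldParams:
    """All interaction constants, in reduced units (sigma = epsilon = 1)."""

    sigma: float = 1.0
    epsilon: float = 1.0
    b_HH: float = 0.95
    b_HT: float = 0.95
    b_TT: float = 1.0
    w_c: float = 1.0                 # attraction width where it applies
    k_bond: float = 30.0             # FENE stiffness, eps/sigma^2
    r_inf: float = 1.5               # FENE divergence length
    k_bend: float = 10.0             # lipid straightening spring
    r_bend0: float = 4.0             # straightening rest length
    k_elastic: float = 30.0          # peptide elastic network
    temperature_K: float = 310.0
    r_floor_frac: float = 0.3        # overlap guard: r_min = frac * b
    units: Units = field(default_factory=Units)

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")
        for name in ("b_HH", "b_HT", "b_TT", "w_c", "k_bond", "k_bend",
                     "k_elastic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # ------------------------------------------------------------------
    @property
    def kT(self) -> float:
        """Thermal energy at the configured temperature, reduced units."""
        return self.units.kT(self.temperature_K)

    def b_pair(self, class_i: int, class_j: int) -> float:
        """WCA diameter for a bead-class pair."""
        if class_i == CLASS_T and class_j == CLASS_T:
            return self.b_TT * self.sigma
        if class_i == CLASS_H and class_j == CLASS_H:
            return self.b_HH * self.sigma
        return self.b_HT * self.sigma

    def wc_pair(self, class_i: int, class_j: int,
                kind_i: int, kind_j: int) -> float:
        """Attraction width for a pair.

        Nonzero (= sigma) only for hydrophobic-hydrophobic pairs where at
        least one bead belongs to a lipid; in particular peptide-peptide
        attraction is zero (the peptide alone does not aggregate).
        """
        if class_i == CLASS_T and class_j == CLASS_T and (
                kind_i == KIND_LIPID or kind_j == KIND_LIPID):
            return self.w_c * self.sigma
        return 0.0

    def r_cut(self, class_i: int, class_j: int) -> float:
        """WCA cutoff 2^(1/6) b for the pair."""
        return 2.0 ** (1.0 / 6.0) * self.b_pair(class_i, class_j)

    @property
    def max_interaction_range(self) -> float:
        """Largest r_c + w_c over all pairs (the neighbor-list cutoff)."""
        return 2.0 ** (1.0 / 6.0) * max(self.b_HH, self.b_HT, self.b_TT) \
            * self.sigma + self.w_c * self.sigma

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(b, w_c) lookup tables indexed by combined bead type.

        Used by the vectorized force kernels; entries follow ``b_pair`` and
        ``wc_pair`` exactly.
        """
        b_tab = np.empty((N_TYPES, N_TYPES))
        wc_tab = np.empty((N_TYPES, N_TYPES))
        for ti in range(N_TYPES):
            for tj in range(N_TYPES):
                ci, ki = divmod(ti, 2)
                cj, kj = divmod(tj, 2)
                b_tab[ti, tj] = self.b_pair(ci, cj)
                wc_tab[ti, tj] = self.wc_pair(ci, cj, ki, kj)
        return b_tab, wc_tab

    # --- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = asdict(self.units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        d = dict(d)
        if "units" in d:
            d["units"] = Units(**d["units"])
        return cls(**d)


# ----------------------------------------------------------------------
# scalar potentials (reference implementations; the dynamics kernels in
# _kernels.py are validated against these in the test suite)
# ----------------------------------------------------------------------

def v_rep(r: float, b: float, epsilon: float = 1.0) -> float:
    """WCA repulsion: 4 eps [(b/r)^12 - (b/r)^6 + 1/4] for r <= 2^(1/6) b."""
    if r <= 0 or b <= 0:
        raise ValueError("r and b must be positive")
    rc = 2.0 ** (1.0 / 6.0) * b
    if r > rc:
        return 0.0
    x6 = (b / r) ** 6
    return 4.0 * epsilon * (x6 * x6 - x6 + 0.25)


def v_att(r: float, w_c: float, b: float, epsilon: float = 1.0) -> float:
    """Broadened attraction: -eps inside r_c, cos^2 ramp to 0 over w_c.

    The ramp is ``-eps cos^2[pi (r - r_c) / (2 w_c)]``; the minus sign is
    required for continuity with the -eps plateau at r_c and the zero tail
    at r_c + w_c.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if w_c < 0:
        raise ValueError("w_c must be >= 0")
    if w_c == 0.0:
        return 0.0
    rc = 2.0 ** (1.0 / 6.0) * b
    if r < rc:
        return -epsilon
    if r > rc + w_c:
        return 0.0
    c = np.cos(np.pi * (r - rc) / (2.0 * w_c))
    return -epsilon * c * c


def v_fene(r: float, k_bond: float = 30.0, r_inf: float = 1.5) -> float:
    """FENE bond: -(1/2) k r_inf^2 log[1 - (r/r_inf)^2]; diverges at r_inf."""
    if r < 0:
        raise ValueError("r must be >= 0")
    if r >= r_inf:
        raise BondOverextensionError(
            f"FENE bond stretched to r={r:.4f} >= r_inf={r_inf:.4f}")
    x = r / r_inf
    return -0.5 * k_bond * r_inf ** 2 * np.log1p(-x * x)


def v_bend(r: float, k_bend: float = 10.0, r0: float = 4.0) -> float:
    """Lipid straightening spring: (1/2) k (r - 4 sigma)^2."""
    if r < 0:
        raise ValueError("r must be >= 0")
    return 0.5 * k_bend * (r - r0) ** 2


def v_elastic(r: float, r0: float, k_elastic: float = 30.0) -> float:
    """Elastic-network bond: (1/2) k (r - r0)^2 with build-time rest length."""
    if r < 0:
        raise ValueError("r must be >= 0")
    return 0.5 * k_elastic * (r - r0) ** 2


def pair_energy_force(r_vec: np.ndarray, class_i: int, class_j: int,
                      kind_i: int, kind_j: int,
                      params: ForceFieldParams) -> tuple[float, np.ndarray]:
    """Nonbonded energy and force on bead i for a minimum-image displacement.

    ``r_vec`` points from j to i; the returned force acts on i and the force
    on j is its negative.  Raises :class:`OverlapError` below the guard
    distance ``r_floor_frac * b`` where the r^-12 term would overflow any
    sensible integrator.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    b = params.b_pair(class_i, class_j)
    wc = params.wc_pair(class_i, class_j, kind_i, kind_j)
    eps = params.epsilon
    if r < params.r_floor_frac * b:
        raise OverlapError(f"beads at r={r:.4f} below guard {params.r_floor_frac * b:.4f}")
    rc = 2.0 ** (1.0 / 6.0) * b
    energy = v_rep(r, b, eps) + (v_att(r, wc, b, eps) if wc > 0 else 0.0)
    # dV/dr
    dvdr = 0.0
    if r <= rc:
        x6 = (b / r) ** 6
        dvdr += 4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) / r
    elif wc > 0 and r <= rc + wc:
        u = np.pi * (r - rc) / (2.0 * wc)
        dvdr += eps * np.pi / (2.0 * wc) * np.sin(2.0 * u)
    force = -dvdr / r * r_vec
    return energy, force
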