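"""Reduced-unit system and conversions.

Internally everything is expressed in reduced units with the bead diameter
``sigma`` as the length unit and the pair-attraction depth ``epsilon`` as the
energy unit.  The physical mapping used throughout is

* ``sigma``   = 0.6 nm
* ``epsilon`` = 1 kcal/mol
* bead mass   = 100 amu (uniform; NVT equilibrium statistics are
  mass-independent, so the value only sets the time scale)

which gives a reduced time unit ``tau = sigma * sqrt(mass / epsilon)``
of about 2.933 ps.  The thermal energy at 310 K is kT ~= 0.616 epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_PER_MOL_K = 0.0019872041
#: Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23
#: kcal/mol expressed in the md unit amu nm^2 ps^-2 (= kJ/mol)
KCAL_PER_MOL_IN_KJ = 4.184


@dataclass(frozen=True)
class Units:
    """Conversion layer between reduced units and (nm, kcal/mol, fs, amu)."""

    sigma_nm: float = 0.6
    epsilon_kcal_mol: float = 1.0
    mass_amu: float = 100.0

    @property
    def tau_ps(self) -> float:
        """Reduced time unit in picoseconds."""
        eps_md = self.epsilon_kcal_mol * KCAL_PER_MOL_IN_KJ  # amu nm^2/ps^2
        return self.sigma_nm * math.sqrt(self.mass_amu / eps_md)

    # --- lengths -------------------------------------------------------
    def nm_to_sigma(self, x_nm: float) -> float:
        return x_nm / self.sigma_nm

    def sigma_to_nm(self, x_sigma: float) -> float:
        return x_sigma * self.sigma_nm

    # --- times ---------------------------------------------------------
    def fs_to_tau(self, t_fs: float) -> float:
        return t_fs * 1e-3 / self.tau_ps

    def tau_to_fs(self, t_tau: float) -> float:
        return t_tau * self.tau_ps * 1e3

    def per_ps_to_per_tau(self, rate_per_ps: float) -> float:
        return rate_per_ps * self.tau_ps

    # --- energies ------------------------------------------------------
    def kT(self, temperature_K: float) -> float:
        """Thermal energy at ``temperature_K`` in reduced energy units."""
        return KB_KCAL_PER_MOL_K * temperature_K / self.epsilon_kcal_mol

    def kelvin_from_kinetic(self, ke_per_dof: float) -> float:
        """Map mean kinetic energy per degree of freedom (reduced) to K."""
        return 2.0 * ke_per_dof * self.epsilon_kcal_mol / KB_KCAL_PER_MOL_K


DEFAULT_UNITS = Units()
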