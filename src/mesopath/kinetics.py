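"""Closed-form first-binding-time estimation for a finite simulation cell.

For a bimolecular association P + L -> C with rate constant k_on, the
initial rate of complex formation is k_on * P0 * L0. In a simulation cell
of volume V with n_sites empty protein sites and n_ligands free ligand
copies, P0 = n_sites / (N_A V) and L0 = n_ligands / (N_A V), and a single
binding event changes the complex concentration by 1 / (N_A V). Inverting
the finite-difference rate equation for the time of that first event gives

    dt = (1 / (N_A V)) / (k_on P0 L0) = N_A V / (n_sites n_ligands k_on),

the expected waiting time for the first association starting from
all-sites-empty. The same quantity is the mean of the exponential
first-event distribution with propensity
a0 = k_on n_sites n_ligands / (N_A V), so the closed form and the
stochastic (Gillespie-style) model agree exactly, not just asymptotically.

Units: k_on in M^-1 s^-1, volumes in Angstrom^3 (1 A^3 = 1e-27 L),
times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = [
    "ReactionSystem",
    "kon_from_equilibrium",
    "koff_from_residence_time",
    "koff_from_half_life",
    "mean_first_binding_time",
    "A3_TO_L",
]

A3_TO_L = 1e-27


def kon_from_equilibrium(k_off: float, K_D: float) -> float:
    """k_on = k_off / K_D (K_D and the inhibition constant K_i are
    used interchangeably for a simple one-step binder)."""
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    return k_off / K_D


def koff_from_residence_time(tau: float) -> float:
    """k_off = 1 / tau for a residence time tau in seconds."""
    if tau <= 0:
        raise ValueError("residence time must be positive")
    return 1.0 / tau


def koff_from_half_life(t_half: float) -> float:
    """k_off = ln 2 / t_half for a dissociation half-life in seconds."""
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / t_half


@dataclass
class ReactionSystem:
    """Kinetic constants plus simulation-cell composition.

    Supply ``k_on`` directly, or ``k_off`` and ``K_D`` (then
    k_on = k_off / K_D). If all three are given they must be consistent.
    """

    V_cell: float  # Angstrom^3
    n_sites: int
    n_ligands: int
    k_on: float | None = None  # M^-1 s^-1
    k_off: float | None = None  # s^-1
    K_D: float | None = None  # M

    def __post_init__(self) -> None:
        if self.V_cell <= 0:
            raise ValueError("cell volume must be positive")
        if self.n_sites <= 0 or self.n_ligands <= 0:
            raise ValueError("site and ligand counts must be positive")
        if self.k_on is None:
            if self.k_off is None or self.K_D is None:
                raise ValueError("supply k_on, or both k_off and K_D")
            self.k_on = kon_from_equilibrium(self.k_off, self.K_D)
        elif self.k_off is not None and self.K_D is not None:
            implied = kon_from_equilibrium(self.k_off, self.K_D)
            if abs(implied - self.k_on) > 1e-9 * abs(self.k_on):
                raise ValueError(
                    f"inconsistent constants: k_off/K_D = {implied:g} "
                    f"but k_on = {self.k_on:g}"
                )
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")

    @property
    def volume_molar(self) -> float:
        """N_A * V in M^-1 (per-copy concentration denominator)."""
        return Avogadro * self.V_cell * A3_TO_L

    @property
    def P0(self) -> float:
        """Initial free-site concentration, M."""
        return self.n_sites / self.volume_molar

    @property
    def L0(self) -> float:
        """Initial free-ligand concentration, M."""
        return self.n_ligands / self.volume_molar


def mean_first_binding_time(system: ReactionSystem) -> float:
    """Expected time (s) to the first binding event from all-sites-empty.

    dt = N_A V / (n_sites * n_ligands * k_on); equals the mean of the
    exponential first-event time with propensity
    a0 = k_on * n_sites * n_ligands / (N_A V).
    """
    return system.volume_molar / (system.n_sites * system.n_ligands * system.k_on)
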