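"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the data a binding study would produce:

* multi-basin trajectories — frames scatter (Gaussian, isotropic) around
  per-state reference conformations visited by a known Markov chain,
  optionally subjected to random rigid motions so that alignment
  invariance is exercised downstream;
* restrained (umbrella) sampling on a known 1-D potential, either by the
  closed-form Boltzmann Gaussian (harmonic/linear potentials) or by
  overdamped Langevin dynamics (any potential);
* stochastic bimolecular first-binding events in a finite cell — the
  waiting time of the first association is exponential with propensity
  a0 = k_on * n_sites * n_ligands / (N_A V).

These are statistical stand-ins, not molecular models: no force field, no
solvent, no protein. Everything is reproducible bit-for-bit under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro
from scipy.spatial.transform import Rotation

from .geometry import Trajectory
from .kinetics import A3_TO_L

__all__ = [
    "MesostateModel",
    "Potential1D",
    "make_separated_references",
    "gen_mesostate_trajectory",
    "gen_restrained_samples",
    "gen_binding_event_times",
    "KBT_300K_KCAL",
]

#: k_B T at ~300 K in kcal/mol.
KBT_300K_KCAL = 0.596


@dataclass
class MesostateModel:
    """A hidden-Markov-style multi-basin conformational model.

    Frames are ``reference_conformations[state] + N(0, noise_sigma^2)``
    per coordinate, with the state sequence a Markov chain over the
    row-stochastic ``transition_matrix`` starting in state 0. With
    ``rigid_motion`` each frame additionally receives a uniformly random
    rotation and a translation uniform in ``[-box/2, box/2]^3``.
    """

    reference_conformations: np.ndarray  # (n_states, n_atoms, 3), Angstrom
    transition_matrix: np.ndarray  # (n_states, n_states), row-stochastic
    noise_sigma: float = 0.0  # Angstrom
    rigid_motion: bool = False
    box: float = 20.0  # Angstrom, translation range for rigid motions
    seed: int | None = None

    def __post_init__(self) -> None:
        self.reference_conformations = np.asarray(self.reference_conformations, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        refs, T = self.reference_conformations, self.transition_matrix
        if refs.ndim != 3 or refs.shape[2] != 3:
            raise ValueError("reference_conformations must be (n_states, n_atoms, 3)")
        if refs.shape[1] < 3:
            raise ValueError("need at least 3 atoms per conformation")
        if T.shape != (refs.shape[0], refs.shape[0]):
            raise ValueError("transition matrix shape mismatch")
        if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must be stochastic (sum to 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def n_states(self) -> int:
        return self.reference_conformations.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.reference_conformations.shape[1]


def make_separated_references(
    n_states: int,
    n_atoms: int,
    separation: float,
    seed: int | None = None,
    spread: float = 2.0,
) -> np.ndarray:
    """Reference conformations with a guaranteed minimum *shape* separation.

    States differing only by a rigid motion are indistinguishable after
    superposition, so separation must live in internal geometry: each
    state's atoms are drawn independently (isotropic Gaussian, sd
    ``spread``) and all conformations are rescaled so the minimum pairwise
    Kabsch-aligned RMSD equals ``separation`` (Angstrom) exactly.
    """
    from .geometry import Frame, SelectionPair, rmsd as _rmsd

    if n_states < 2:
        raise ValueError("need at least 2 states")
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    refs = rng.normal(0.0, spread, size=(n_states, n_atoms, 3))
    sel = SelectionPair(np.arange(n_atoms), np.arange(n_atoms))
    dmin = min(
        _rmsd(Frame(refs[i]), Frame(refs[j]), sel)
        for i in range(n_states)
        for j in range(i + 1, n_states)
    )
    return refs * (separation / dmin)


def gen_mesostate_trajectory(
    model: MesostateModel, n_frames: int
) -> tuple[Trajectory, np.ndarray]:
    """Sample a trajectory and its ground-truth state labels."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed)
    states = np.empty(n_frames, dtype=int)
    states[0] = 0
    cumT = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        states[t] = int(np.searchsorted(cumT[states[t - 1]], u[t - 1], side="right"))
    coords = model.reference_conformations[states].copy()
    if model.noise_sigma > 0:
        coords += rng.normal(0.0, model.noise_sigma, size=coords.shape)
    if model.rigid_motion:
        R = Rotation.random(n_frames, random_state=rng).as_matrix()
        t = rng.uniform(-model.box / 2, model.box / 2, size=(n_frames, 3))
        coords = np.einsum("fij,faj->fai", R, coords) + t[:, None, :]
    n_atoms = model.n_atoms
    traj = Trajectory(
        coords=coords,
        atom_names=[f"C{i}" for i in range(n_atoms)],
        elements=["C"] * n_atoms,
    )
    return traj, states


@dataclass
class Potential1D:
    """A 1-D test potential with an analytic derivative.

    Forms (energy in k_B T unless stated otherwise by the caller):

    * ``harmonic``: U(s) = (a / 2) (s - s0)^2, params ``a`` (>= 0), ``s0``.
    * ``linear``: U(s) = g s, param ``g``.
    * ``double_well``: U(s) = h (((s - s0) / w)^2 - 1)^2, params ``h``
      (barrier height), ``s0`` (midpoint, default 0), ``w`` (half well
      separation, default 1); stationary at s0 +/- w.
    """

    form: str
    params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (-2.0, 2.0)

    _FORMS = ("harmonic", "linear", "double_well")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown form {self.form!r}; use one of {self._FORMS}")
        if self.domain[0] >= self.domain[1]:
            raise ValueError("domain must be an increasing interval")

    def _p(self, key: str, default: float) -> float:
        return float(self.params.get(key, default))

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        if self.form == "harmonic":
            return 0.5 * self._p("a", 1.0) * (s - self._p("s0", 0.0)) ** 2
        if self.form == "linear":
            return self._p("g", 1.0) * s
        h, s0, w = self._p("h", 1.0), self._p("s0", 0.0), self._p("w", 1.0)
        return h * (((s - s0) / w) ** 2 - 1.0) ** 2

    def derivative(self, s):
        s = np.asarray(s, dtype=float)
        if self.form == "harmonic":
            return self._p("a", 1.0) * (s - self._p("s0", 0.0))
        if self.form == "linear":
            return self._p("g", 1.0) * np.ones_like(s)
        h, s0, w = self._p("h", 1.0), self._p("s0", 0.0), self._p("w", 1.0)
        x = (s - s0) / w
        return 4.0 * h * x * (x * x - 1.0) / w

    def scalar_derivative(self):
        """A fast scalar U'(s) closure for tight integrator loops."""
        if self.form == "harmonic":
            a, s0 = self._p("a", 1.0), self._p("s0", 0.0)
            return lambda s: a * (s - s0)
        if self.form == "linear":
            g = self._p("g", 1.0)
            return lambda s: g
        h, s0, w = self._p("h", 1.0), self._p("s0", 0.0), self._p("w", 1.0)
        return lambda s: 4.0 * h * ((s - s0) / w) * (((s - s0) / w) ** 2 - 1.0) / w

    def max_curvature(self) -> float:
        """max |U''| over the domain (used to pick a stable Langevin step)."""
        grid = np.linspace(self.domain[0], self.domain[1], 1001)
        eps = (self.domain[1] - self.domain[0]) * 1e-6
        second = (self.derivative(grid + eps) - self.derivative(grid - eps)) / (2 * eps)
        return float(np.max(np.abs(second)))


def gen_restrained_samples(
    potential: Potential1D,
    kappa: float,
    center: float,
    n_samples: int,
    method: str = "exact_gaussian",
    seed: int | None = None,
    kBT: float = 1.0,
    stride: int = 10,
) -> np.ndarray:
    """Draw s under the Boltzmann weight of U(s) + (kappa/2)(s - center)^2.

    ``exact_gaussian`` uses the closed form (harmonic or linear U only):
    the biased density is Gaussian with precision (a + kappa)/kBT and mean
    (a s0 + kappa c)/(a + kappa) (harmonic), or mean c - g/kappa and
    variance kBT/kappa (linear). ``overdamped_langevin`` integrates
    Euler-Maruyama with unit friction, time step chosen so that
    dt * max|U_tot''| <= 0.1, keeps every ``stride``-th step and discards a
    10% burn-in. Energies (kappa, U, kBT) must share one unit.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if kBT <= 0:
        raise ValueError("kBT must be positive")
    rng = np.random.default_rng(seed)

    if method == "exact_gaussian":
        if potential.form == "harmonic":
            a = potential._p("a", 1.0)
            s0 = potential._p("s0", 0.0)
            mean = (a * s0 + kappa * center) / (a + kappa)
            var = kBT / (a + kappa)
        elif potential.form == "linear":
            g = potential._p("g", 1.0)
            mean = center - g / kappa
            var = kBT / kappa
        else:
            raise ValueError(
                "exact_gaussian supports harmonic or linear potentials only; "
                "use overdamped_langevin for double_well"
            )
        return rng.normal(mean, math.sqrt(var), size=n_samples)

    if method != "overdamped_langevin":
        raise ValueError(f"unknown method {method!r}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    dt = 0.1 / (potential.max_curvature() + kappa)
    n_prod = n_samples * stride
    n_burn = int(math.ceil(0.1 * n_prod))
    noise = rng.normal(0.0, math.sqrt(2.0 * kBT * dt), size=n_prod + n_burn).tolist()
    dU = potential.scalar_derivative()
    s = float(center)
    out = np.empty(n_samples)
    k = 0
    for t in range(n_prod + n_burn):
        s = s - (dU(s) + kappa * (s - center)) * dt + noise[t]
        if t >= n_burn and (t - n_burn) % stride == stride - 1:
            out[k] = s
            k += 1
    return out


def gen_binding_event_times(
    kon: float,
    cell_volume: float,
    n_sites: int,
    n_ligands: int,
    n_reps: int,
    seed: int | None = None,
) -> np.ndarray:
    """First-binding waiting times (s) for ``n_reps`` independent cells.

    The first association out of all-sites-empty has total propensity
    a0 = kon * n_sites * n_ligands / (N_A V), so the waiting time is
    exponential with mean 1/a0 (the single-step Gillespie draw).
    """
    if kon <= 0 or cell_volume <= 0:
        raise ValueError("kon and cell_volume must be positive")
    if n_sites < 1 or n_ligands < 1 or n_reps < 1:
        raise ValueError("counts must be positive")
    a0 = kon * n_sites * n_ligands / (Avogadro * cell_volume * A3_TO_L)
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / a0, size=n_reps)
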