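"""Synthetic input generators with exact ground truth.

Every downstream statistic in this package is validated on inputs produced
here: two-state Markov contact dynamics (stationary occupancy and correlation
time are exact by construction), Gaussian positional ensembles with a
prescribed covariance, single hydrogen-bond geometries, harmonic-oscillator
alchemical ladders with closed-form free energies, and overdamped Langevin
dynamics on analytic 1D/2D potentials.  Each generator takes an explicit seed
and is bit-reproducible; none touches global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_selection import AtomMeta, Structure, Trajectory
from .units import KB

__all__ = [
    "MarkovContactSpec",
    "MarkovContactTruth",
    "HarmonicEnsembleSpec",
    "gen_markov_contact",
    "gen_harmonic_ensemble",
    "gen_hbond_frame",
    "gen_alchemical_harmonics",
    "gen_langevin",
    "Harmonic1D",
    "DoubleWell1D",
    "Separable2D",
]


# --------------------------------------------------------------------------
# Two-state Markov contact dynamics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovContactSpec:
    """Two-state (bound/unbound) contact process.

    The hidden chain has stationary occupancy ``p_on`` and exponential
    relaxation time ``tau`` (ps).  Interaction energies are drawn per state
    (attractive-negative convention for the bound state); the probe atom sits
    at COM distance ``d_on``/``d_off`` (nm) from a fixed target atom.
    """

    p_on: float = 0.3
    tau: float = 10.0
    dt: float = 1.0
    n_frames: int = 5000
    e_on_mean: float = -120.0
    e_on_sd: float = 10.0
    e_off_mean: float = -10.0
    e_off_sd: float = 10.0
    d_on: float = 0.4
    d_off: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_on <= 1.0:
            raise ValueError("p_on must be in (0, 1]")
        if self.tau < self.dt:
            raise ValueError("tau must be >= dt")
        if not self.d_on < self.d_off:
            raise ValueError("d_on must be < d_off")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class MarkovContactTruth:
    """Exact hidden state path and the parameters that generated it."""

    states: np.ndarray  # (F,) in {0,1}
    p_on: float
    tau: float
    dt: float

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.states))


def _markov_states(p_on: float, tau: float, dt: float, n: int, rng) -> np.ndarray:
    """Exact discretization of the two-state chain at step dt.

    Rates k_on = p_on/tau, k_off = (1-p_on)/tau give relaxation rate 1/tau;
    the exact transition matrix at step dt has second eigenvalue
    lam = exp(-dt/tau), so P(on|on) = p_on + (1-p_on)*lam and
    P(on|off) = p_on*(1-lam).
    """
    if p_on >= 1.0:
        return np.ones(n, dtype=np.int8)
    lam = math.exp(-dt / tau)
    p_on_on = p_on + (1.0 - p_on) * lam
    p_on_off = p_on * (1.0 - lam)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    s = 1 if u[0] < p_on else 0
    states[0] = s
    for i in range(1, n):
        thresh = p_on_on if s else p_on_off
        s = 1 if u[i] < thresh else 0
        states[i] = s
    return states


def _two_atom_structure() -> Structure:
    atoms = [
        AtomMeta(0, "TGT", 1, "TGT", "A", 12.011),
        AtomMeta(1, "PRB", 2, "PRB", "A", 12.011),
    ]
    return Structure(atoms=atoms, coords=np.zeros((2, 3)))


def gen_markov_contact(
    spec: MarkovContactSpec,
) -> tuple[Trajectory, np.ndarray, MarkovContactTruth]:
    """Generate a contact trajectory, its energy series and the truth record.

    Returns ``(traj, energies, truth)``: a two-atom trajectory whose probe
    sits at ``d_on`` (bound) or ``d_off`` (unbound) from the target on the x
    axis, per-frame interaction energies (kJ/mol) drawn from the state's
    normal distribution, and the exact hidden state path.
    """
    rng = np.random.default_rng(spec.seed)
    states = _markov_states(spec.p_on, spec.tau, spec.dt, spec.n_frames, rng)
    dist = np.where(states == 1, spec.d_on, spec.d_off)
    noise = rng.standard_normal(spec.n_frames)
    energies = np.where(
        states == 1,
        spec.e_on_mean + spec.e_on_sd * noise,
        spec.e_off_mean + spec.e_off_sd * noise,
    )
    frames = np.zeros((spec.n_frames, 2, 3))
    frames[:, 1, 0] = dist
    times = spec.dt * np.arange(spec.n_frames)
    traj = Trajectory(structure=_two_atom_structure(), frames=frames, times=times)
    truth = MarkovContactTruth(
        states=states, p_on=spec.p_on, tau=spec.tau, dt=spec.dt
    )
    return traj, energies, truth


# --------------------------------------------------------------------------
# Harmonic (Gaussian) positional ensembles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicEnsembleSpec:
    """Independent Gaussian frames about a fixed mean with a prescribed
    3A x 3A positional covariance (nm^2)."""

    masses: np.ndarray  # (A,) amu
    covariance: np.ndarray  # (3A, 3A) nm^2, symmetric PD
    n_frames: int = 1000
    temperature: float = 300.0
    seed: int = 0
    mean: np.ndarray | None = None  # (A, 3) nm

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "covariance", c)
        if c.shape != (3 * m.size, 3 * m.size):
            raise ValueError("covariance must be 3A x 3A")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")


def gen_harmonic_ensemble(spec: HarmonicEnsembleSpec) -> Trajectory:
    """Draw ``n_frames`` i.i.d. Gaussian frames with the prescribed covariance."""
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.masses.size
    # Cholesky with tiny jitter so near-singular (frozen-mode) specs work
    c = spec.covariance + 1e-18 * np.eye(3 * n_atoms)
    chol = np.linalg.cholesky(c)
    z = rng.standard_normal((spec.n_frames, 3 * n_atoms))
    disp = z @ chol.T
    mean = (
        np.zeros((n_atoms, 3)) if spec.mean is None else np.asarray(spec.mean, float)
    )
    frames = mean[None, :, :] + disp.reshape(spec.n_frames, n_atoms, 3)
    atoms = [
        AtomMeta(i, f"C{i+1}", i + 1, "GHO", "A", float(spec.masses[i]))
        for i in range(n_atoms)
    ]
    structure = Structure(atoms=atoms, coords=mean.copy())
    times = 1.0 * np.arange(spec.n_frames)
    return Trajectory(structure=structure, frames=frames, times=times)


# --------------------------------------------------------------------------
# Hydrogen-bond geometry fixtures
# --------------------------------------------------------------------------


def gen_hbond_frame(d_da: float, theta_hda: float, r_dh: float = 0.10) -> Structure:
    """One donor-hydrogen-acceptor geometry.

    Donor (ARG NE) at the origin, acceptor (guanine O6) at ``d_da`` nm along
    x, hydrogen at bond length ``r_dh`` from the donor rotated so the
    hydrogen-donor-acceptor angle (vertex at the donor) is ``theta_hda``
    degrees, in the xy plane.
    """
    if d_da <= 0:
        raise ValueError("d_da must be > 0")
    th = math.radians(theta_hda)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_dh * math.cos(th), r_dh * math.sin(th), 0.0],
            [d_da, 0.0, 0.0],
        ]
    )
    atoms = [
        AtomMeta(0, "NE", 1, "ARG", "A", 14.007),
        AtomMeta(1, "HE", 1, "ARG", "A", 1.008),
        AtomMeta(2, "O6", 2, "DG", "B", 15.999),
    ]
    return Structure(atoms=atoms, coords=coords)


# --------------------------------------------------------------------------
# Harmonic-oscillator alchemical ladders
# --------------------------------------------------------------------------


def gen_alchemical_harmonics(
    spring_constants: Sequence[float],
    n_per_state: int,
    seed: int = 0,
) -> tuple["ReducedPotentialMatrix", np.ndarray]:
    """Sample a ladder of 1D harmonic states with closed-form free energies.

    State k has reduced potential ``u_k(x) = 0.5 * k_k * x^2`` (k in kT/nm^2,
    u in kT).  The exact free energy of state k relative to state 0 is
    ``0.5 * ln(k_k / k_0)`` kT.  Returns the reduced-potential matrix of all
    samples evaluated in every state, and the analytic free-energy vector.
    """
    from .alchemy import ReducedPotentialMatrix

    ks = np.asarray(spring_constants, dtype=float)
    if np.any(ks <= 0):
        raise ValueError("spring constants must be > 0")
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    rng = np.random.default_rng(seed)
    xs = [rng.standard_normal(n_per_state) / math.sqrt(k) for k in ks]
    x_all = np.concatenate(xs)
    u_kn = 0.5 * ks[:, None] * x_all[None, :] ** 2
    n_k = np.full(ks.size, n_per_state, dtype=int)
    analytic = 0.5 * np.log(ks / ks[0])
    return ReducedPotentialMatrix(u_kn=u_kn, n_k=n_k), analytic


# --------------------------------------------------------------------------
# Analytic potentials and overdamped Langevin dynamics
# --------------------------------------------------------------------------


class Harmonic1D:
    """U(x) = 0.5 k (x - x0)^2, kJ/mol with x in nm."""

    ndim = 1

    def __init__(self, k: float, x0: float = 0.0):
        self.k = float(k)
        self.x0 = float(x0)

    def energy(self, x):
        return 0.5 * self.k * (np.asarray(x) - self.x0) ** 2

    def gradient(self, x):
        return self.k * (np.asarray(x) - self.x0)


class DoubleWell1D:
    """Quartic double well with a linear tilt.

    ``U(x) = h * ((x-m)^2 - w^2)^2 / w^4 + c*(x-m)`` so the untilted barrier
    height is ``h`` (kJ/mol) and the minima sit near ``m - w`` and ``m + w``.
    A nonzero tilt ``c`` (kJ/mol/nm) makes the well asymmetric.
    """

    ndim = 1

    def __init__(self, barrier: float = 10.0, center: float = 0.7,
                 half_width: float = 0.25, tilt: float = 0.0):
        self.h = float(barrier)
        self.m = float(center)
        self.w = float(half_width)
        self.c = float(tilt)

    def energy(self, x):
        d = np.asarray(x) - self.m
        return self.h * (d * d - self.w**2) ** 2 / self.w**4 + self.c * d

    def gradient(self, x):
        d = np.asarray(x) - self.m
        return 4.0 * self.h * (d * d - self.w**2) * d / self.w**4 + self.c

    @property
    def barrier_top(self) -> float:
        """CV value separating the two basins (untilted barrier location)."""
        return self.m


class Separable2D:
    """Sum of two independent 1D potentials, one per CV."""

    ndim = 2

    def __init__(self, pot_x, pot_y):
        self.pot_x = pot_x
        self.pot_y = pot_y

    def energy(self, x):
        x = np.asarray(x)
        return self.pot_x.energy(x[..., 0]) + self.pot_y.energy(x[..., 1])

    def gradient(self, x):
        x = np.asarray(x)
        return np.stack(
            [self.pot_x.gradient(x[..., 0]), self.pot_y.gradient(x[..., 1])], axis=-1
        )


def gen_langevin(
    potential,
    kT: float,
    friction: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
    bias: Callable[[np.ndarray], tuple[float, np.ndarray]] | None = None,
    x0: float | Sequence[float] | None = None,
) -> np.ndarray:
    """Overdamped Langevin trajectory on an analytic potential.

    Update: ``x += -grad(U + V_bias)/friction * dt + sqrt(2 kT dt / friction) * xi``
    with ``xi`` standard normal.  ``bias``, if given, is a callable returning
    ``(energy, gradient)`` at a point.  Returns positions of shape
    ``(n_steps + 1,)`` for 1D potentials or ``(n_steps + 1, 2)`` for 2D.

    ``kT`` is in kJ/mol, friction in amu/ps, dt in ps; at zero temperature
    the dynamics is plain gradient descent.
    """
    ndim = getattr(potential, "ndim", 1)
    rng = np.random.default_rng(seed)
    if x0 is None:
        x = np.zeros(ndim)
    else:
        x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    sigma = math.sqrt(max(2.0 * kT * dt / friction, 0.0))
    noise = rng.standard_normal((n_steps, ndim)) * sigma
    out = np.empty((n_steps + 1, ndim))
    out[0] = x
    for i in range(n_steps):
        if ndim == 1:
            g = float(potential.gradient(x[0]))
            if bias is not None:
                g += float(bias(x[0])[1])
        else:
            g = np.asarray(potential.gradient(x), dtype=float)
            if bias is not None:
                g = g + np.asarray(bias(x)[1], dtype=float)
        x = x - g / friction * dt + noise[i]
        out[i + 1] = x
    return out[:, 0] if ndim == 1 else out


def thermal_kt(temperature: float) -> float:
    """kT in kJ/mol."""
    return KB * temperature
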