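"""Side-chain flexibility (RMSF) and quasi-harmonic conformational entropy.

After removing rotational and translational motion by mass-weighted
least-squares superposition, the mass-weighted covariance of atomic
fluctuations is diagonalized; each eigenvalue lambda_i (nm^2 amu) defines a
vibrational mode of angular frequency ``omega_i = sqrt(kB*T / lambda_i)``
(1/ps in this unit system).  The default entropy is the quantum
harmonic-oscillator form

    S = R * sum_i [ x_i/(exp(x_i)-1) - ln(1-exp(-x_i)) ],  x_i = hbar*omega_i/(kB*T)

which remains finite for stiff modes; the classical form
``S = R * sum_i [1 - ln(x_i)]`` diverges there and is available for
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_selection import AtomGroup, Trajectory
from .struct_compare import kabsch
from .units import ANGSTROM_PER_NM, HBAR, KB, R_GAS

__all__ = [
    "EntropyResult",
    "RMSFProfile",
    "superpose_series",
    "rmsf",
    "fluctuation_covariance",
    "quasiharmonic_entropy",
    "entropy_difference",
    "EIGENVALUE_FLOOR",
]

#: Modes with mass-weighted covariance eigenvalues below this (nm^2 amu) are
#: treated as frozen rigid-body remnants and excluded from the entropy sum.
EIGENVALUE_FLOOR = 1e-12


@dataclass(frozen=True)
class EntropyResult:
    """Quasi-harmonic entropy and the eigen-spectrum it came from."""

    S: float  # J/(mol K)
    eigenvalues: np.ndarray  # nm^2 amu, descending
    n_modes_used: int
    temperature: float  # K
    formula: str = "quantum"

    def __post_init__(self) -> None:
        if self.S < 0 and self.formula == "quantum":
            raise ValueError("quantum quasi-harmonic entropy cannot be negative")


@dataclass(frozen=True)
class RMSFProfile:
    """Per-atom root-mean-square fluctuations, reported in angstrom."""

    atom_indices: np.ndarray
    values: np.ndarray  # angstrom
    residue_mean: float  # angstrom, mean over the group's atoms
    align_label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be >= 0")


def superpose_series(
    traj: Trajectory,
    align_group: AtomGroup,
    reference_frame: int = 0,
    mass_weighted: bool = True,
) -> Trajectory:
    """Least-squares superpose every frame onto a reference frame.

    The rotation/translation is fitted on ``align_group`` (mass-weighted by
    default) and applied to all atoms, removing rigid-body motion of that
    group.  Idempotent: re-aligning an aligned trajectory is a no-op.
    """
    idx = align_group.indices
    w = align_group.masses() if mass_weighted else None
    ref = traj.frames[reference_frame][idx]
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch(ref, traj.frames[f][idx], w)
        out[f] = traj.frames[f] @ rot.T + trans
    return Trajectory(structure=traj.structure, frames=out, times=traj.times.copy())


def rmsf(traj: Trajectory, group: AtomGroup, align_label: str = "") -> RMSFProfile:
    """Per-atom RMSF about the time-mean position, in angstrom.

    The trajectory is expected to be aligned already (see
    :func:`superpose_series`).  The group-level value is the unweighted mean
    over the group's atoms, the convention for side-chain flexibility
    profiles.
    """
    coords = traj.frames[:, group.indices, :]
    mean = coords.mean(axis=0)
    msd = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    values_nm = np.sqrt(msd)
    return RMSFProfile(
        atom_indices=group.indices.copy(),
        values=values_nm * ANGSTROM_PER_NM,
        residue_mean=float(values_nm.mean() * ANGSTROM_PER_NM),
        align_label=align_label,
    )


def fluctuation_covariance(
    traj: Trajectory, group: AtomGroup, mass_weighted: bool = True
) -> np.ndarray:
    """3A x 3A covariance of atomic fluctuations over the trajectory.

    ``C_ij = <dx_i dx_j>`` with deviations about the time mean; with
    ``mass_weighted`` the entries are scaled by sqrt(m_i m_j) (units
    nm^2 amu), the input expected by :func:`quasiharmonic_entropy`.
    """
    coords = traj.frames[:, group.indices, :].reshape(traj.n_frames, -1)
    dev = coords - coords.mean(axis=0)
    cov = dev.T @ dev / traj.n_frames
    if mass_weighted:
        m = np.repeat(group.masses(), 3)
        cov = cov * np.sqrt(np.outer(m, m))
    return cov


def quasiharmonic_entropy(
    covariance: np.ndarray,
    temperature: float,
    formula: str = "quantum",
    eigenvalue_floor: float = EIGENVALUE_FLOOR,
) -> EntropyResult:
    """Quasi-harmonic entropy from a mass-weighted covariance matrix.

    ``covariance`` in nm^2 amu; ``temperature`` in K.  Eigenvalues at or
    below ``eigenvalue_floor`` (frozen modes, rigid-body remnants) are
    excluded and show up in ``n_modes_used``.  Result in J/(mol K).
    """
    c = np.asarray(covariance, dtype=float)
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(c)[::-1]
    if evals[-1] < -1e-8 * max(1.0, abs(evals[0])):
        raise ValueError("covariance is not positive semi-definite")
    kt = KB * temperature
    used = evals[evals > eigenvalue_floor]
    if formula == "quantum":
        # x = hbar*omega/kT with omega = sqrt(kT/lambda)
        x = HBAR * np.sqrt(kt / used) / kt
        terms = np.zeros_like(x)
        soft = x < 50.0  # stiffer modes contribute < 1e-20 R
        terms[soft] = x[soft] / np.expm1(x[soft]) - np.log1p(-np.exp(-x[soft]))
    elif formula == "classical":
        x = HBAR * np.sqrt(kt / used) / kt
        terms = 1.0 - np.log(x)
    else:
        raise ValueError("formula must be 'quantum' or 'classical'")
    s = R_GAS * float(terms.sum())
    return EntropyResult(
        S=s,
        eigenvalues=evals,
        n_modes_used=int(used.size),
        temperature=temperature,
        formula=formula,
    )


def entropy_difference(
    a: EntropyResult | float, b: EntropyResult | float
) -> float:
    """S_a - S_b in J/(mol K).

    Accepts :class:`EntropyResult` objects (which must share formula and
    temperature) or plain entropy values in J/(mol K).
    """
    if isinstance(a, EntropyResult) and isinstance(b, EntropyResult):
        if a.formula != b.formula:
            raise ValueError("entropy results use different formulas")
        if not math.isclose(a.temperature, b.temperature, rel_tol=1e-9):
            raise ValueError("entropy results computed at different temperatures")
        return a.S - b.S
    sa = a.S if isinstance(a, EntropyResult) else float(a)
    sb = b.S if isinstance(b, EntropyResult) else float(b)
    return sa - sb
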