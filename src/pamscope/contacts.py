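"""Contact classification and occupancy statistics.

A residue-nucleotide pair is an effective contact in a frame when two
criteria hold simultaneously: the COM distance of the pair is below the
kind-specific cutoff (0.6 nm for arginine-base, 0.5 nm for
arginine-phosphate pairs) and the attractive interaction energy magnitude is
at least the kind-specific threshold (100 kJ/mol base, 350 kJ/mol
phosphate).  Candidate pairs are pre-screened by requiring the distance
criterion in at least 5% of the pooled trajectory.

The resulting binary occupancy series is treated as Bernoulli; its standard
error uses an effective sample count ``n_eff = T_total / tau`` where ``tau``
is the largest integrated autocorrelation time of the interaction-energy
series across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .io_selection import AtomGroup, Trajectory

__all__ = [
    "ContactCriteria",
    "OccupancySeries",
    "FrequencyEstimate",
    "com_distance_series",
    "find_candidate_pairs",
    "classify_contacts",
    "integrated_autocorrelation_time",
    "frequency_with_error",
]

ContactKind = Literal["base", "phosphate"]


@dataclass(frozen=True)
class ContactCriteria:
    """Distance/energy thresholds for effective contacts."""

    base_distance_cutoff: float = 0.6  # nm
    phosphate_distance_cutoff: float = 0.5  # nm
    candidate_fraction: float = 0.05
    base_energy_threshold: float = 100.0  # kJ/mol, magnitude of attraction
    phosphate_energy_threshold: float = 350.0  # kJ/mol

    def __post_init__(self) -> None:
        if self.base_distance_cutoff <= 0 or self.phosphate_distance_cutoff <= 0:
            raise ValueError("distance cutoffs must be > 0")
        if not 0.0 < self.candidate_fraction < 1.0:
            raise ValueError("candidate_fraction must be in (0, 1)")
        if self.base_energy_threshold < 0 or self.phosphate_energy_threshold < 0:
            raise ValueError("energy thresholds must be >= 0")

    def distance_cutoff(self, kind: ContactKind) -> float:
        return {"base": self.base_distance_cutoff,
                "phosphate": self.phosphate_distance_cutoff}[kind]

    def energy_threshold(self, kind: ContactKind) -> float:
        return {"base": self.base_energy_threshold,
                "phosphate": self.phosphate_energy_threshold}[kind]


@dataclass
class OccupancySeries:
    """Per-frame binary contact indicator for one pair."""

    values: np.ndarray  # (F,) in {0,1}
    dt: float  # ps
    pair: str = ""
    category: str = "PAM_NB"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("occupancy values must be 0 or 1")
        self.values = v.astype(np.int8)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class FrequencyEstimate:
    """Pooled occupancy with an autocorrelation-corrected standard error.

    ``stderr`` is the Bernoulli error sqrt(p(1-p)/n_eff) with n_eff from the
    largest energy-autocorrelation time across replicates;
    ``stderr_replicates`` is the alternative standard deviation of the mean
    over replicates.
    """

    mean: float
    stderr: float
    tau: float  # ps, largest integrated autocorrelation time
    n_eff: float
    n_replicates: int
    stderr_replicates: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("mean must be in [0, 1]")
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


def _group_com(traj: Trajectory, group: AtomGroup, mass_weighted: bool) -> np.ndarray:
    coords = traj.frames[:, group.indices, :]  # (F, n, 3)
    if mass_weighted:
        w = group.masses()
        w = w / w.sum()
        return np.einsum("fnx,n->fx", coords, w)
    return coords.mean(axis=1)


def com_distance_series(
    traj: Trajectory, a: AtomGroup, b: AtomGroup, mass_weighted: bool = True
) -> np.ndarray:
    """Per-frame distance (nm) between the groups' centers of mass."""
    coms_a = _group_com(traj, a, mass_weighted)
    coms_b = _group_com(traj, b, mass_weighted)
    return np.linalg.norm(coms_a - coms_b, axis=1)


def find_candidate_pairs(
    distance_series: Mapping[str, Sequence[np.ndarray] | np.ndarray],
    criteria: ContactCriteria,
    kind: ContactKind,
    pooled: bool = True,
) -> list[str]:
    """Screen pairs whose COM distance is below the cutoff often enough.

    ``distance_series`` maps a pair label to either a single distance array
    or a sequence of per-replicate arrays.  With ``pooled=True`` (the
    default, matching the cumulative-trajectory reading) the below-cutoff
    fraction is computed over all replicates concatenated; otherwise every
    replicate must individually reach ``candidate_fraction``.
    """
    cutoff = criteria.distance_cutoff(kind)
    kept: list[str] = []
    for label, series in distance_series.items():
        reps = [np.asarray(series)] if np.ndim(series[0]) == 0 else [
            np.asarray(s) for s in series
        ]
        if pooled:
            pooled_d = np.concatenate(reps)
            frac = float(np.mean(pooled_d < cutoff))
            ok = frac >= criteria.candidate_fraction
        else:
            ok = all(
                float(np.mean(r < cutoff)) >= criteria.candidate_fraction
                for r in reps
            )
        if ok:
            kept.append(label)
    return kept


def classify_contacts(
    distances: np.ndarray,
    energies: np.ndarray,
    criteria: ContactCriteria,
    kind: ContactKind,
    dt: float = 1.0,
    pair: str = "",
    category: str = "PAM_NB",
) -> OccupancySeries:
    """Mark frames where both the distance and energy criteria hold.

    A frame counts as contact iff the COM distance is below the kind's
    cutoff AND the interaction energy is attractive (negative) with
    magnitude at least the kind's threshold.  Repulsive frames never count.
    """
    distances = np.asarray(distances, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if distances.shape != energies.shape:
        raise ValueError(
            f"distance ({distances.shape}) and energy ({energies.shape}) "
            "series are misaligned"
        )
    cutoff = criteria.distance_cutoff(kind)
    threshold = criteria.energy_threshold(kind)
    on = (distances < cutoff) & (energies <= -threshold)
    return OccupancySeries(values=on.astype(np.int8), dt=dt, pair=pair,
                           category=category)


def integrated_autocorrelation_time(series: np.ndarray, dt: float) -> float:
    """Integrated autocorrelation time, ps.

    ``tau = dt * (1 + 2 * sum_k rho(k))`` with the sum truncated at the
    first lag where the empirical autocorrelation drops below zero
    (initial-positive-sequence window).  A constant series carries no
    correlation information and returns ``dt``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("series too short for autocorrelation analysis (need >= 100)")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0 or not np.isfinite(var):
        return float(dt)
    # FFT autocovariance, biased normalization (1/n), standard for IACT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] < 0.0:
            break
        s += rho[k]
    return float(dt * (1.0 + 2.0 * s))


def frequency_with_error(
    occupancies: Sequence[OccupancySeries],
    energy_series: Sequence[np.ndarray],
    dt: float | None = None,
) -> FrequencyEstimate:
    """Pooled contact frequency with an autocorrelation-corrected error.

    The mean is the pooled occupancy fraction over all replicates.  The
    error model treats frames as Bernoulli draws and divides by the
    effective number of independent samples ``n_eff = T_total / tau`` where
    ``tau`` is the largest integrated autocorrelation time of the
    interaction-energy series over the replicates.  The replicate-SEM
    alternative (standard deviation of per-replicate means over sqrt(R)) is
    reported alongside.
    """
    if len(occupancies) == 0:
        raise ValueError("need at least one replicate")
    if len(energy_series) != len(occupancies):
        raise ValueError("occupancies and energy series must pair up per replicate")
    if dt is None:
        dt = occupancies[0].dt
    total = sum(o.values.size for o in occupancies)
    pooled_mean = sum(int(o.values.sum()) for o in occupancies) / total
    tau = max(
        integrated_autocorrelation_time(np.asarray(e, dtype=float), dt)
        for e in energy_series
    )
    n_eff = total * dt / tau
    stderr = math.sqrt(pooled_mean * (1.0 - pooled_mean) / n_eff)
    rep_means = np.array([o.mean for o in occupancies])
    if rep_means.size > 1:
        sem = float(rep_means.std(ddof=1) / math.sqrt(rep_means.size))
    else:
        sem = float("nan")
    return FrequencyEstimate(
        mean=float(pooled_mean),
        stderr=float(stderr),
        tau=float(tau),
        n_eff=float(n_eff),
        n_replicates=len(occupancies),
        stderr_replicates=sem,
    )
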