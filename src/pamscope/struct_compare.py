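"""Domain geometry, Kabsch superposition and distance-distribution tests.

Provides the mass-weighted domain centre-of-mass distance (reported in
angstrom), least-squares rigid-body superposition with a proper rotation
(Kabsch), a two-tailed Z test on effective sample sizes for comparing
distance distributions, and Gaussian kernel density estimates of distance
samples.

Default domain boundaries ship for the two SpCas9 domains whose separation
reports the recognition-lobe opening: REC3 residues 498-718 and HNH
residues 775-908 (author numbering; configurable, and printed in every CLI
output header).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .io_selection import Structure, Trajectory
from .units import ANGSTROM_PER_NM

__all__ = [
    "DomainDefinition",
    "DEFAULT_DOMAINS",
    "DistanceDistribution",
    "com_domain_distance",
    "kabsch",
    "kabsch_rmsd",
    "z_test_two_tailed",
    "distance_density",
]

AtomScope = Literal["heavy", "backbone", "CA"]

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class DomainDefinition:
    """A named residue-range domain with an atom scope."""

    name: str
    residue_ranges: tuple[tuple[int, int], ...]
    atom_scope: AtomScope = "heavy"

    def __post_init__(self) -> None:
        spans = sorted(self.residue_ranges)
        for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"domain {self.name}: overlapping residue ranges")
        for lo, hi in spans:
            if hi < lo:
                raise ValueError(f"domain {self.name}: empty range {lo}-{hi}")

    def contains(self, resid: int) -> bool:
        return any(lo <= resid <= hi for lo, hi in self.residue_ranges)

    def atom_indices(self, structure: Structure) -> np.ndarray:
        idx = []
        for a in structure.atoms:
            if not self.contains(a.residue_number):
                continue
            name = a.name.upper()
            if self.atom_scope == "CA" and name != "CA":
                continue
            if self.atom_scope == "backbone" and name not in _BACKBONE_NAMES:
                continue
            if self.atom_scope == "heavy" and name.startswith("H"):
                continue
            idx.append(a.index)
        if not idx:
            raise ValueError(f"domain {self.name} matches no atoms")
        return np.array(idx, dtype=int)


#: Standard SpCas9 domain annotation (author numbering).
DEFAULT_DOMAINS: dict[str, DomainDefinition] = {
    "REC3": DomainDefinition("REC3", ((498, 718),)),
    "HNH": DomainDefinition("HNH", ((775, 908),)),
}


def _com(structure_coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses / masses.sum()
    return w @ structure_coords


def com_domain_distance(
    obj: Structure | Trajectory,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
) -> float | np.ndarray:
    """Mass-weighted COM distance between two domains, in angstrom.

    Returns a scalar for a :class:`Structure` and a per-frame series for a
    :class:`Trajectory`.
    """
    structure = obj if isinstance(obj, Structure) else obj.structure
    idx_a = dom_a.atom_indices(structure)
    idx_b = dom_b.atom_indices(structure)
    masses = structure.masses
    wa = masses[idx_a] / masses[idx_a].sum()
    wb = masses[idx_b] / masses[idx_b].sum()
    if isinstance(obj, Structure):
        d = np.linalg.norm(wa @ obj.coords[idx_a] - wb @ obj.coords[idx_b])
        return float(d * ANGSTROM_PER_NM)
    coms_a = np.einsum("fnx,n->fx", obj.frames[:, idx_a, :], wa)
    coms_b = np.einsum("fnx,n->fx", obj.frames[:, idx_b, :], wb)
    return np.linalg.norm(coms_a - coms_b, axis=1) * ANGSTROM_PER_NM


def kabsch(
    ref: np.ndarray, mobile: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal (weighted) rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``ref``; the rotation is proper (det = +1).  Coordinates in any length
    unit; the RMSD is in the same unit.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape:
        raise ValueError("coordinate arrays must have identical shape")
    n = ref.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_c = ref - w @ ref
    mob_c = mobile - w @ mobile
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    rotated = mob_c @ rot.T
    rmsd = math.sqrt(float(np.sum(w[:, None] * (rotated - ref_c) ** 2)))
    trans = (w @ ref) - (w @ mobile) @ rot.T
    return rot, trans, rmsd


def _match_atoms(
    ref: Structure, mobile: Structure, atoms: AtomScope
) -> tuple[np.ndarray, np.ndarray]:
    def keep(a) -> bool:
        name = a.name.upper()
        if atoms == "CA":
            return name == "CA"
        if atoms == "backbone":
            return name in _BACKBONE_NAMES
        return not name.startswith("H")

    key = lambda a: (a.chain, a.residue_number, a.name.upper())
    ref_map = {key(a): a.index for a in ref.atoms if keep(a)}
    mob_map = {key(a): a.index for a in mobile.atoms if keep(a)}
    common = sorted(set(ref_map) & set(mob_map))
    if not common:
        missing = sorted(set(ref_map) ^ set(mob_map))[:10]
        raise ValueError(f"no matching atoms; first mismatches: {missing}")
    return (
        np.array([ref_map[k] for k in common]),
        np.array([mob_map[k] for k in common]),
    )


def kabsch_rmsd(
    ref: Structure,
    mobile: Structure,
    atoms: AtomScope = "backbone",
    mass_weighted: bool = False,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose two structures matched by (chain, residue, atom name).

    Returns ``(rotation, translation, rmsd)`` with the RMSD in angstrom.
    ``selection``, if given, restricts the superposition (and RMSD) to those
    reference atom indices after matching.
    """
    idx_ref, idx_mob = _match_atoms(ref, mobile, atoms)
    if selection is not None:
        sel = np.isin(idx_ref, np.asarray(selection, dtype=int))
        if not sel.any():
            raise ValueError("selection excludes every matched atom")
        idx_ref, idx_mob = idx_ref[sel], idx_mob[sel]
    w = ref.masses[idx_ref] if mass_weighted else None
    rot, trans, rmsd_nm = kabsch(ref.coords[idx_ref], mobile.coords[idx_mob], w)
    return rot, trans, rmsd_nm * ANGSTROM_PER_NM


def z_test_two_tailed(
    samples1: np.ndarray,
    samples2: np.ndarray,
    n_eff1: float,
    n_eff2: float,
) -> tuple[float, float]:
    """Two-tailed Z test for a difference of means on effective sample sizes.

    ``Z = (m1 - m2) / sqrt(s1^2/n_eff1 + s2^2/n_eff2)``;
    ``p = 2 (1 - Phi(|Z|))``.  The effective sample sizes absorb frame
    autocorrelation; duplicating correlated frames while holding them fixed
    leaves the statistic unchanged.
    """
    if n_eff1 < 2 or n_eff2 < 2:
        raise ValueError("effective sample sizes must be >= 2")
    x1 = np.asarray(samples1, dtype=float)
    x2 = np.asarray(samples2, dtype=float)
    # population variance: the frame count enters only through n_eff, so
    # duplicating correlated frames cannot move the statistic
    se = math.sqrt(x1.var() / n_eff1 + x2.var() / n_eff2)
    if se == 0.0:
        z = 0.0 if x1.mean() == x2.mean() else math.inf
    else:
        z = (x1.mean() - x2.mean()) / se
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return float(z), float(p)


@dataclass
class DistanceDistribution:
    """Samples (angstrom) with a normalized Gaussian KDE on a grid."""

    samples: np.ndarray
    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        total = np.trapezoid(self.density, self.grid)
        if not math.isclose(total, 1.0, rel_tol=1e-6, abs_tol=1e-6):
            raise ValueError("density must integrate to 1 on its grid")


def distance_density(
    samples: np.ndarray, grid: np.ndarray, bandwidth: float
) -> DistanceDistribution:
    """Gaussian kernel density of distance samples, renormalized on the grid."""
    samples = np.asarray(samples, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    z = (grid[:, None] - samples[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (
        samples.size * bandwidth * math.sqrt(2.0 * math.pi)
    )
    total = np.trapezoid(dens, grid)
    if total <= 0:
        raise ValueError("grid does not cover the samples")
    return DistanceDistribution(samples=samples, grid=grid, density=dens / total)
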