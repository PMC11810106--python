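"""Geometric hydrogen-bond detection and the PAM specificity index.

A donor-hydrogen-acceptor triple forms a hydrogen bond in a frame when the
donor-acceptor distance is at most 0.35 nm and the hydrogen-donor-acceptor
angle (vertex at the donor) is at most 30 degrees.  Frequencies are
event-frames over total frames per acceptor category (PAM nucleobase, PAM
backbone, non-PAM), normalized to sum to one, and condensed into a
specificity index: the PAM frequency relative to the non-PAM frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_selection import AtomGroup, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondEventTable",
    "DONOR_HYDROGEN_TEMPLATES",
    "NUCLEOTIDE_BACKBONE_ATOMS",
    "assign_acceptor_category",
    "detect_hbonds",
    "hbond_frequencies",
    "normalize_frequencies",
    "specificity_index",
]


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff: float = 0.35  # nm, donor-acceptor distance
    hda_angle_cutoff: float = 30.0  # degrees, hydrogen-donor-acceptor angle

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be > 0")
        if not 0.0 < self.hda_angle_cutoff < 90.0:
            raise ValueError("hda_angle_cutoff must be in (0, 90) degrees")


#: Donor -> attached hydrogens, per (residue name, donor atom name).
#: Covers the arginine guanidinium/backbone donors used throughout; other
#: donors fall back to geometric attachment in the first frame.
DONOR_HYDROGEN_TEMPLATES: dict[tuple[str, str], tuple[str, ...]] = {
    ("ARG", "NE"): ("HE",),
    ("ARG", "NH1"): ("HH11", "HH12"),
    ("ARG", "NH2"): ("HH21", "HH22"),
    ("ARG", "N"): ("H",),
}

#: Sugar-phosphate atom names of a DNA nucleotide; every other O/N acceptor
#: in a nucleotide is part of the base.
NUCLEOTIDE_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "O1P", "O2P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}

_DH_ATTACH_CUTOFF = 0.125  # nm, geometric donor-H attachment fallback


def assign_acceptor_category(
    structure: Structure, atom_index: int, pam_resids: Iterable[int]
) -> str:
    """PAM_NB / PAM_BB / NONPAM for an acceptor atom.

    Acceptors in PAM residues split by atom membership: sugar-phosphate
    names count as backbone, everything else as nucleobase.  Acceptors
    outside the PAM residues are NONPAM regardless of atom type.
    """
    atom = structure.atoms[atom_index]
    if atom.residue_number not in set(pam_resids):
        return "NONPAM"
    if atom.name.upper() in NUCLEOTIDE_BACKBONE_ATOMS:
        return "PAM_BB"
    return "PAM_NB"


@dataclass
class HBondEventTable:
    """Binary per-frame event series per (donor, hydrogen, acceptor) triple."""

    events: dict[tuple[int, int, int], np.ndarray]
    categories: dict[tuple[int, int, int], str]
    n_frames: int
    dt: float = 1.0

    def triples(self) -> list[tuple[int, int, int]]:
        return list(self.events)


def _find_hydrogens(structure: Structure, donor_idx: int,
                    frame0: np.ndarray) -> list[int]:
    donor = structure.atoms[donor_idx]
    key = (donor.residue_name.upper(), donor.name.upper())
    same_res = [
        a.index
        for a in structure.atoms
        if a.residue_number == donor.residue_number and a.chain == donor.chain
    ]
    if key in DONOR_HYDROGEN_TEMPLATES:
        wanted = set(DONOR_HYDROGEN_TEMPLATES[key])
        hs = [i for i in same_res if structure.atoms[i].name.upper() in wanted]
        if hs:
            return hs
    # geometric fallback: same-residue hydrogens bonded in the first frame
    hs = [
        i
        for i in same_res
        if structure.atoms[i].name.upper().startswith("H")
        and np.linalg.norm(frame0[i] - frame0[donor_idx]) <= _DH_ATTACH_CUTOFF
    ]
    return hs


def detect_hbonds(
    traj: Trajectory,
    donors: AtomGroup,
    acceptors: AtomGroup,
    criteria: HBondCriteria = HBondCriteria(),
    pam_resids: Iterable[int] = (),
) -> HBondEventTable:
    """Detect hydrogen bonds between donor and acceptor groups.

    ``donors`` holds the heavy donor atoms; their hydrogens are resolved
    from the residue templates (arginine NE/NH1/NH2) with a geometric
    first-frame fallback.  A donor with no attached hydrogen raises.
    """
    structure = traj.structure
    frame0 = traj.frames[0]
    pairs: list[tuple[int, int]] = []
    for d in donors.indices:
        hs = _find_hydrogens(structure, int(d), frame0)
        if not hs:
            a = structure.atoms[int(d)]
            raise ValueError(
                f"donor atom {a.name} (residue {a.residue_name} "
                f"{a.residue_number}) has no attached hydrogen"
            )
        pairs.extend((int(d), h) for h in hs)

    cos_cut = math.cos(math.radians(criteria.hda_angle_cutoff))
    events: dict[tuple[int, int, int], np.ndarray] = {}
    categories: dict[tuple[int, int, int], str] = {}
    acc = traj.frames[:, acceptors.indices, :]  # (F, Na, 3)
    for d, h in pairs:
        dpos = traj.frames[:, d, :]  # (F, 3)
        hpos = traj.frames[:, h, :]
        da = acc - dpos[:, None, :]  # (F, Na, 3)
        da_dist = np.linalg.norm(da, axis=2)
        dh = hpos - dpos  # (F, 3)
        dh_norm = np.linalg.norm(dh, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("fx,fax->fa", dh, da) / (
                dh_norm[:, None] * da_dist
            )
        hit = (da_dist <= criteria.da_cutoff) & (cosang >= cos_cut)
        for j, a_idx in enumerate(acceptors.indices):
            if int(a_idx) in (d, h):
                continue
            triple = (d, h, int(a_idx))
            events[triple] = hit[:, j].astype(np.int8)
            categories[triple] = assign_acceptor_category(
                structure, int(a_idx), pam_resids
            )
    return HBondEventTable(
        events=events, categories=categories, n_frames=traj.n_frames, dt=traj.dt
    )


def hbond_frequencies(table: HBondEventTable) -> dict[str, float]:
    """Raw event frequency per acceptor category.

    A frame counts for a category when any triple of that category bonds in
    it (consistent with the contact-pattern semantics).  Categories present
    in the table but never bonding report 0.0.
    """
    freqs: dict[str, float] = {}
    for cat in sorted(set(table.categories.values())):
        any_on = np.zeros(table.n_frames, dtype=bool)
        for triple, series in table.events.items():
            if table.categories[triple] == cat:
                any_on |= series.astype(bool)
        freqs[cat] = float(np.mean(any_on))
    return freqs


def normalize_frequencies(freqs: Mapping[str, float]) -> dict[str, float]:
    """Divide every entry by the sum of all entries (result sums to 1)."""
    total = float(sum(freqs.values()))
    if any(v < 0 for v in freqs.values()):
        raise ValueError("frequencies must be >= 0")
    if total <= 0.0:
        raise ValueError("cannot normalize all-zero frequencies")
    return {k: float(v) / total for k, v in freqs.items()}


def specificity_index(
    f_pam: float, f_nonpam: float, epsilon: float = 0.0
) -> float:
    """(f_pam + eps) / (f_nonpam + eps).

    With the default ``epsilon=0`` a zero non-PAM frequency against a
    positive PAM frequency is reported as ``inf``.
    """
    if f_pam < 0 or f_nonpam < 0:
        raise ValueError("frequencies must be >= 0")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    num, den = f_pam + epsilon, f_nonpam + epsilon
    if den == 0.0:
        return float("inf") if num > 0 else float("nan")
    return num / den
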