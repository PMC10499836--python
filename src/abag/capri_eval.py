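"""CAPRI-style quality evaluation of docked antibody-antigen models.

A model is compared to the reference (crystal) complex with the three
community-standard metrics: the fraction of native cross-partner residue
contacts preserved (fnat, 5 Å heavy-atom cutoff), the interface RMSD (backbone
atoms of reference-side interface residues, 10 Å criterion, after best-fit
superposition of those same atoms) and the ligand RMSD (antibody backbone
after superposing the antigen, no refit).  The three metrics combine into the
High / Medium / Acceptable / Incorrect quality classes; a model of at least
Acceptable quality counts as a positive.

Residue correspondence between model and reference is by
(chain id, author number, insertion code) — inputs are same-sequence by
construction.  Distance ties at exactly the cutoff count as contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .structure_model import BACKBONE_ATOMS, ComplexStructure, ResKey

logger = logging.getLogger("abag")

CONTACT_CUTOFF = 5.0     # Å, native-contact definition
INTERFACE_CUTOFF = 10.0  # Å, interface-residue definition on the reference

AtomSet = Literal["backbone", "CA"]


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ContactSet:
    """Cross-partner residue contacts: pairs of (antibody key, antigen key)."""

    pairs: frozenset[tuple[ResKey, ResKey]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class QualityMetrics:
    fnat: float
    irmsd: float
    lrmsd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fnat <= 1.0):
            raise ValueError(f"fnat out of range: {self.fnat}")
        if self.irmsd < 0 or self.lrmsd < 0:
            raise ValueError("RMSD values must be non-negative")


class QualityClass(IntEnum):
    """CAPRI model-quality class; total order Incorrect < Acceptable < Medium < High."""

    INCORRECT = 0
    ACCEPTABLE = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.capitalize()

    @property
    def positive(self) -> bool:
        """Positive = at least Acceptable quality."""
        return self >= QualityClass.ACCEPTABLE

    @classmethod
    def from_label(cls, label: str) -> "QualityClass":
        return cls[label.upper()]


# ---------------------------------------------------------------------------
# contacts

def _partner_atom_table(
    complex_: ComplexStructure, side: Literal["antibody", "antigen"]
) -> tuple[np.ndarray, list[ResKey]]:
    """Stacked heavy-atom coordinates and the residue key of each atom row."""
    coords: list[np.ndarray] = []
    keys: list[ResKey] = []
    for key, res in complex_.iter_residues(side):
        for atom in res.atoms:
            coords.append(atom.position)
            keys.append(key)
    if not coords:
        raise ValueError(f"{side} partner has no atoms")
    return np.vstack(coords), keys


def contact_pairs(complex_: ComplexStructure, cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """Residue pairs across partners with any heavy-atom distance ≤ cutoff."""
    ab_xyz, ab_keys = _partner_atom_table(complex_, "antibody")
    ag_xyz, ag_keys = _partner_atom_table(complex_, "antigen")
    close = cdist(ab_xyz, ag_xyz) <= cutoff
    pairs = {
        (ab_keys[i], ag_keys[j]) for i, j in zip(*np.nonzero(close))
    }
    return ContactSet(pairs=frozenset(pairs), cutoff=cutoff)


def fnat(
    model: ComplexStructure,
    reference: ComplexStructure,
    cutoff: float = CONTACT_CUTOFF,
) -> float:
    """Fraction of the reference's cross-partner contacts preserved in the model."""
    native = contact_pairs(reference, cutoff).pairs
    if not native:
        raise ValueError("no native contacts in the reference complex")
    modeled = contact_pairs(model, cutoff).pairs
    return len(native & modeled) / len(native)


def conserved_contact_fraction(
    af2_model: ComplexStructure,
    docking_template: ComplexStructure,
    cutoff: float = CONTACT_CUTOFF,
) -> float:
    """Fraction of the docking template's contacts retained in the rebuilt model.

    Same contact engine as :func:`fnat`, with the template playing the role of
    the reference set.
    """
    template_contacts = contact_pairs(docking_template, cutoff).pairs
    if not template_contacts:
        raise ValueError("template contact set is empty")
    return fnat(af2_model, docking_template, cutoff)


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (rotation, translation, rmsd) with ``fixed ≈ rotation @ moving + t``;
    the rotation is proper (det +1).  Requires n ≥ 3 non-collinear points.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fixed.mean(axis=0) - rot @ moving.mean(axis=0)
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return rot, trans, rmsd


def _matched_coords(
    model: ComplexStructure,
    reference: ComplexStructure,
    keys: set[ResKey] | None,
    side: Literal["antibody", "antigen"] | None,
    atom_set: AtomSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (model, reference) coordinates for shared residue-key/atom-name slots."""
    names = ("CA",) if atom_set == "CA" else BACKBONE_ATOMS
    ref_res = dict(reference.iter_residues(side))
    mod_res = dict(model.iter_residues(side))
    mod_xyz: list[np.ndarray] = []
    ref_xyz: list[np.ndarray] = []
    for key, rres in ref_res.items():
        if keys is not None and key not in keys:
            continue
        mres = mod_res.get(key)
        if mres is None:
            continue
        for name in names:
            ra, ma = rres.atom(name), mres.atom(name)
            if ra is not None and ma is not None:
                ref_xyz.append(ra.position)
                mod_xyz.append(ma.position)
    if not mod_xyz:
        raise ValueError("no matched atoms between model and reference")
    return np.vstack(mod_xyz), np.vstack(ref_xyz)


def interface_residues(
    reference: ComplexStructure, cutoff: float = INTERFACE_CUTOFF
) -> set[ResKey]:
    """Residues of either partner with any cross-partner heavy atom ≤ cutoff,
    defined on the reference structure only."""
    ab_xyz, ab_keys = _partner_atom_table(reference, "antibody")
    ag_xyz, ag_keys = _partner_atom_table(reference, "antigen")
    close = cdist(ab_xyz, ag_xyz) <= cutoff
    rows, cols = np.nonzero(close)
    keys: set[ResKey] = set()
    for i, j in zip(rows, cols):
        keys.add(ab_keys[i])
        keys.add(ag_keys[j])
    return keys


def interface_rmsd(
    model: ComplexStructure,
    reference: ComplexStructure,
    interface_cutoff: float = INTERFACE_CUTOFF,
    atom_set: AtomSet = "backbone",
) -> float:
    """RMSD over interface-residue atoms after best-fit superposition of those atoms.

    The interface is defined on the reference (10 Å heavy-atom criterion,
    both partners jointly); the fit uses the same atom selection that is
    scored.
    """
    keys = interface_residues(reference, interface_cutoff)
    if not keys:
        raise ValueError("empty interface in the reference complex")
    mod_xyz, ref_xyz = _matched_coords(model, reference, keys, None, atom_set)
    _, _, rmsd = kabsch_superpose(mod_xyz, ref_xyz)
    return rmsd


def ligand_rmsd(
    model: ComplexStructure,
    reference: ComplexStructure,
    atom_set: AtomSet = "backbone",
) -> float:
    """Antibody RMSD after superposing the model's antigen onto the reference's.

    The antigen-fit transform is applied to the antibody atoms and the RMSD is
    reported without refitting — the mobile-partner displacement metric.
    """
    ag_mod, ag_ref = _matched_coords(model, reference, None, "antigen", atom_set)
    rot, trans, _ = kabsch_superpose(ag_mod, ag_ref)
    ab_mod, ab_ref = _matched_coords(model, reference, None, "antibody", atom_set)
    moved = ab_mod @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - ab_ref) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# classification

def classify_capri(metrics: QualityMetrics) -> QualityClass:
    """Combine fnat/iRMSD/lRMSD into the CAPRI quality class.

    Standard CAPRI criteria: High when fnat ≥ 0.5 and (lRMSD ≤ 1.0 or
    iRMSD ≤ 1.0); Medium when fnat ≥ 0.3 and (lRMSD ≤ 5.0 or iRMSD ≤ 2.0);
    Acceptable when fnat ≥ 0.1 and (lRMSD ≤ 10.0 or iRMSD ≤ 4.0); otherwise
    Incorrect.
    """
    f, i, l = metrics.fnat, metrics.irmsd, metrics.lrmsd
    if f >= 0.5 and (l <= 1.0 or i <= 1.0):
        return QualityClass.HIGH
    if f >= 0.3 and (l <= 5.0 or i <= 2.0):
        return QualityClass.MEDIUM
    if f >= 0.1 and (l <= 10.0 or i <= 4.0):
        return QualityClass.ACCEPTABLE
    return QualityClass.INCORRECT


def evaluate_model(
    model: ComplexStructure,
    reference: ComplexStructure,
    atom_set: AtomSet = "backbone",
    contact_cutoff: float = CONTACT_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> tuple[QualityMetrics, QualityClass]:
    """All three metrics plus the quality class for one model/reference pair."""
    metrics = QualityMetrics(
        fnat=fnat(model, reference, contact_cutoff),
        irmsd=interface_rmsd(model, reference, interface_cutoff, atom_set),
        lrmsd=ligand_rmsd(model, reference, atom_set),
    )
    return metrics, classify_capri(metrics)
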