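"""Poly-alanine template feature construction for structure-conditioned AF2 runs.

A merged docking pose becomes a structure template by keeping only the
backbone and Cβ atoms and relabelling every residue as alanine.  Stripping
side chains releases unnecessary constraints on the structure module and
forces side-chain rebuilding, while the query side keeps the true merged
sequence (with X at artificial linkers) and a deliberately blanked MSA that
contains only that one sequence.  Glycines, which have no Cβ, are given a
constructed one from ideal local geometry so the inclusive backbone+Cβ atom
mask is uniform.

The exported :class:`TemplateFeatureBundle` is this package's own versioned
schema carrying exactly the template-side fields a structure-conditioned run
needs (template sequence and residue classes, per-slot atom mask and
coordinates, no domain name, single-row MSA); wiring it into a particular
inference harness is out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_model import BACKBONE_ATOMS, AtomRecord, MergedTemplate

logger = logging.getLogger("abag")

SCHEMA_VERSION = 1

#: atom slot order of the mask/coordinate arrays
ATOM_SLOTS = ("N", "CA", "C", "O", "CB")

#: ideal C(alpha)-C(beta) bond length, Å
CB_BOND_LENGTH = 1.522


# ---------------------------------------------------------------------------
# local geometry

def place_dihedral(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d).

    Standard internal-coordinate (NeRF) construction; used both for the ideal
    helix generator and for Cβ reconstruction.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def construct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N, CA, C.

    The direction is the standard local-frame combination of the N→CA and
    CA→C difference vectors with their cross product (tetrahedral, correct
    L-chirality), renormalised to an exact 1.522 Å bond.  Built purely from
    local difference vectors, so equivariant under rigid motion.
    """
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    direction = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    direction = direction / np.linalg.norm(direction)
    return ca + CB_BOND_LENGTH * direction


# ---------------------------------------------------------------------------
# poly-alanine mutation

def to_polyalanine(template: MergedTemplate) -> MergedTemplate:
    """Strip a merged template to backbone+Cβ and relabel all residues alanine.

    Every real residue retains exactly N, CA, C, O and (constructed where
    missing) CB; linker residues stay untouched (aa X, no atoms); backbone
    coordinates are not moved.  The original sequence survives in
    ``query_sequence``.  Idempotent.
    """
    out = template.copy()
    keep = set(BACKBONE_ATOMS) | {"CB"}
    for res in out.merged_chain.residues:
        if res.aa == "X":
            continue
        res.atoms = [a for a in res.atoms if a.name in keep]
        have = {a.name: a for a in res.atoms}
        if "CB" not in have:
            if all(k in have for k in ("N", "CA", "C")):
                cb = construct_cb(
                    have["N"].position, have["CA"].position, have["C"].position
                )
                res.atoms.append(AtomRecord(name="CB", element="C", position=cb))
            else:
                logger.warning(
                    "cannot construct CB for residue %s%d: backbone incomplete",
                    res.aa, res.author_number,
                )
        res.aa = "A"
    return out


# ---------------------------------------------------------------------------
# feature bundle

@dataclass
class TemplateFeatureBundle:
    """Template-side features plus query sequence and blanked single-row MSA.

    Arrays are indexed by merged-chain position (length L including linker
    positions for the linker strategy); ``residue_numbers`` records the merged
    numbering, which carries the gaps under the gap strategy.
    """

    template_sequence: str              # all-alanine over template positions
    template_aatype: str                # per-position class labels, all alanine
    atom_mask: np.ndarray               # (L, 5) binary over ATOM_SLOTS
    coordinates: np.ndarray             # (L, 5, 3) Å; zeros where mask is 0
    residue_numbers: np.ndarray         # (L,) merged residue numbers
    query_sequence: str                 # true merged sequence, X at linkers
    msa: list[str] = field(default_factory=list)
    template_domain_names: None = None  # deliberately no template identity
    strategy: str = "linker"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.atom_mask = np.asarray(self.atom_mask, dtype=np.int8)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.validate()

    def validate(self) -> None:
        L = len(self.template_sequence)
        if not (
            len(self.template_aatype) == L
            and len(self.query_sequence) == L
            and self.atom_mask.shape == (L, len(ATOM_SLOTS))
            and self.coordinates.shape == (L, len(ATOM_SLOTS), 3)
            and self.residue_numbers.shape == (L,)
        ):
            raise ValueError("feature bundle length mismatch")
        if set(self.template_sequence) - {"A"}:
            raise ValueError("template_sequence must be all-alanine")
        if self.msa != [self.query_sequence]:
            raise ValueError("msa must contain exactly the query sequence")
        masked_out = self.atom_mask == 0
        if np.any(np.abs(self.coordinates[masked_out]) > 0):
            raise ValueError("coordinates present where atom_mask is 0")
        x_pos = np.array([aa == "X" for aa in self.query_sequence])
        if np.any(self.atom_mask[x_pos]):
            raise ValueError("linker (X) positions must have an all-zero mask")

    @property
    def n_positions(self) -> int:
        return len(self.template_sequence)


def build_features(template: MergedTemplate) -> TemplateFeatureBundle:
    """Build the feature bundle from an already poly-alanine merged template.

    The template side is the alanine sequence with the backbone+Cβ inclusive
    mask; the query side is the original merged sequence (X at linkers) and a
    blanked MSA holding only that sequence.
    """
    residues = template.merged_chain.residues
    if len(template.query_sequence) != len(residues):
        raise ValueError("query sequence length does not match merged chain")
    bad = [r for r in residues if r.aa not in ("A", "X")]
    if bad:
        raise ValueError(
            "template must be poly-alanine before feature construction "
            "(run to_polyalanine first)"
        )
    L = len(residues)
    mask = np.zeros((L, len(ATOM_SLOTS)), dtype=np.int8)
    coords = np.zeros((L, len(ATOM_SLOTS), 3), dtype=float)
    numbers = np.zeros(L, dtype=int)
    for i, res in enumerate(residues):
        numbers[i] = res.author_number
        for j, slot in enumerate(ATOM_SLOTS):
            atom = res.atom(slot)
            if atom is not None:
                mask[i, j] = 1
                coords[i, j] = atom.position
    return TemplateFeatureBundle(
        template_sequence="A" * L,
        template_aatype="A" * L,
        atom_mask=mask,
        coordinates=coords,
        residue_numbers=numbers,
        query_sequence=template.query_sequence,
        msa=[template.query_sequence],
        strategy=template.strategy,
    )


# ---------------------------------------------------------------------------
# serialization (versioned JSON schema; lossless via repr-precision floats)

def export_features(bundle: TemplateFeatureBundle, path: str | Path) -> None:
    payload = {
        "schema_version": bundle.schema_version,
        "strategy": bundle.strategy,
        "atom_slots": list(ATOM_SLOTS),
        "template_sequence": bundle.template_sequence,
        "template_aatype": bundle.template_aatype,
        "template_domain_names": None,
        "residue_numbers": bundle.residue_numbers.tolist(),
        "atom_mask": bundle.atom_mask.tolist(),
        "coordinates": bundle.coordinates.tolist(),
        "query_sequence": bundle.query_sequence,
        "msa": bundle.msa,
    }
    Path(path).write_text(json.dumps(payload))


def import_features(path: str | Path) -> TemplateFeatureBundle:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt feature file {path}: {exc}") from exc
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported feature schema version {payload.get('schema_version')!r}"
        )
    try:
        return TemplateFeatureBundle(
            template_sequence=payload["template_sequence"],
            template_aatype=payload["template_aatype"],
            atom_mask=np.array(payload["atom_mask"], dtype=np.int8),
            coordinates=np.array(payload["coordinates"], dtype=float),
            residue_numbers=np.array(payload["residue_numbers"], dtype=int),
            query_sequence=payload["query_sequence"],
            msa=list(payload["msa"]),
            strategy=payload.get("strategy", "linker"),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"invalid feature file {path}: {exc}") from exc


def write_query_fasta(bundle: TemplateFeatureBundle, path: str | Path,
                      name: str = "merged_query") -> None:
    """FASTA of the merged query sequence (the single MSA row)."""
    seq = bundle.query_sequence
    lines = [f">{name}"] + [seq[i:i + 60] for i in range(0, len(seq), 60)]
    Path(path).write_text("\n".join(lines) + "\n")
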