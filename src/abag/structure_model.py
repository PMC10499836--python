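"""Coordinate data model, PDB I/O and chain-merging for docked antibody-antigen poses.

The docking pipelines this package rescoring supports emit rigid-body poses as
multi-chain PDB files.  Before a pose can be handed to a structure-conditioned
AlphaFold2 run it must be merged into a single chain, either by inserting
artificial linker residues (encoded as unknown residues, never modelled) or by
leaving a large residue-numbering gap between chains.  This module owns the
in-memory structure types, PDB reading/writing, backbone extraction and both
merging strategies.

Conventions: coordinates in Å, residue indices 1-based, ranges closed,
hydrogens dropped on read by default (docking inputs had them removed), and
alternate locations resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("abag")

# ---------------------------------------------------------------------------
# residue naming

AA1 = "ACDEFGHIKLMNPQRSTVWYX"

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residue key used everywhere for model/reference correspondence
ResKey = tuple[str, int, str]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class AtomRecord:
    """One heavy atom: name, element, Cartesian position (Å), occupancy, B."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class ResidueRecord:
    """A residue: one-letter code (X for unknown), author numbering, atoms.

    Atom names are unique within a residue (alternate locations are resolved
    at parse time).  Unknown residues used as artificial linkers carry no
    atoms at all.
    """

    aa: str
    author_number: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa not in AA1:
            raise ValueError(f"unknown amino-acid code {self.aa!r}")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.aa}{self.author_number}"
            )

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class ChainStructure:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class ComplexStructure:
    """One antibody-antigen pose with a partner assignment.

    ``antibody_chains`` and ``antigen_chains`` must be disjoint, non-empty and
    together cover every chain.  The antibody is the mobile partner in the
    ligand-RMSD convention.
    """

    chains: list[ChainStructure]
    antibody_chains: frozenset[str]
    antigen_chains: frozenset[str]

    def __post_init__(self) -> None:
        self.antibody_chains = frozenset(self.antibody_chains)
        self.antigen_chains = frozenset(self.antigen_chains)
        ids = {c.chain_id for c in self.chains}
        if not self.antibody_chains or not self.antigen_chains:
            raise ValueError("both partners need at least one chain")
        if self.antibody_chains & self.antigen_chains:
            raise ValueError("antibody and antigen chain sets overlap")
        if self.antibody_chains | self.antigen_chains != ids:
            raise ValueError("partner assignment does not cover all chains")

    def chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain not found: {chain_id}")

    def partner_chains(self, side: Literal["antibody", "antigen"]) -> list[ChainStructure]:
        wanted = self.antibody_chains if side == "antibody" else self.antigen_chains
        return [c for c in self.chains if c.chain_id in wanted]

    def iter_residues(
        self, side: Literal["antibody", "antigen"] | None = None
    ) -> Iterator[tuple[ResKey, ResidueRecord]]:
        chains = self.chains if side is None else self.partner_chains(side)
        for c in chains:
            for r in c.residues:
                yield (c.chain_id, r.author_number, r.insertion_code), r

    @property
    def n_atoms(self) -> int:
        return sum(r.n_atoms for c in self.chains for r in c.residues)

    def copy(self) -> "ComplexStructure":
        return copy.deepcopy(self)


@dataclass
class MergedTemplate:
    """Chains of a pose merged into one chain for template construction.

    ``strategy="linker"`` inserts blocks of atom-less unknown (X) residues
    between chains and renumbers everything sequentially from 1;
    ``strategy="gap"`` keeps only real residues but offsets each following
    chain's numbering by a fixed gap.  ``index_map`` sends each original
    (chain id, author number, insertion code) to its merged residue number;
    ``query_sequence`` is the true merged amino-acid sequence with X at
    linker positions.
    """

    merged_chain: ChainStructure
    index_map: dict[ResKey, int]
    linker_positions: frozenset[int]
    strategy: Literal["linker", "gap"]
    query_sequence: str
    chain_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.linker_positions = frozenset(self.linker_positions)
        if len(set(self.index_map.values())) != len(self.index_map):
            raise ValueError("index_map must be injective")
        if self.strategy == "gap" and self.linker_positions:
            raise ValueError("gap strategy admits no linker residues")

    def real_residues(self) -> list[ResidueRecord]:
        return [r for r in self.merged_chain.residues if r.aa != "X"]

    def copy(self) -> "MergedTemplate":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# PDB reading

def read_pdb(
    path: str | Path,
    antibody_chains: Iterable[str],
    antigen_chains: Iterable[str],
    drop_hydrogens: bool = True,
) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by first altloc label alphabetically); hydrogens are dropped
    by default; waters and non-polymer heteroatoms are ignored.  Residues with
    names outside the 20 standard amino acids map to X.

    Raises ``KeyError("chain not found: ...")`` when a requested chain is
    absent and ``ValueError`` on unparseable input.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in PDB file {path}")
    model = st[0]

    ab = frozenset(antibody_chains)
    ag = frozenset(antigen_chains)
    wanted = ab | ag
    present = {ch.name for ch in model}
    missing = sorted(wanted - present)
    if missing:
        raise KeyError(f"chain not found: {', '.join(missing)}")

    chains: list[ChainStructure] = []
    for ch in model:
        if ch.name not in wanted:
            continue
        residues: list[ResidueRecord] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_water():
                continue
            if info is not None and info.is_amino_acid():
                aa = info.one_letter_code.upper()
                if aa not in AA1:
                    aa = "X"
            elif res.name in THREE_TO_ONE:
                aa = THREE_TO_ONE[res.name]
            else:
                continue  # ligands, ions
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if drop_hydrogens and atom.element.is_hydrogen:
                    continue
                cur = best.get(atom.name)
                if cur is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > cur.occ or (
                    atom.occ == cur.occ and atom.altloc < cur.altloc
                ):
                    best[atom.name] = atom
            atoms = [
                AtomRecord(
                    name=name,
                    element=best[name].element.name,
                    position=np.array(
                        [best[name].pos.x, best[name].pos.y, best[name].pos.z]
                    ),
                    occupancy=best[name].occ,
                    b_factor=best[name].b_iso,
                )
                for name in order
            ]
            residues.append(
                ResidueRecord(
                    aa=aa,
                    author_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
        if residues:
            chains.append(ChainStructure(chain_id=ch.name, residues=residues))

    found = {c.chain_id for c in chains}
    empty = sorted(wanted - found)
    if empty:
        raise KeyError(f"chain not found: {', '.join(empty)}")
    return ComplexStructure(chains=chains, antibody_chains=ab, antigen_chains=ag)


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_line(
    serial: int,
    atom: AtomRecord,
    resname: str,
    chain_id: str,
    resnum: int,
    icode: str,
) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    x, y, z = atom.position
    return (
        f"ATOM  {serial:>5d} {name:4s} {resname:>3s} {chain_id:1s}"
        f"{resnum:>4d}{icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structure: ComplexStructure | MergedTemplate, path: str | Path) -> None:
    """Write standard ATOM records, with TER between chains.

    Atom-less residues (artificial linkers) cannot be represented by ATOM
    records and are omitted; merged numbering is preserved so the omission is
    visible as a numbering gap.  Raises ``ValueError("no atoms to write")``
    for an empty structure.
    """
    if isinstance(structure, MergedTemplate):
        chains = [structure.merged_chain]
    else:
        chains = structure.chains
    if sum(r.n_atoms for c in chains for r in c.residues) == 0:
        raise ValueError("no atoms to write")

    lines: list[str] = []
    serial = 0
    for chain in chains:
        wrote_any = False
        for res in chain.residues:
            if not res.atoms:
                continue  # linker / placeholder residues carry no coordinates
            resname = ONE_TO_THREE[res.aa]
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _format_atom_line(
                        serial, atom, resname, chain.chain_id,
                        res.author_number, res.insertion_code,
                    )
                )
                wrote_any = True
        if wrote_any:
            serial += 1
            lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# backbone extraction

def extract_backbone(structure: ComplexStructure, include_cb: bool = True) -> ComplexStructure:
    """Keep only N, CA, C, O (and CB when ``include_cb``) in every residue.

    Residue counts are conserved; residues missing some backbone atoms keep
    whatever exists and are reported in the log.  Idempotent.
    """
    keep = set(BACKBONE_ATOMS) | ({"CB"} if include_cb else set())
    out = structure.copy()
    lacking: list[str] = []
    for chain in out.chains:
        for res in chain.residues:
            res.atoms = [a for a in res.atoms if a.name in keep]
            have = {a.name for a in res.atoms}
            if res.aa != "X" and not set(BACKBONE_ATOMS) <= have:
                lacking.append(f"{chain.chain_id}/{res.aa}{res.author_number}")
            elif include_cb and res.aa != "X" and res.aa != "G" and "CB" not in have:
                logger.debug("residue %s/%s%d lacks CB", chain.chain_id, res.aa,
                             res.author_number)
    if lacking:
        logger.warning("residues with incomplete backbone: %s", ", ".join(lacking))
    return out


# ---------------------------------------------------------------------------
# chain merging

def _ordered_chains(
    structure: ComplexStructure, chain_order: Sequence[str] | None
) -> list[ChainStructure]:
    if chain_order is not None:
        return [structure.chain(cid) for cid in chain_order]
    # antibody chains first (as stored: heavy then light by convention),
    # antigen chains last -- matching the docking-partner orientation
    return structure.partner_chains("antibody") + structure.partner_chains("antigen")


def merge_chains(
    structure: ComplexStructure,
    strategy: Literal["linker", "gap"] = "linker",
    linker_length: int = 50,
    gap_size: int = 200,
    chain_order: Sequence[str] | None = None,
    merged_chain_id: str = "M",
) -> MergedTemplate:
    """Merge all chains of a pose into a single chain.

    ``linker``: chains are connected by ``linker_length`` artificial unknown
    (X) residues carrying no atoms, and all residues are renumbered
    sequentially starting at 1.  ``gap``: only real residues are kept and the
    numbering of chain k+1 starts ``gap_size`` past the end of chain k (the
    gap is applied at every chain boundary).

    Sequential renumbering joins both ends of unsolved loops; junctions where
    the author numbering jumps are listed in a log warning.
    """
    if strategy not in ("linker", "gap"):
        raise ValueError(f"unknown merge strategy {strategy!r}")
    if len(structure.chains) < 2:
        raise ValueError("nothing to merge: structure has a single chain")

    ordered = _ordered_chains(structure, chain_order)
    merged: list[ResidueRecord] = []
    index_map: dict[ResKey, int] = {}
    linker_positions: set[int] = set()
    joined_loops: list[str] = []

    next_number = 1
    for k, chain in enumerate(ordered):
        if k > 0:
            if strategy == "linker":
                for _ in range(linker_length):
                    merged.append(ResidueRecord(aa="X", author_number=next_number))
                    linker_positions.add(next_number)
                    next_number += 1
            else:
                next_number += gap_size
        prev_author: int | None = None
        for res in chain.residues:
            if prev_author is not None and res.author_number > prev_author + 1:
                joined_loops.append(
                    f"{chain.chain_id}:{prev_author}-{res.author_number}"
                )
            prev_author = res.author_number
            new = copy.deepcopy(res)
            new.author_number = next_number
            new.insertion_code = ""
            merged.append(new)
            index_map[(chain.chain_id, res.author_number, res.insertion_code)] = next_number
            next_number += 1

    if joined_loops:
        logger.warning(
            "sequential renumbering artificially joins unsolved loop ends at: %s",
            ", ".join(joined_loops),
        )

    query = "".join(r.aa for r in merged)
    return MergedTemplate(
        merged_chain=ChainStructure(chain_id=merged_chain_id, residues=merged),
        index_map=index_map,
        linker_positions=frozenset(linker_positions),
        strategy=strategy,
        query_sequence=query,
        chain_order=tuple(c.chain_id for c in ordered),
    )
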