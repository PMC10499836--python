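"""Shared fixtures: toy complexes, stub chains, rigid-transform helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from abag import ComplexStructure, make_toy_complex

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from abag.structure_model import AtomRecord, ChainStructure, ResidueRecord


@pytest.fixture(scope="session")
def toy_complex() -> ComplexStructure:
    return make_toy_complex(12, 12, seed=7)


def stub_chain(chain_id: str, n_res: int, offset: np.ndarray | None = None,
               start_number: int = 1) -> ChainStructure:
    """Chain of CA-only residues spaced 3.8 Å along x (for merge arithmetic)."""
    if offset is None:
        offset = np.zeros(3)
    residues = [
        ResidueRecord(
            aa="A",
            author_number=start_number + i,
            atoms=[AtomRecord("CA", "C", np.array([3.8 * i, 0.0, 0.0]) + offset)],
        )
        for i in range(n_res)
    ]
    return ChainStructure(chain_id=chain_id, residues=residues)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_complex(complex_: ComplexStructure, rot: np.ndarray,
                      trans: np.ndarray) -> ComplexStructure:
    """Jointly transform every atom of a complex (returns a copy)."""
    out = complex_.copy()
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.position = rot @ atom.position + trans
    return out


def brute_force_contacts(complex_: ComplexStructure, cutoff: float = 5.0):
    """O(n²) residue-contact enumeration, independent of the contact engine."""
    pairs = set()
    ab = list(complex_.iter_residues("antibody"))
    ag = list(complex_.iter_residues("antigen"))
    for ab_key, ab_res in ab:
        for ag_key, ag_res in ag:
            hit = False
            for a in ab_res.atoms:
                for b in ag_res.atoms:
                    if np.linalg.norm(a.position - b.position) <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add((ab_key, ag_key))
    return pairs
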