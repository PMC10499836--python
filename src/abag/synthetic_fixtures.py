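"""Deterministic synthetic antibody-antigen fixtures for desk-scale testing.

Running real docking programs and the AF2 network over benchmark sets is far
outside desk scale, so this module generates everything the pipeline needs:

* idealized two-chain poly-alanine complexes with valid backbone geometry and
  a genuine 5 Å contact interface,
* rigid-body decoy ensembles built by perturbing the antibody along a
  magnitude ladder calibrated to span all four CAPRI quality classes,
* mock confidence metrics whose correlation with true model quality
  (``signal_strength``) and with each other (``agreement``) are controllable —
  emulating the empirical behaviour that the two confidence metrics agree
  well on good models and poorly on bad ones,
* a full labelled benchmark (scores + quality labels per model) that
  round-trips through every other module and the CLI.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import capri_eval
from .capri_eval import QualityClass, QualityMetrics
from .enrichment_eval import LabeledDecoySet
from .rescoring import composite_scores
from .structure_model import (
    AtomRecord,
    ChainStructure,
    ComplexStructure,
    ResidueRecord,
    write_pdb,
)
from .template_prep import construct_cb, place_dihedral

logger = logging.getLogger("abag")

# ideal backbone internal coordinates (Å, degrees) for the helix generator
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
PHI, PSI, OMEGA = -57.0, -47.0, 180.0

#: default rigid-perturbation ladder (rotation degrees, translation Å),
#: calibrated once so a 50-model ensemble spans all four CAPRI classes while
#: keeping positives scarce (roughly 10-25%), as docking decoy sets are
#: dominated by incorrect poses
DEFAULT_LADDER: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (2.0, 0.6),
    (5.0, 1.5),
    (9.0, 4.0),
    (12.0, 8.0),
    (15.0, 12.0),
    (20.0, 16.0),
    (25.0, 20.0),
    (30.0, 24.0),
    (35.0, 28.0),
    (40.0, 32.0),
    (45.0, 36.0),
    (50.0, 40.0),
    (55.0, 44.0),
    (60.0, 48.0),
    (25.0, 52.0),
    (35.0, 56.0),
    (45.0, 60.0),
    (55.0, 30.0),
    (60.0, 20.0),
)


@dataclass(frozen=True)
class DecoyGenSpec:
    """Rigid-body decoy ensemble parameters (deterministic for fixed seed)."""

    n_systems: int = 20
    n_models_per_system: int = 50
    ladder: tuple[tuple[float, float], ...] = DEFAULT_LADDER
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 or t < 0 for r, t in self.ladder):
            raise ValueError("ladder magnitudes must be non-negative")


@dataclass(frozen=True)
class MockConfidenceSpec:
    """Mock confidence-metric generator parameters.

    ``signal_strength`` scales how strongly both metrics track the latent
    true-quality score; ``agreement`` is the correlation of the two metrics'
    noise components (near 1 = the metrics agree, the regime where the
    composite works best); ``noise_sd`` the per-metric noise level.
    """

    signal_strength: float = 0.8
    agreement: float = 0.9
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not (0.0 <= self.agreement <= 1.0):
            raise ValueError("agreement must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class Decoy:
    """One perturbed pose with its ground-truth quality."""

    model_id: str
    structure: ComplexStructure
    metrics: QualityMetrics
    quality: QualityClass
    ladder_index: int


# ---------------------------------------------------------------------------
# toy complex construction

def _ideal_helix(n_res: int, chain_id: str) -> ChainStructure:
    """Ideal poly-alanine α-helix (N, CA, C, O, CB) built from internal coords."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues = []
    for i in range(n_res):
        if i > 0:
            n_next = place_dihedral(n, ca, c, BOND_C_N, ANGLE_CA_C_N, PSI)
            ca_next = place_dihedral(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_next = place_dihedral(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, PHI)
            n, ca, c = n_next, ca_next, c_next
        o = place_dihedral(n, ca, c, BOND_C_O, ANGLE_CA_C_O, PSI + 180.0)
        cb = construct_cb(n, ca, c)
        residues.append(
            ResidueRecord(
                aa="A",
                author_number=i + 1,
                atoms=[
                    AtomRecord("N", "N", n.copy()),
                    AtomRecord("CA", "C", ca.copy()),
                    AtomRecord("C", "C", c.copy()),
                    AtomRecord("O", "O", o.copy()),
                    AtomRecord("CB", "C", cb.copy()),
                ],
            )
        )
    return ChainStructure(chain_id=chain_id, residues=residues)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def _transform_chain(chain: ChainStructure, rot: np.ndarray, trans: np.ndarray,
                     about: np.ndarray | None = None) -> None:
    """In-place rigid transform of all atom positions (optionally about a pivot)."""
    pivot = np.zeros(3) if about is None else about
    for res in chain.residues:
        for atom in res.atoms:
            atom.position = rot @ (atom.position - pivot) + pivot + trans


def _chain_coords(chain: ChainStructure) -> np.ndarray:
    return np.vstack([a.position for r in chain.residues for a in r.atoms])


def make_toy_complex(n_ab: int = 12, n_ag: int = 12, seed: int = 0) -> ComplexStructure:
    """Two idealized helical chains placed in contact across a 5 Å interface.

    The antibody helix (chain H) sits at the origin; the antigen helix
    (chain A) is given a small seed-dependent orientation and slid toward the
    antibody until at least 3 residue contact pairs exist at the 5 Å cutoff.
    Deterministic and bitwise-reproducible for a fixed seed.
    """
    if n_ab < 4 or n_ag < 4:
        raise ValueError("need at least 4 residues per chain")
    rng = np.random.default_rng([seed, 9107])
    ab = _ideal_helix(n_ab, "H")
    ag = _ideal_helix(n_ag, "A")

    # small random reorientation of the antigen about its centroid
    axis = rng.normal(size=3)
    angle = rng.uniform(0.0, 20.0)
    centroid_ag = _chain_coords(ag).mean(axis=0)
    _transform_chain(ag, _rotation_matrix(axis, angle), np.zeros(3), about=centroid_ag)

    # approach direction: mostly +x with a small random lateral component
    lateral = rng.normal(scale=0.15, size=2)
    u = np.array([1.0, lateral[0], lateral[1]])
    u /= np.linalg.norm(u)

    ab_xyz = _chain_coords(ab)
    ab_centroid = ab_xyz.mean(axis=0)
    complex_ = ComplexStructure(
        chains=[ab, ag], antibody_chains={"H"}, antigen_chains={"A"}
    )
    # slide the antigen in until ≥3 residue contacts form
    for dist in np.arange(30.0, 3.0, -0.25):
        target = ab_centroid + dist * u
        shift = target - _chain_coords(ag).mean(axis=0)
        _transform_chain(ag, np.eye(3), shift)
        pairs = capri_eval.contact_pairs(complex_)
        if len(pairs) >= 3:
            return complex_
    raise RuntimeError("failed to place chains in contact")  # pragma: no cover


# ---------------------------------------------------------------------------
# decoy generation

def _perturb_antibody(
    reference: ComplexStructure,
    rot_deg: float,
    trans_mag: float,
    rng: np.random.Generator,
) -> ComplexStructure:
    """Rigidly perturb the antibody (antigen frame fixed)."""
    decoy = reference.copy()
    for chain in decoy.partner_chains("antibody"):
        centroid = _chain_coords(chain).mean(axis=0)
        rot = _rotation_matrix(rng.normal(size=3), rot_deg)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        _transform_chain(chain, rot, trans_mag * direction, about=centroid)
    return decoy


def make_decoys(reference: ComplexStructure, spec: DecoyGenSpec) -> list[Decoy]:
    """Rigid-body decoy ensemble with ground-truth CAPRI quality per decoy.

    Each decoy takes its (rotation, translation) magnitudes from the ladder,
    cycling, with random axis/direction; the default ladder yields all four
    quality classes in a default-size ensemble.
    """
    rng = np.random.default_rng([spec.seed, 23])
    decoys = []
    for i in range(spec.n_models_per_system):
        k = i % len(spec.ladder)
        rot_deg, trans_mag = spec.ladder[k]
        structure = _perturb_antibody(reference, rot_deg, trans_mag, rng)
        metrics, quality = capri_eval.evaluate_model(structure, reference)
        decoys.append(
            Decoy(
                model_id=f"m{i:03d}",
                structure=structure,
                metrics=metrics,
                quality=quality,
                ladder_index=k,
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# mock confidence metrics

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def mock_confidences(
    lrmsds,
    spec: MockConfidenceSpec,
    system_id: str = "sys",
    method: str = "synthetic",
    model_ids=None,
) -> pd.DataFrame:
    """Quality-correlated mock pLDDT/pTMscore records for one ensemble.

    The latent true-quality score is −log(1 + lRMSD) (monotone: better models
    score higher).  Each metric is ``signal_strength × z(latent)`` plus
    Gaussian noise; the two metrics' noise components correlate at
    ``agreement``.  Values are squashed to (0, 1) with a logistic.
    """
    lrmsds = np.asarray(lrmsds, dtype=float)
    n = lrmsds.size
    if n == 0:
        raise ValueError("ensemble must be non-empty")
    rng = np.random.default_rng([spec.seed, 77])
    latent = -np.log1p(lrmsds)
    sd = latent.std(ddof=1) if n > 1 else 0.0
    z = (latent - latent.mean()) / sd if sd > 0 else np.zeros(n)

    e1 = rng.standard_normal(n)
    e3 = rng.standard_normal(n)
    a = spec.agreement
    e2 = a * e1 + np.sqrt(max(0.0, 1.0 - a * a)) * e3

    plddt = _sigmoid(spec.signal_strength * z + spec.noise_sd * e1)
    ptm = _sigmoid(spec.signal_strength * z + spec.noise_sd * e2)
    if model_ids is None:
        model_ids = [f"m{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "system_id": system_id,
            "model_id": list(model_ids),
            "method": method,
            "plddt": plddt,
            "ptmscore": ptm,
        }
    )


# ---------------------------------------------------------------------------
# full benchmark

def make_benchmark(
    decoy_spec: DecoyGenSpec,
    confidence_spec: MockConfidenceSpec,
    out_dir: str | Path | None = None,
    keep_structures: bool = False,
) -> list[LabeledDecoySet]:
    """Generate a labelled multi-system benchmark for the whole pipeline.

    Per system: a toy complex, a rigid-body decoy ensemble with ground-truth
    CAPRI labels, signal-free oriented docking scores (pure noise — the
    docking baseline carries no information by construction), and mock
    confidence metrics turned into composite scores.  Both quality-label
    variants are carried; the synthetic rebuild step is identity, so they
    coincide.  When ``out_dir`` is given, reference/decoy PDBs plus
    ``scores.tsv`` and ``labels.tsv`` are written in the formats the CLI
    consumes.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    sets: list[LabeledDecoySet] = []
    score_rows = []
    label_rows = []
    for s in range(decoy_spec.n_systems):
        system_id = f"sys{s:03d}"
        sys_seed = decoy_spec.seed * 10_000 + s
        reference = make_toy_complex(
            n_ab=12 + s % 4, n_ag=12 + (s // 2) % 4, seed=sys_seed
        )
        decoys = make_decoys(
            reference,
            DecoyGenSpec(
                n_systems=1,
                n_models_per_system=decoy_spec.n_models_per_system,
                ladder=decoy_spec.ladder,
                seed=sys_seed,
            ),
        )
        rng = np.random.default_rng([decoy_spec.seed, 555, s])
        docking_scores = rng.standard_normal(len(decoys))  # signal-free baseline
        conf = mock_confidences(
            [d.metrics.lrmsd for d in decoys],
            MockConfidenceSpec(
                signal_strength=confidence_spec.signal_strength,
                agreement=confidence_spec.agreement,
                noise_sd=confidence_spec.noise_sd,
                seed=confidence_spec.seed * 10_000 + s,
            ),
            system_id=system_id,
            model_ids=[d.model_id for d in decoys],
        )
        conf = composite_scores(conf)
        df = pd.DataFrame(
            {
                "model_id": [d.model_id for d in decoys],
                "method": "synthetic",
                "docking_score": docking_scores,
                "composite": conf["composite"].to_numpy(),
                "plddt": conf["plddt"].to_numpy(),
                "ptmscore": conf["ptmscore"].to_numpy(),
                "class_docking": [d.quality for d in decoys],
                "class_af2": [d.quality for d in decoys],
                "fnat": [d.metrics.fnat for d in decoys],
                "irmsd": [d.metrics.irmsd for d in decoys],
                "lrmsd": [d.metrics.lrmsd for d in decoys],
            }
        )
        sets.append(LabeledDecoySet(system_id=system_id, models=df))

        if out_path is not None:
            sys_dir = out_path / system_id
            sys_dir.mkdir(exist_ok=True)
            write_pdb(reference, sys_dir / "reference.pdb")
            if keep_structures:
                for d in decoys:
                    write_pdb(d.structure, sys_dir / f"{d.model_id}.pdb")
            for d, ds, p, t, c in zip(
                decoys, docking_scores, conf["plddt"], conf["ptmscore"],
                conf["composite"],
            ):
                score_rows.append(
                    (system_id, d.model_id, "synthetic", ds, p, t, c)
                )
                label_rows.append(
                    (system_id, d.model_id, d.metrics.fnat, d.metrics.irmsd,
                     d.metrics.lrmsd, d.quality.label, d.quality.label)
                )

    if out_path is not None:
        pd.DataFrame(
            score_rows,
            columns=["system_id", "model_id", "method", "docking_score",
                     "plddt", "ptmscore", "composite"],
        ).to_csv(out_path / "scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            label_rows,
            columns=["system_id", "model_id", "fnat", "irmsd", "lrmsd",
                     "class_docking", "class_af2"],
        ).to_csv(out_path / "labels.tsv", sep="\t", index=False)
    return sets
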