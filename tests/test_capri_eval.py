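"""CAPRI metrics: contact engine vs brute force, superposition, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from abag import (
    QualityClass,
    QualityMetrics,
    classify_capri,
    conserved_contact_fraction,
    contact_pairs,
    fnat,
    interface_rmsd,
    kabsch_superpose,
    ligand_rmsd,
    make_toy_complex,
)
from abag.structure_model import AtomRecord, ChainStructure, ComplexStructure, ResidueRecord

from conftest import brute_force_contacts, random_rotation, transform_complex


def _ca_complex(ab_xyz: np.ndarray, ag_xyz: np.ndarray) -> ComplexStructure:
    """CA-only complex from coordinate arrays (one residue per row)."""
    def chain(cid, xyz):
        return ChainStructure(cid, [
            ResidueRecord("A", i + 1, atoms=[AtomRecord("CA", "C", p)])
            for i, p in enumerate(xyz)
        ])
    return ComplexStructure(
        chains=[chain("H", ab_xyz), chain("A", ag_xyz)],
        antibody_chains={"H"}, antigen_chains={"A"},
    )


class TestContacts:
    def test_cutoff_is_closed_interval(self):
        below = _ca_complex(np.array([[0.0, 0, 0]]), np.array([[4.9, 0, 0]]))
        at = _ca_complex(np.array([[0.0, 0, 0]]), np.array([[5.0, 0, 0]]))
        above = _ca_complex(np.array([[0.0, 0, 0]]), np.array([[5.1, 0, 0]]))
        assert len(contact_pairs(below)) == 1
        assert len(contact_pairs(at)) == 1  # ties at the cutoff count
        assert len(contact_pairs(above)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ab = rng.uniform(0, 12, size=(16, 3))
        ag = rng.uniform(0, 12, size=(16, 3))
        complex_ = _ca_complex(ab, ag)
        assert contact_pairs(complex_).pairs == brute_force_contacts(complex_)

    def test_only_cross_partner_pairs(self, toy_complex):
        for (ab_key, ag_key) in contact_pairs(toy_complex).pairs:
            assert ab_key[0] in toy_complex.antibody_chains
            assert ag_key[0] in toy_complex.antigen_chains


class TestFnat:
    def test_self_is_one(self, toy_complex):
        assert fnat(toy_complex, toy_complex) == 1.0

    def test_separated_model_is_zero(self, toy_complex):
        far = toy_complex.copy()
        for chain in far.partner_chains("antibody"):
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + np.array([50.0, 0, 0])
        assert fnat(far, toy_complex) == 0.0

    def test_partial_preservation_counts_pairs(self):
        # reference: 4 antigen residues each in contact with the single
        # antibody residue; model keeps only 2 of the 4 within 5 Å
        ab = np.array([[0.0, 0.0, 0.0]])
        ag_ref = np.array([[4.0, 0, 0], [0, 4.0, 0], [-4.0, 0, 0], [0, -4.0, 0]])
        ag_mod = np.array([[4.0, 0, 0], [0, 4.0, 0], [-9.0, 0, 0], [0, -9.0, 0]])
        reference = _ca_complex(ab, ag_ref)
        model = _ca_complex(ab, ag_mod)
        assert len(brute_force_contacts(reference)) == 4
        assert len(brute_force_contacts(model)) == 2
        assert fnat(model, reference) == 0.5

    def test_no_native_contacts_raises(self):
        reference = _ca_complex(np.array([[0.0, 0, 0]]), np.array([[50.0, 0, 0]]))
        with pytest.raises(ValueError, match="no native contacts"):
            fnat(reference, reference)

    def test_shares_engine_with_conserved_contact_fraction(self, toy_complex):
        rng = np.random.default_rng(5)
        jig = transform_complex(toy_complex, random_rotation(rng), rng.normal(size=3))
        assert conserved_contact_fraction(jig, toy_complex) == fnat(jig, toy_complex)

    def test_conserved_fraction_empty_template_raises(self):
        template = _ca_complex(np.array([[0.0, 0, 0]]), np.array([[50.0, 0, 0]]))
        with pytest.raises(ValueError, match="empty"):
            conserved_contact_fraction(template, template)


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(xyz, xyz)
        assert rmsd < 1e-12
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0, atol=1e-10)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        fixed = rng.normal(size=(20, 3))
        true_rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        true_trans = np.array([5.0, -2.0, 1.0])
        moving = (fixed - true_trans) @ true_rot  # inverse transform
        rot, trans, rmsd = kabsch_superpose(moving, fixed)
        assert rmsd < 1e-8
        assert np.allclose(rot, true_rot, atol=1e-8)
        assert np.allclose(trans, true_trans, atol=1e-8)
        assert np.isclose(np.linalg.det(rot), 1.0)

    def test_minimum_among_random_rigid_transforms(self):
        rng = np.random.default_rng(2)
        fixed = rng.normal(scale=5.0, size=(15, 3))
        moving = fixed + rng.normal(scale=1.0, size=(15, 3))
        _, _, best = kabsch_superpose(moving, fixed)
        for _ in range(1000):
            rot = random_rotation(rng)
            trans = rng.normal(scale=3.0, size=3)
            moved = moving @ rot.T + trans
            rmsd = np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


def _align_vectors_rmsd(moving, fixed):
    """Independent superposition oracle via scipy's align_vectors."""
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    rot, _ = Rotation.align_vectors(fc, mc)
    return np.sqrt(np.mean(np.sum((rot.apply(mc) - fc) ** 2, axis=1)))


class TestInterfaceRmsd:
    def test_rigidly_moved_model_is_zero(self, toy_complex):
        rng = np.random.default_rng(4)
        moved = transform_complex(toy_complex, random_rotation(rng), rng.normal(size=3))
        assert interface_rmsd(moved, toy_complex) < 1e-8

    def test_matches_independent_superposition_oracle(self, toy_complex):
        rng = np.random.default_rng(6)
        model = toy_complex.copy()
        # perturb one interface atom and a few others
        for chain in model.chains:
            for res in chain.residues[::3]:
                res.atoms[0].position = res.atoms[0].position + rng.normal(scale=0.5, size=3)
        from abag.capri_eval import _matched_coords, interface_residues
        keys = interface_residues(toy_complex)
        mod_xyz, ref_xyz = _matched_coords(model, toy_complex, keys, None, "backbone")
        expected = _align_vectors_rmsd(mod_xyz, ref_xyz)
        assert np.isclose(interface_rmsd(model, toy_complex), expected, atol=1e-6)

    def test_ca_and_backbone_selections_differ(self, toy_complex):
        rng = np.random.default_rng(8)
        model = toy_complex.copy()
        # asymmetric perturbation: move only carbonyl O atoms
        for chain in model.chains:
            for res in chain.residues:
                o = res.atom("O")
                if o is not None:
                    o.position = o.position + rng.normal(scale=1.0, size=3)
        ca_val = interface_rmsd(model, toy_complex, atom_set="CA")
        bb_val = interface_rmsd(model, toy_complex, atom_set="backbone")
        assert ca_val < 1e-8  # CAs untouched
        assert bb_val > 0.1

    def test_empty_interface_raises(self):
        apart = _ca_complex(np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]),
                            np.array([[50.0, 0, 0], [53.8, 0, 0], [57.6, 0, 0]]))
        with pytest.raises(ValueError, match="interface"):
            interface_rmsd(apart, apart)


class TestLigandRmsd:
    def test_self_is_zero(self, toy_complex):
        assert ligand_rmsd(toy_complex, toy_complex) < 1e-12

    def test_pure_antibody_translation_preserved(self, toy_complex):
        model = toy_complex.copy()
        for chain in model.partner_chains("antibody"):
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + np.array([3.0, 0, 0])
        assert np.isclose(ligand_rmsd(model, toy_complex), 3.0, atol=1e-8)

    def test_combined_rotation_matches_two_stage_oracle(self, toy_complex):
        rng = np.random.default_rng(9)
        model = transform_complex(toy_complex, random_rotation(rng), rng.normal(size=3))
        for chain in model.partner_chains("antibody"):
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + np.array([0.0, 2.0, 0])
        from abag.capri_eval import _matched_coords
        ag_mod, ag_ref = _matched_coords(model, toy_complex, None, "antigen", "backbone")
        rot, trans, _ = kabsch_superpose(ag_mod, ag_ref)
        ab_mod, ab_ref = _matched_coords(model, toy_complex, None, "antibody", "backbone")
        expected = np.sqrt(np.mean(np.sum((ab_mod @ rot.T + trans - ab_ref) ** 2, axis=1)))
        assert np.isclose(ligand_rmsd(model, toy_complex), expected, atol=1e-10)


class TestClassification:
    @pytest.mark.parametrize(
        "metrics,expected",
        [
            ((0.6, 0.8, 0.5), QualityClass.HIGH),
            ((0.05, 0.5, 0.5), QualityClass.INCORRECT),  # fnat gate fails
            ((0.15, 3.5, 12.0), QualityClass.ACCEPTABLE),  # iRMSD branch
            ((0.35, 1.8, 7.0), QualityClass.MEDIUM),
            ((0.5, 1.0, 1.0), QualityClass.HIGH),  # thresholds inclusive
            ((0.09, 0.5, 0.5), QualityClass.INCORRECT),
        ],
    )
    def test_classification_table(self, metrics, expected):
        f, i, l = metrics
        assert classify_capri(QualityMetrics(fnat=f, irmsd=i, lrmsd=l)) == expected

    @given(
        fnat_=st.floats(0, 1), irmsd=st.floats(0, 20), lrmsd=st.floats(0, 60),
        better=st.sampled_from(["fnat", "irmsd", "lrmsd"]),
        delta=st.floats(0.01, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_metric(self, fnat_, irmsd, lrmsd, better, delta):
        base = classify_capri(QualityMetrics(fnat=fnat_, irmsd=irmsd, lrmsd=lrmsd))
        improved = {
            "fnat": QualityMetrics(fnat=min(1.0, fnat_ + delta / 5), irmsd=irmsd, lrmsd=lrmsd),
            "irmsd": QualityMetrics(fnat=fnat_, irmsd=max(0.0, irmsd - delta), lrmsd=lrmsd),
            "lrmsd": QualityMetrics(fnat=fnat_, irmsd=irmsd, lrmsd=max(0.0, lrmsd - delta)),
        }[better]
        assert classify_capri(improved) >= base

    def test_positive_means_at_least_acceptable(self):
        assert QualityClass.ACCEPTABLE.positive
        assert QualityClass.HIGH.positive
        assert not QualityClass.INCORRECT.positive
        assert (QualityClass.HIGH > QualityClass.MEDIUM
                > QualityClass.ACCEPTABLE > QualityClass.INCORRECT)


class TestRigidInvariance:
    def test_all_metrics_invariant_under_joint_transforms(self):
        reference = make_toy_complex(10, 10, seed=3)
        model = make_toy_complex(10, 10, seed=3)
        for chain in model.partner_chains("antibody"):
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + np.array([1.0, 0.5, 0.0])
        f0 = fnat(model, reference)
        i0 = interface_rmsd(model, reference)
        l0 = ligand_rmsd(model, reference)
        rng = np.random.default_rng(12)
        for _ in range(25):
            rot, trans = random_rotation(rng), rng.normal(scale=20.0, size=3)
            m2 = transform_complex(model, rot, trans)
            r2 = transform_complex(reference, rot, trans)
            assert fnat(m2, r2) == f0
            assert abs(interface_rmsd(m2, r2) - i0) < 1e-8
            assert abs(ligand_rmsd(m2, r2) - l0) < 1e-8
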