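"""Template sanitization, superposition, COM gating, symmetry RMSD, states, H-bonds."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from cofoldeval import pose_eval as pe
from cofoldeval import synthetic_data as sd
from cofoldeval.complex_io import Atom, ComplexStructure


def _embedded(smiles, seed=0):
    els, xyz = sd.embed_ligand(smiles, seed=seed)
    return els, xyz


# ---------------------------------------------------------------------------
# sanitize_with_template
# ---------------------------------------------------------------------------

class TestSanitize:
    def test_benzene_aromatic_bonds(self):
        els, xyz = _embedded("c1ccccc1")
        lig = pe.sanitize_with_template(els, xyz, "c1ccccc1")
        assert lig.n_heavy == 6
        assert all(b.GetIsAromatic() for b in lig.mol.GetBonds())

    def test_element_multiset_mismatch(self):
        els, xyz = _embedded("Cc1ccccc1")  # toluene coordinates
        with pytest.raises(pe.TemplateError):
            pe.sanitize_with_template(els, xyz, "c1ccccc1")  # benzene template

    def test_nitro_dialects_normalize_to_same_template(self):
        t1 = pe._template_from_smiles("c1ccccc1N(=O)=O")
        t2 = pe._template_from_smiles("c1ccccc1[N+](=O)[O-]")
        assert Chem.MolToSmiles(t1) == Chem.MolToSmiles(t2)

    def test_hydrogens_in_input_are_ignored(self):
        els, xyz = _embedded("CO")
        els_h = els + ["H"]
        xyz_h = np.vstack([xyz, xyz[0] + [0.0, 0.0, 1.0]])
        lig = pe.sanitize_with_template(els_h, xyz_h, "CO")
        assert lig.n_heavy == 2


# ---------------------------------------------------------------------------
# automorphisms / match_atoms
# ---------------------------------------------------------------------------

def brute_force_automorphisms(mol):
    """All element- and adjacency-preserving atom permutations, by enumeration."""
    n = mol.GetNumAtoms()
    els = [a.GetSymbol() for a in mol.GetAtoms()]
    adj = np.zeros((n, n), dtype=bool)
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx(), b.GetEndAtomIdx()] = True
        adj[b.GetEndAtomIdx(), b.GetBeginAtomIdx()] = True
    out = []
    for perm in itertools.permutations(range(n)):
        if any(els[i] != els[perm[i]] for i in range(n)):
            continue
        if all(adj[i, j] == adj[perm[i], perm[j]]
               for i in range(n) for j in range(i + 1, n)):
            out.append(perm)
    return out


@pytest.mark.parametrize("smiles,expected", [
    ("c1ccccc1", 12),        # 6 rotations x 2 reflections
    ("Cc1ccc(C)cc1", 4),     # para-xylene
    ("CC(=O)Nc1ccccc1F", 1), # asymmetric: identity only
])
def test_automorphism_counts_match_brute_force(smiles, expected):
    mol = Chem.MolFromSmiles(smiles)
    autos = pe.enumerate_automorphisms(mol)
    assert len(autos) == expected
    assert sorted(autos) == sorted(brute_force_automorphisms(mol))
    assert tuple(range(mol.GetNumAtoms())) in autos  # identity always present


def test_match_atoms_requires_same_template():
    els, xyz = _embedded("CCO")
    a = pe.sanitize_with_template(els, xyz, "CCO")
    els2, xyz2 = _embedded("CCN")
    b = pe.sanitize_with_template(els2, xyz2, "CCN")
    with pytest.raises(pe.CorrespondenceError):
        pe.match_atoms(a, b)
    autos = pe.match_atoms(a, a)
    assert tuple(range(3)) in autos


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_self_alignment_is_identity(self, receptor):
        res = pe.superpose_ca(receptor, receptor)
        assert res.ca_rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-6

    def test_rigid_motion_recovered(self, receptor, rng):
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = ComplexStructure(
            [Atom(a.entity_kind, a.chain, a.res_name, a.res_seq, a.name,
                  a.element, tuple(np.asarray(a.xyz) @ R.T + t), a.is_hydrogen)
             for a in receptor.atoms], None, "mmCIF", None)
        res = pe.superpose_ca(moved, receptor)
        assert res.ca_rmsd == pytest.approx(0.0, abs=1e-6)
        assert res.n_ca == len(receptor.ca_map())

    def test_matches_independent_kabsch_oracle(self, rng):
        """One Cα displaced by 1 Å: compare against scipy's align_vectors."""
        n = 10
        ref = rng.uniform(-10, 10, (n, 3))
        mob = ref.copy()
        mob[0] += [1.0, 0.0, 0.0]
        R, t, rmsd = pe.kabsch(mob, ref)
        rot, rssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        oracle_rmsd = np.sqrt(rssd**2 / n)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)
        np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-6)

    def test_too_few_common_ca(self, receptor):
        chopped = ComplexStructure(
            [a for a in receptor.atoms if a.res_seq < 22], None, "mmCIF", None)
        with pytest.raises(pe.AlignmentError):
            pe.superpose_ca(chopped, receptor)


# ---------------------------------------------------------------------------
# COM distance
# ---------------------------------------------------------------------------

class TestCOM:
    def test_identical_and_translated(self):
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]])
        els = ["C", "C", "C"]
        assert pe.com_distance(xyz, xyz, els) == 0.0
        assert pe.com_distance(xyz + [3, 0, 0], xyz, els) == pytest.approx(3.0)

    def test_mass_weighting_hand_value(self):
        """C at origin, O at (2,0,0) vs O moved to (4,0,0): COM shift
        = m_O/(m_C+m_O) x 2 = 15.999/28.01 x 2."""
        ref = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        prd = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        d = pe.com_distance(prd, ref, ["C", "O"])
        assert d == pytest.approx(15.999 / (12.011 + 15.999) * 2.0, abs=1e-6)

    def test_geometric_weighting_differs(self):
        ref = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        prd = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert pe.com_distance(prd, ref, ["C", "O"], "geometric") == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# symmetry RMSD
# ---------------------------------------------------------------------------

class TestSymmetryRMSD:
    def _benzene(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        th = np.arange(6) * np.pi / 3
        xyz = np.column_stack([1.39 * np.cos(th), 1.39 * np.sin(th), np.zeros(6)])
        return mol, xyz

    def test_identity_and_translation(self):
        mol, xyz = self._benzene()
        autos = pe.enumerate_automorphisms(mol)
        assert pe.symmetry_rmsd(xyz, xyz, autos) == 0.0
        assert pe.symmetry_rmsd(xyz + [0, 0, 2.5], xyz, autos) == pytest.approx(2.5)

    def test_ring_rotation_is_zero_under_symmetry(self):
        mol, xyz = self._benzene()
        rotated = np.roll(xyz, 1, axis=0)  # relabel by one ring step
        autos = pe.enumerate_automorphisms(mol)
        identity = [tuple(range(6))]
        assert pe.rmsd_under_map(rotated, xyz, identity[0]) > 1.0
        assert pe.symmetry_rmsd(rotated, xyz, autos) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_never_exceeds_identity(self, rng):
        mol, xyz = self._benzene()
        autos = pe.enumerate_automorphisms(mol)
        for _ in range(20):
            noisy = xyz + rng.normal(0, 1.0, xyz.shape)
            sym = pe.symmetry_rmsd(noisy, xyz, autos)
            ident = pe.rmsd_under_map(noisy, xyz, tuple(range(6)))
            assert sym <= ident + 1e-12


# ---------------------------------------------------------------------------
# pocket states
# ---------------------------------------------------------------------------

class TestClassifyState:
    def test_ground_vs_itself(self, receptor):
        assert pe.classify_state(receptor, receptor) == "ground"

    def test_open_state_by_construction(self, receptor):
        atoms = [Atom(a.entity_kind, a.chain, a.res_name, a.res_seq, a.name,
                      a.element,
                      tuple(np.asarray(a.xyz) + (8.0 if a.res_seq in (129, 130) else 0.0)
                            * np.array([1.0, 0, 0])),
                      a.is_hydrogen)
                 for a in receptor.atoms]
        moved = ComplexStructure(atoms, None, "mmCIF", None)
        assert pe.classify_state(moved, receptor) == "open"

    def test_twisted_state_by_construction(self, receptor):
        atoms = []
        c156 = np.asarray(receptor.residue_atom(156, "C").xyz)
        o156 = np.asarray(receptor.residue_atom(156, "O").xyz)
        flipped_o = tuple(2 * c156 - o156)  # invert the C=O vector
        for a in receptor.atoms:
            xyz = flipped_o if (a.res_seq == 156 and a.name == "O") else a.xyz
            atoms.append(Atom(a.entity_kind, a.chain, a.res_name, a.res_seq,
                              a.name, a.element, xyz, a.is_hydrogen))
        assert pe.classify_state(ComplexStructure(atoms, None, "mmCIF", None),
                                 receptor) == "twisted"

    def test_missing_residue_is_unknown(self, receptor):
        chopped = ComplexStructure(
            [a for a in receptor.atoms if a.res_seq != 156], None, "mmCIF", None)
        assert pe.classify_state(chopped, receptor) == "unknown"


# ---------------------------------------------------------------------------
# H-bonds
# ---------------------------------------------------------------------------

class TestHBonds:
    def _ligand_at(self, offset):
        els, xyz = _embedded("NCCO")  # amino alcohol: N and O polar atoms
        lig = pe.sanitize_with_template(els, xyz, "NCCO")
        shift = offset - lig.coords[0]
        return lig, lig.coords + shift

    def test_bond_at_29_but_not_38(self, receptor):
        bb_o = np.asarray(receptor.residue_atom(22, "O").xyz)
        lig, coords = self._ligand_at(bb_o + [2.9, 0, 0])
        rep = pe.detect_hbonds(receptor, lig, coords)
        assert 22 in rep.residues()
        lig, coords = self._ligand_at(bb_o + [3.8, 0, 0])
        coords = coords + 100.0  # move the whole ligand far away
        rep = pe.detect_hbonds(receptor, lig, coords)
        assert rep.bonds == []

    def test_missed_and_spurious_interactions(self, receptor):
        bb22 = np.asarray(receptor.residue_atom(22, "O").xyz)
        bb156 = np.asarray(receptor.residue_atom(156, "O").xyz)
        lig, ref_coords = self._ligand_at(bb22 + [2.8, 0, 0])
        _, pred_coords = self._ligand_at(bb156 + [2.8, 0, 0])
        ref_rep = pe.detect_hbonds(receptor, lig, ref_coords)
        pred_rep = pe.detect_hbonds(receptor, lig, pred_coords)
        table = pe.compare_hbonds(ref_rep, pred_rep, (22, 23, 156, 157))
        assert table[22]["reference"] and not table[22]["predicted"]   # missed
        assert table[156]["predicted"] and not table[156]["reference"]  # spurious


# ---------------------------------------------------------------------------
# full pipeline invariants
# ---------------------------------------------------------------------------

class TestEvaluatePose:
    def test_planted_rmsd_recovered_in_memory(self, receptor, pose_spec):
        for i, target in enumerate([0.5, 1.9, 3.7]):
            pred, ref = sd.make_pose_pair(receptor, pose_spec, target, seed=100 + i)
            comp = pe.evaluate_pose(pred, ref, pose_spec.smiles, f"p{i}")
            assert comp.failure is None
            assert comp.rmsd == pytest.approx(target, abs=1e-6)
            assert comp.success == (target < 2.0)
            assert comp.n_matched_atoms == 11

    def test_common_rigid_motion_invariance(self, receptor, pose_spec, rng):
        """Applying one rigid motion to both structures changes nothing."""
        pred, ref = sd.make_pose_pair(receptor, pose_spec, 1.2, seed=42)
        base = pe.evaluate_pose(pred, ref, pose_spec.smiles, "x")
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.uniform(-15, 15, 3)

        def move(st):
            return ComplexStructure(
                [Atom(a.entity_kind, a.chain, a.res_name, a.res_seq, a.name,
                      a.element, tuple(np.asarray(a.xyz) @ R.T + t), a.is_hydrogen)
                 for a in st.atoms], st.ligand_component_id, st.source_format, None)

        moved = pe.evaluate_pose(move(pred), move(ref), pose_spec.smiles, "x")
        assert moved.rmsd == pytest.approx(base.rmsd, abs=1e-6)
        assert moved.com_distance == pytest.approx(base.com_distance, abs=1e-6)

    def test_out_of_pocket_translation_gates_com(self, receptor, pose_spec):
        spec = sd.PoseSpec(perturb_mode="translate", smiles=pose_spec.smiles)
        pred, ref = sd.make_pose_pair(receptor, spec, 3.0, seed=9)
        comp = pe.evaluate_pose(pred, ref, spec.smiles, "far")
        assert comp.com_distance == pytest.approx(3.0, abs=1e-6)
        assert not comp.in_pocket and not comp.success

    def test_sanitization_failure_recorded_not_raised(self, receptor, pose_spec):
        pred, ref = sd.make_pose_pair(receptor, pose_spec, 1.0, seed=5)
        comp = pe.evaluate_pose(pred, ref, "c1ccccc1", "bad")  # wrong template
        assert comp.failure == "sanitization"
        assert not comp.sanitization_ok and not comp.success
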