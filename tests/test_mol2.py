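"""MOL2 parsing, the (F, S) encoding, marking, labels, color merging."""

import numpy as np
import pytest

from pispki import (
    BindingRecord,
    ELEMENT_GROUPS,
    MARK_EMPHASIS,
    MERGE_TABLE,
    strip_mark,
    MoleculeGraph,
    Mol2ParseError,
    N_COLORS,
    SYBYL_ATOM_TYPES,
    bond_class,
    conv_input,
    mark_atom,
    merge_colors,
    parse_mol2,
    parse_mol2_text,
    resolve_labels,
    write_mol2,
)
from pispki.mol2 import _COLOR_INDEX


class TestParse:
    def test_two_molecules_parsed(self, mol2_file):
        mols = parse_mol2(mol2_file)
        assert [m.n_atoms for m in mols] == [4, 3]
        assert mols[0].molecule_id == "ethanamide-like"

    def test_bond_classes(self, mol2_file):
        amide, benzene = parse_mol2(mol2_file)
        # single -> 1, double -> 2, amide -> 3, aromatic -> 4
        assert amide.S[0, 1] == 1
        assert amide.S[1, 2] == 2
        assert amide.S[1, 3] == 3
        assert benzene.S[0, 1] == 4

    @pytest.mark.parametrize("tstr,cls", [
        ("1", 1), ("3", 1), ("du", 1), ("un", 1), ("nc", 1),
        ("2", 2), ("am", 3), ("ar", 4), ("pi", 0), ("weird", 0),
    ])
    def test_bond_class_table(self, tstr, cls):
        assert bond_class(tstr) == cls

    def test_atom_colors_one_hot(self, mol2_file):
        mol = parse_mol2(mol2_file)[0]
        f = mol.F
        assert f.shape == (4, N_COLORS)
        assert np.array_equal(f.sum(axis=1), np.ones(4))
        assert f[0, _COLOR_INDEX["C.3"]] == 1
        assert f[3, _COLOR_INDEX["N.am"]] == 1

    def test_symmetry_and_zero_diagonal(self, mol2_file):
        for mol in parse_mol2(mol2_file):
            assert np.array_equal(mol.S, mol.S.T)
            assert np.all(np.diag(mol.S) == 0)
            assert mol.S.max() <= 4

    def test_unknown_atom_type_names_offender(self, tmp_path):
        bad = ("@<TRIPOS>MOLECULE\nbad\n1 0 0 0 0\nSMALL\nNO_CHARGES\n"
               "@<TRIPOS>ATOM\n1 X1 0 0 0 Xx.9 1 LIG 0.0\n")
        p = tmp_path / "bad.mol2"
        p.write_text(bad)
        with pytest.raises(Mol2ParseError, match="Xx.9"):
            parse_mol2(p)

    def test_malformed_atom_reports_line(self):
        text = ("@<TRIPOS>MOLECULE\nbad\n1 0 0\nSMALL\nX\n"
                "@<TRIPOS>ATOM\n1 C1 0.0\n")
        with pytest.raises(Mol2ParseError, match=":7"):
            parse_mol2_text(text)

    def test_single_atom_molecule(self):
        text = ("@<TRIPOS>MOLECULE\none\n1 0 0\nSMALL\nX\n"
                "@<TRIPOS>ATOM\n1 C1 0 0 0 C.3 1 LIG 0.0\n")
        mol = parse_mol2_text(text)[0]
        assert mol.S.shape == (1, 1) and mol.S[0, 0] == 0
        assert mol.F.sum() == 1

    def test_roundtrip_write_parse(self, small_molecules, tmp_path):
        p = tmp_path / "rt.mol2"
        write_mol2(small_molecules, p)
        back = parse_mol2(p)
        assert len(back) == len(small_molecules)
        for a, b in zip(small_molecules, back):
            assert np.array_equal(a.colors, b.colors)
            assert np.array_equal(a.S, b.S)

    def test_writer_cross_checked_against_rdkit(self, mol2_file, tmp_path):
        """An independent MOL2 reader (rdkit) agrees with ours on atom and
        bond counts and on which bonds are aromatic."""
        from rdkit import Chem

        mols = parse_mol2(mol2_file)
        p = tmp_path / "roundtrip.mol2"
        write_mol2(mols, p)
        blocks = p.read_text().split("@<TRIPOS>MOLECULE")[1:]
        for ours, block in zip(mols, blocks):
            rd = Chem.MolFromMol2Block("@<TRIPOS>MOLECULE" + block,
                                       sanitize=False, removeHs=False)
            assert rd is not None
            assert rd.GetNumAtoms() == ours.n_atoms
            assert rd.GetNumBonds() == int((ours.S > 0).sum() // 2)
            n_ar = sum(1 for b in rd.GetBonds()
                       if b.GetBondType() == Chem.BondType.AROMATIC)
            assert n_ar == int((ours.S == 4).sum() // 2)

    def test_vocabulary_sizes(self):
        assert len(SYBYL_ATOM_TYPES) == 35
        assert len(set(SYBYL_ATOM_TYPES)) == 35
        assert len(ELEMENT_GROUPS) == 16
        assert set(MERGE_TABLE.values()) == set(ELEMENT_GROUPS)


class TestGraphInvariants:
    def test_asymmetric_s_rejected(self):
        s = np.zeros((2, 2), dtype=int)
        s[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            MoleculeGraph("x", [0, 1], s)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            MoleculeGraph("x", [0], np.array([[2]]))


class TestMarking:
    def test_mark_column(self, mol2_file):
        mol = parse_mol2(mol2_file)[0]
        sp = mark_atom(mol, 2)
        assert sp.F_marked.shape == (4, N_COLORS + 1)
        assert np.array_equal(sp.F_marked[:, -1], [0, 1, 0, 0])

    def test_mark_strip_recovers_f(self, mol2_file):
        mol = parse_mol2(mol2_file)[0]
        sp = mark_atom(mol, 3)
        assert np.array_equal(strip_mark(sp), mol.F)

    def test_marked_row_color_emphasized(self, mol2_file):
        mol = parse_mol2(mol2_file)[0]
        sp = mark_atom(mol, 2)
        assert sp.F_marked[1, :-1].sum() == MARK_EMPHASIS
        assert sp.F_marked[0, :-1].sum() == 1.0
        # the marked atom's color is still the argmax of its row
        assert sp.F_marked[1, :-1].argmax() == mol.colors[1]

    def test_n_samples_share_structure(self, mol2_file):
        mol = parse_mol2(mol2_file)[0]
        sps = [mark_atom(mol, i) for i in range(1, mol.n_atoms + 1)]
        assert len(sps) == mol.n_atoms
        marks = {tuple(sp.F_marked[:, -1]) for sp in sps}
        assert len(marks) == mol.n_atoms  # all distinct
        for sp in sps:
            assert np.array_equal(sp.S, mol.S)

    @pytest.mark.parametrize("i", [0, 5])
    def test_out_of_range(self, mol2_file, i):
        mol = parse_mol2(mol2_file)[0]
        with pytest.raises(IndexError):
            mark_atom(mol, i)


class TestConvInput:
    def test_single_atom(self):
        mol = MoleculeGraph("x", [0], np.zeros((1, 1), dtype=int))
        assert np.array_equal(conv_input(mol), [[-1.0]])

    def test_two_atoms_hand_derived(self):
        mol = MoleculeGraph("x", [1, 4], np.array([[0, 1], [1, 0]]))
        assert np.array_equal(conv_input(mol), [[-2.0, 1.0], [1.0, -5.0]])

    def test_off_diagonal_equals_s(self, small_molecules):
        for mol in small_molecules:
            sc = conv_input(mol)
            off = ~np.eye(mol.n_atoms, dtype=bool)
            assert np.array_equal(sc[off], mol.S[off].astype(float))
            assert np.array_equal(np.diag(sc), -(mol.colors + 1.0))


class TestResolveLabels:
    def test_union_across_structures(self):
        recs = [
            BindingRecord("K", "I", 1, frozenset({1, 2})),
            BindingRecord("K", "I", 2, frozenset({2, 5})),
            BindingRecord("K", "I", 3, frozenset()),
        ]
        assert np.array_equal(resolve_labels(recs, 6), [1, 1, 0, 0, 1, 0])

    def test_bound_in_one_structure_only_is_positive(self):
        recs = [BindingRecord("K", "I", 1, frozenset({3})),
                BindingRecord("K", "I", 2, frozenset())]
        assert resolve_labels(recs, 4)[2] == 1

    def test_single_structure_is_membership(self):
        y = resolve_labels([BindingRecord("K", "I", 1, frozenset({1, 4}))], 4)
        assert np.array_equal(y, [1, 0, 0, 1])

    def test_order_independent(self):
        recs = [BindingRecord("K", "I", m, frozenset(b))
                for m, b in [(1, {1}), (2, {2, 3}), (3, {5})]]
        fwd = resolve_labels(recs, 5)
        rev = resolve_labels(recs[::-1], 5)
        assert np.array_equal(fwd, rev)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            resolve_labels([], 3)

    def test_mixed_pairs_rejected(self):
        recs = [BindingRecord("K1", "I", 1, frozenset({1})),
                BindingRecord("K2", "I", 1, frozenset({1}))]
        with pytest.raises(ValueError):
            resolve_labels(recs, 3)

    def test_out_of_range_atom(self):
        with pytest.raises(ValueError, match="out of range"):
            resolve_labels([BindingRecord("K", "I", 1, frozenset({9}))], 4)


class TestMergeColors:
    def test_same_element_subtypes_merge(self):
        f = np.zeros((2, N_COLORS))
        f[0, _COLOR_INDEX["C.3"]] = 1
        f[1, _COLOR_INDEX["C.ar"]] = 1
        m = merge_colors(f)
        assert m.shape == (2, 16)
        assert np.array_equal(m[0], m[1])

    def test_rows_stay_one_hot(self, small_molecules):
        for mol in small_molecules:
            m = merge_colors(mol.F)
            assert np.array_equal(m.sum(axis=1), np.ones(mol.n_atoms))

    def test_idempotent(self, small_molecules):
        m1 = merge_colors(small_molecules[0].F)
        assert np.array_equal(merge_colors(m1), m1)

    def test_mark_column_carried_through(self, small_molecules):
        sp = mark_atom(small_molecules[0], 1)
        m = merge_colors(sp.F_marked)
        assert m.shape[1] == 17
        assert np.array_equal(m[:, -1], sp.F_marked[:, -1])

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            merge_colors(np.zeros((2, 20)))
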