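"""Chromosome expression, deterministic assembly, and H2 activation."""

import itertools

import pytest
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from flpga import AssemblyError, LibraryError, assemble, express, to_int2
from flpga.fragment_library import _load_lines

FULL = ("a_mes", "a_c6f5", "b_me", "b_et", "k_ophen", "s_me", "s_f", "s_me")


class TestExpress:
    def test_endocyclic_nitrogen_silences_second_base_slot(self, minilib):
        ch = express(FULL[:4] + ("k_pyrrole",) + FULL[5:], minilib)
        assert ch.expression_mask[3] is False     # base_sub_2 silenced
        assert ch.expression_mask[2] is True
        assert ch.expression_mask[4] is True      # backbone always expressed

    def test_no_decoration_slots_silences_decorations_only(self, minilib):
        ch = express(FULL[:4] + ("k_gem",) + FULL[5:], minilib)
        assert ch.expression_mask == (True,) * 5 + (False,) * 3

    def test_unknown_fragment_fatal(self, minilib):
        with pytest.raises(LibraryError, match="unknown fragment"):
            express(("nope",) + FULL[1:], minilib)

    def test_role_mismatch_fatal(self, minilib):
        genes = ("k_gem",) + FULL[1:]  # a backbone id in an acid slot
        with pytest.raises(LibraryError, match="role"):
            express(genes, minilib)


class TestAssemble:
    def test_two_weld_case_has_adjacent_b_and_n_and_no_dummies(self, minilib):
        cand = assemble(express(FULL[:4] + ("k_gem",) + FULL[5:], minilib), minilib)
        mol = Chem.MolFromSmiles(cand.smiles_int1)
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("[B]C[N]"))
        assert "*" not in cand.smiles_int1 and "*" not in cand.smiles_int2

    def test_assembly_is_deterministic(self, minilib):
        a = assemble(express(FULL, minilib), minilib)
        b = assemble(express(FULL, minilib), minilib)
        assert a.smiles_int1 == b.smiles_int1
        assert a.smiles_int2 == b.smiles_int2

    def test_silenced_gene_never_changes_the_molecule(self, minilib):
        g1 = FULL[:4] + ("k_pyrrole",) + FULL[5:]
        g2 = ("a_mes", "a_c6f5", "b_me", "b_ipr", "k_pyrrole") + FULL[5:]
        # base_sub_2 differs but is silenced on this backbone
        assert assemble(express(g1, minilib), minilib).smiles_int1 == \
            assemble(express(g2, minilib), minilib).smiles_int1

    def test_exhaustive_2x2_space_yields_16_distinct_molecules(self):
        lib = _load_lines([
            "acid_substituent\ta1\tC[*:1]",
            "acid_substituent\ta2\t[*:1]c1ccccc1",
            "base_substituent\tb1\tCC[*:1]",
            "base_substituent\tb2\tCC(C)[*:1]",
            "backbone\tk\t[*:1]B([*:2])c1ccccc1N([*:3])[*:4]",
            "backbone_substituent\ts\tC[*:1]",
        ])
        smiles = set()
        combos = itertools.product(["a1", "a2"], ["a1", "a2"],
                                   ["b1", "b2"], ["b1", "b2"])
        for a1, a2, b1, b2 in combos:
            cand = assemble(express((a1, a2, b1, b2, "k", "s", "s", "s"), lib), lib)
            smiles.add(cand.smiles_int1)
        # ordered slots over-count: (a1,a2) and (a2,a1) weld to the same
        # molecule, so 16 assignments collapse to 3*3 distinct structures
        assert len(smiles) == 9

    def test_expressed_heavy_atoms_are_all_accounted_for(self, minilib):
        ch = express(FULL, minilib)
        cand = assemble(ch, minilib)
        mol = Chem.MolFromSmiles(cand.smiles_int1)
        expected = 0
        for slot, gid in cand.provenance.items():
            frag = Chem.MolFromSmiles(minilib.get(gid).smiles)
            expected += sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)
        assert mol.GetNumHeavyAtoms() == expected

    def test_provenance_lists_exactly_the_expressed_genes(self, minilib):
        ch = express(FULL[:4] + ("k_azabor",) + FULL[5:], minilib)
        cand = assemble(ch, minilib)
        assert set(cand.provenance) == {"backbone", "acid_sub_1", "base_sub_1"}


class TestInt2:
    def test_int2_adds_hydride_and_proton_with_charges(self, minilib):
        cand = assemble(express(FULL, minilib), minilib)
        mol = Chem.MolFromSmiles(cand.smiles_int2)
        charges = sorted(a.GetFormalCharge() for a in mol.GetAtoms()
                         if a.GetFormalCharge() != 0)
        assert charges == [-1, 1]
        assert Chem.GetFormalCharge(mol) == 0

    def test_toy_borane_amine_pair(self):
        out = to_int2("CB(C)CN(C)C")
        mol = Chem.MolFromSmiles(out)
        b = next(a for a in mol.GetAtoms() if a.GetAtomicNum() == 5)
        n = next(a for a in mol.GetAtoms() if a.GetAtomicNum() == 7)
        assert (b.GetFormalCharge(), b.GetTotalNumHs()) == (-1, 1)
        assert (n.GetFormalCharge(), n.GetTotalNumHs()) == (1, 1)

    def test_heavy_atom_composition_preserved(self, minilib):
        cand = assemble(express(FULL, minilib), minilib)
        f1 = rdMolDescriptors.CalcMolFormula(Chem.MolFromSmiles(cand.smiles_int1))
        f2 = rdMolDescriptors.CalcMolFormula(Chem.MolFromSmiles(cand.smiles_int2))

        def heavies(formula):
            import re
            counts = {}
            for el, k in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
                if el and el != "H":
                    counts[el] = counts.get(el, 0) + int(k or 1)
            return counts

        assert heavies(f1) == heavies(f2)

    def test_no_trivalent_boron_is_an_error(self):
        with pytest.raises(AssemblyError, match="boron"):
            to_int2("CN(C)C")  # amine without any boron
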