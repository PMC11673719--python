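"""Name -> structure parser: worked examples, ring lexicon fidelity and
failure categories."""

import pytest
from rdkit import Chem

from chemnmt.corpus import canonicalize_smiles
from chemnmt.nomen import (DisconnectedNameError, KekulizationError,
                           LocantError, NameParseError, StereoError,
                           UnsupportedNameError, name_to_structure,
                           parse_name)


def canon(smiles: str) -> str:
    return canonicalize_smiles(smiles)


class TestAcyclicNames:
    @pytest.mark.parametrize("name,smiles", [
        ("methane", "C"),
        ("ethane", "CC"),
        ("2-methylpropane", "CC(C)C"),
        ("2,2-dimethylpropane", "CC(C)(C)C"),
        ("ethanol", "CCO"),
        ("propan-2-ol", "CC(O)C"),
        ("hexan-2-one", "CCCCC(C)=O"),
        ("butan-1-amine", "NCCCC"),
        ("2-methylbutanoic acid", "CCC(C)C(O)=O"),
        ("N-methylbutanamide", "CCCC(=O)NC"),
        ("butanenitrile", "CCCC#N"),
        ("but-2-ene", "CC=CC"),
        ("pent-1-yne", "C#CCCC"),
        ("hexa-1,3-diene", "C=CC=CCC"),
        ("1-chloro-3-fluoro-2-methylpropane", "ClCC(C)CF"),
        ("propanal", "CCC=O"),
    ])
    def test_known_structures(self, name, smiles):
        assert name_to_structure(name) == canon(smiles)


class TestRingNames:
    @pytest.mark.parametrize("name,smiles", [
        ("cyclohexane", "C1CCCCC1"),
        ("cyclohexan-1-ol", "OC1CCCCC1"),
        ("benzene", "c1ccccc1"),
        ("pyridine", "c1ccncc1"),
        ("pyridine-2-carboxylic acid", "OC(=O)c1ccccn1"),
        ("naphthalene", "c1ccc2ccccc2c1"),
        ("quinoline", "c1ccc2ncccc2c1"),
        ("aniline", "Nc1ccccc1"),
        ("pyrrolidine", "C1CCNC1"),
        ("morpholine", "C1COCCN1"),
        ("1,3-benzothiazole", "c1ccc2sc[nH0]c2c1"),
        ("purine", "c1ncc2[nH]cnc2n1"),
        ("bicyclo[2.2.1]heptane", "C1CC2CCC1C2"),
        ("bicyclo[2.2.2]octane", "C1CC2CCC1CC2"),
        ("tert-butyl cyclohexane-1-carboxylate", "CC(C)(C)OC(=O)C1CCCCC1"),
    ])
    def test_known_structures(self, name, smiles):
        assert name_to_structure(name) == canon(smiles)

    def test_caffeine_from_systematic_name(self):
        got = name_to_structure("1,3,7-trimethylpurine-2,6-dione")
        assert got == canon("Cn1cnc2c1c(=O)n(C)c(=O)n2C")

    def test_tautomer_shift_on_substituted_nitrogen(self):
        got = name_to_structure("9-methylpurine")
        assert got == canon("Cn1cnc2cncnc21")

    def test_indicated_hydrogen_with_ketone(self):
        got = name_to_structure("6H-imidazo[4,5-b]pyridin-7-one")
        mol = Chem.MolFromSmiles(got)
        assert mol is not None and mol.GetNumAtoms() == 10


class TestStereoHandling:
    def test_descriptors_parsed_and_ignored(self):
        with_stereo = name_to_structure("(2R)-butan-2-ol")
        without = name_to_structure("butan-2-ol")
        assert with_stereo == without

    def test_enantiomeric_names_give_identical_structure(self):
        a = name_to_structure(
            "[(1R,5S)-3-pentadecan-8-yl-3-azabicyclo[3.2.1]octan-8-yl]cyanamide")
        b = name_to_structure(
            "[(1S,5R)-3-pentadecan-8-yl-3-azabicyclo[3.2.1]octan-8-yl]cyanamide")
        assert a == b

    def test_missing_stereo_locant_rejected(self):
        with pytest.raises(StereoError):
            name_to_structure("(7R)-butan-2-ol")

    def test_pseudoasymmetric_descriptors_rejected(self):
        with pytest.raises(StereoError, match="pseudo-asymmetric"):
            name_to_structure("(1 s,4 s)-4-(chlorooxy)cyclohexyl hypofluorite")


class TestFailureCategories:
    def test_unfindable_replacement_locant(self):
        # aza position 18 does not exist in a 17-atom ring system
        name = ("tert-butyl 15-(2-aminoquinolin-8-yl)-14-fluoro-17-methoxy-"
                "11-methyl-10-oxa-2,5,8,16,18-pentazatricyclo[7.7.1.013,17]"
                "heptadeca-1(16),9(17),13(17),14-tetraene-5-carboxylate")
        with pytest.raises(LocantError, match="18"):
            parse_name(name)

    def test_unfindable_substituent_locant(self):
        name = ("(8S)-8-(ethoxymethyl)-3-[[5-(trifluoromethyl)pyridazin-3-yl]"
                "oxymethyl]-1,2,3,5,6,7-hexahydropyrrolizine")
        with pytest.raises(LocantError, match="8"):
            parse_name(name)

    def test_disconnected_names_rejected(self):
        with pytest.raises(DisconnectedNameError):
            parse_name("sodium;acetate")

    def test_stereocentre_on_ch2_rejected(self):
        name = ("(7S,10S,13S)-N-[(1S)-1-cyclopropylethyl]-13-(2-morpholin-4-"
                "ylethyl)-9,12-dioxo-16-(2-oxopyrrolidin-1-yl)-2-oxa-8,11-"
                "diazabicyclo[16.3.1]docosa-1(21),18(22),19-triene-7-"
                "carboxamide")
        with pytest.raises(StereoError, match="10"):
            parse_name(name)

    def test_spiro_unsupported(self):
        with pytest.raises(UnsupportedNameError, match="spiro"):
            parse_name("spiro[4.5]decane")

    def test_gibberish_rejected(self):
        with pytest.raises(NameParseError):
            parse_name("florblegarble")


class TestVonBaeyer:
    def test_bridge_sizes_must_sum(self):
        with pytest.raises(NameParseError):
            parse_name("bicyclo[9.9.9]heptane")

    def test_secondary_bridge_resolution(self):
        # tetracyclo with two zero bridges: all 11 carbons, 4 rings
        got = name_to_structure("tetracyclo[5.3.1.03,9.05,9]undecane")
        mol = Chem.MolFromSmiles(got)
        assert mol.GetNumAtoms() == 11
        # 11 atoms, 14 bonds -> 4 independent rings
        assert mol.GetNumBonds() - mol.GetNumAtoms() + 1 == 4

    def test_replacement_in_bridge(self):
        got = name_to_structure("2-oxabicyclo[2.2.1]heptane")
        mol = Chem.MolFromSmiles(got)
        assert mol.GetNumAtoms() == 7
        oxygens = [a for a in mol.GetAtoms() if a.GetSymbol() == "O"]
        assert len(oxygens) == 1
        # the oxygen sits between a bridgehead (degree 3) and a CH2
        degs = sorted(nb.GetDegree() for nb in oxygens[0].GetNeighbors())
        assert degs == [2, 3]
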