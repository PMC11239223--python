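"""Phosphosite key construction (five scenarios) and peptide keys."""

import pytest

from phosreport.keys import SiteKey, build_peptide_key, build_site_keys, multiplicity
from phosreport.modseq import (
    ACETYL_NTERM,
    OXIDATION,
    PHOSPHO,
    ModifiedPeptide,
    parse_modified_sequence,
)


@pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 3), (5, 3), (17, 3)])
def test_multiplicity_classes(n, expected):
    assert multiplicity(n) == expected


def test_multiplicity_rejects_unphosphorylated():
    with pytest.raises(ValueError):
        multiplicity(0)


def _phospho_pep(stripped, positions):
    return ModifiedPeptide(stripped, tuple((p, PHOSPHO) for p in positions))


def _rendered(keys):
    return sorted(str(k) for k in keys)


class TestFiveScenarios:
    """Golden enumeration on the toy proteome (see conftest)."""

    def test_i_single_phospho_single_protein(self, toy_proteome):
        # "AASK" at P1 start 3, phospho at peptide position 3 -> S5
        keys = build_site_keys(_phospho_pep("AASK", [3]), ("P1",), toy_proteome)
        assert _rendered(keys) == ["P1_S5_M1"]
        assert not keys[0].ambiguous

    def test_ii_repeated_peptide_single_protein(self, toy_proteome):
        # "ASSK" occurs in P2 at starts 2 and 8: one ambiguous key listing
        # both alternative positions, not two keys
        keys = build_site_keys(_phospho_pep("ASSK", [3]), ("P2",), toy_proteome)
        assert _rendered(keys) == ["P2_S4,S10_M1"]
        assert keys[0].ambiguous

    def test_iii_doubly_phosphorylated(self, toy_proteome):
        # "TTYSAK" at P1 start 8, phospho at 1 and 3 -> T8 and Y10, both M2
        keys = build_site_keys(_phospho_pep("TTYSAK", [1, 3]), ("P1",), toy_proteome)
        assert _rendered(keys) == ["P1_T8_M2", "P1_Y10_M2"]

    def test_iv_three_or_more_phospho(self, toy_proteome):
        # "SSTSYR" at P5 start 3 with 4 phospho groups -> one key per site, M3
        keys = build_site_keys(
            _phospho_pep("SSTSYR", [1, 2, 3, 5]), ("P5",), toy_proteome
        )
        assert _rendered(keys) == ["P5_S3_M3", "P5_S4_M3", "P5_T5_M3", "P5_Y7_M3"]

    def test_v_multiple_isoforms(self, toy_proteome):
        # "LSDEK" in P3 (start 2) and P4 (start 4): one key listing both
        keys = build_site_keys(_phospho_pep("LSDEK", [2]), ("P3", "P4"), toy_proteome)
        assert _rendered(keys) == ["P3;P4_S3;S5_M1"]

    def test_scenarios_compose(self, toy_proteome):
        # doubly phosphorylated repeated peptide: two ambiguous M2 keys,
        # each enumerating its alternative positions
        keys = build_site_keys(_phospho_pep("ASSK", [2, 3]), ("P2",), toy_proteome)
        assert _rendered(keys) == ["P2_S3,S9_M2", "P2_S4,S10_M2"]
        assert all(k.ambiguous for k in keys)

    def test_full_golden_enumeration(self, toy_proteome):
        """All five scenarios at once equal the hand enumeration."""
        cases = [
            (_phospho_pep("AASK", [3]), ("P1",)),
            (_phospho_pep("ASSK", [3]), ("P2",)),
            (_phospho_pep("TTYSAK", [1, 3]), ("P1",)),
            (_phospho_pep("SSTSYR", [1, 2, 3, 5]), ("P5",)),
            (_phospho_pep("LSDEK", [2]), ("P3", "P4")),
        ]
        produced = sorted(
            str(k) for pep, group in cases for k in build_site_keys(pep, group, toy_proteome)
        )
        assert produced == [
            "P1_S5_M1",
            "P1_T8_M2",
            "P1_Y10_M2",
            "P2_S4,S10_M1",
            "P3;P4_S3;S5_M1",
            "P5_S3_M3",
            "P5_S4_M3",
            "P5_T5_M3",
            "P5_Y7_M3",
        ]


def test_sites_match_proteome_residues(toy_proteome):
    """Every generated key points at an S/T/Y with the stated letter."""
    cases = [
        (_phospho_pep("AASK", [3]), ("P1",)),
        (_phospho_pep("ASSK", [3]), ("P2",)),
        (_phospho_pep("SSTSYR", [1, 2, 3, 5]), ("P5",)),
        (_phospho_pep("LSDEK", [2]), ("P3", "P4")),
    ]
    for pep, group in cases:
        for key in build_site_keys(pep, group, toy_proteome):
            for accession, sites in zip(key.accessions, key.sites):
                for residue, pos in sites:
                    assert residue in "STY"
                    assert toy_proteome[accession][pos - 1] == residue


def test_unknown_accession_skipped_absent_peptide_empty(toy_proteome):
    keys = build_site_keys(_phospho_pep("AASK", [3]), ("P1", "NOPE"), toy_proteome)
    assert _rendered(keys) == ["P1_S5_M1"]
    assert build_site_keys(_phospho_pep("WWWSK", [4]), ("P1",), toy_proteome) == []


def test_multiplicity_distinguishes_keys(toy_proteome):
    m1 = build_site_keys(_phospho_pep("AASK", [3]), ("P1",), toy_proteome)[0]
    m2 = SiteKey(m1.accessions, m1.sites, 2, m1.ambiguous)
    assert str(m1) != str(m2) and m1 != m2


def test_same_count_different_position_same_peptide_key(toy_proteome):
    """Positional isomers share a PeptideKey but not SiteKeys."""
    a = _phospho_pep("SSTSYR", [1])
    b = _phospho_pep("SSTSYR", [2])
    assert build_peptide_key(a) == build_peptide_key(b)
    ka = _rendered(build_site_keys(a, ("P5",), toy_proteome))
    kb = _rendered(build_site_keys(b, ("P5",), toy_proteome))
    assert ka != kb


@pytest.mark.parametrize(
    "modseq,expected",
    [
        ("_AAS[Phospho (STY)]K_", "AASK_Phospho (STY)x1"),
        ("_M[Oxidation (M)]AAS[Phospho (STY)]K_",
         "MAASK_Phospho (STY)x1_Oxidation (M)x1"),
        ("AASK", "AASK"),
        ("_[Acetyl (Protein N-term)]MS[Phospho (STY)]S[Phospho (STY)]K_",
         "MSSK_Phospho (STY)x2_Acetyl (Protein N-term)x1"),
    ],
)
def test_peptide_key_rendering(modseq, expected):
    pep = parse_modified_sequence(modseq, "bracket")
    assert str(build_peptide_key(pep)) == expected


def test_peptide_key_counts():
    pep = parse_modified_sequence(
        "_M[Oxidation (M)]AAS[Phospho (STY)]K_", "bracket"
    )
    key = build_peptide_key(pep)
    assert dict(key.mod_counts) == {OXIDATION: 1, PHOSPHO: 1}


def test_peptide_key_tracked_subset():
    pep = ModifiedPeptide("MSK", ((0, ACETYL_NTERM), (2, PHOSPHO)))
    key = build_peptide_key(pep, tracked=(PHOSPHO,))
    assert str(key) == "MSK_Phospho (STY)x1"
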