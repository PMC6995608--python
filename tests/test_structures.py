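import pytest

from flavoglyc.chem import ELECTRON_MASS, MONOISOTOPIC_MASS
from flavoglyc.structures import (
    AGLYCONES,
    SUGARS,
    GlycosideStructure,
    Linkage,
    ModelError,
    compose_formula,
    enumerate_candidates,
    enumerate_structures,
)


def _mono(aglycone, sugar, **kw):
    return GlycosideStructure(AGLYCONES[aglycone], (SUGARS[sugar],), **kw)


def test_compose_formula_kaempferol_hexoside():
    s = _mono("kaempferol", "hexose")
    assert compose_formula(s).hill() == "C21H19O11"
    assert s.anion_mz == pytest.approx(447.09329, abs=1e-5)


def test_compose_formula_malonyl_hexoside():
    s = _mono("kaempferol", "hexose", malonyl_on_6pp=True)
    assert compose_formula(s).hill() == "C24H21O14"
    assert s.anion_mz == pytest.approx(533.09368, abs=1e-5)


def test_bare_aglycone_mass_by_independent_summation():
    # oracle: explicit sum over atomic masses of C15H9O7 plus one electron
    expected = 15 * 12.0 + 9 * MONOISOTOPIC_MASS["H"] + 7 * MONOISOTOPIC_MASS["O"] + ELECTRON_MASS
    bare = GlycosideStructure(AGLYCONES["quercetin"])
    assert bare.anion_mz == pytest.approx(round(expected, 5), abs=1e-5)
    assert bare.nominal_mz == 301
    assert bare.anion_mz == pytest.approx(301.03538, abs=1e-5)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(position3=(SUGARS["hexose"], SUGARS["hexose"])),  # chain without linkage
        dict(position3=(), malonyl_on_6pp=True),  # malonyl needs position 3
        dict(position3=(SUGARS["deoxyhexose"],), malonyl_on_6pp=True),  # no 6''-OH
        dict(position3=(SUGARS["hexose"],), linkage=Linkage("1->2")),  # linkage w/o chain
    ],
)
def test_invalid_structures_rejected(kwargs):
    with pytest.raises(ModelError):
        GlycosideStructure(AGLYCONES["quercetin"], **kwargs)


def test_linkage_type_validated():
    with pytest.raises(ValueError):
        Linkage("1->4")


@pytest.mark.parametrize("aglycone", list(AGLYCONES))
@pytest.mark.parametrize("sugar", list(SUGARS))
def test_adding_7_O_hexose_adds_residue_mass(aglycone, sugar):
    base = _mono(aglycone, sugar)
    extended = GlycosideStructure(
        AGLYCONES[aglycone], (SUGARS[sugar],), position7=SUGARS["hexose"]
    )
    assert extended.anion_mz - base.anion_mz == pytest.approx(162.05282, abs=2e-5)


def test_residue_masses():
    assert SUGARS["hexose"].residue_mass == pytest.approx(162.05282, abs=1e-5)
    assert SUGARS["deoxyhexose"].residue_mass == pytest.approx(146.05791, abs=1e-5)
    assert SUGARS["pentose"].residue_mass == pytest.approx(132.04226, abs=1e-5)


def test_enumerate_candidates_at_609(space):
    codes = {s.code for s in enumerate_candidates(609.14679, 5, space)}
    assert {
        "Q-3[RHA(1->2)HEX]",
        "Q-3[RHA(1->6)HEX]",
        "K-3[HEX(1->2)HEX]",
        "K-3[HEX]-7[HEX]",
        "I-3[PEN(1->2)HEX]",
        "I-3[PEN(1->6)HEX]",
    } <= codes


def test_enumerate_candidates_below_any_structure(space):
    assert enumerate_candidates(100.0, 5, space) == []


def test_enumerate_candidates_matches_brute_force_at_771(space):
    """Oracle: direct ppm filter over every composed structure mass."""
    target = 771.20038
    oracle = {
        s.code for s in space if abs((target - s.anion_mz) / s.anion_mz * 1e6) <= 5
    }
    got = {s.code for s in enumerate_candidates(target, 5, space)}
    assert got == oracle
    assert "Q-3[RHA(1->6)HEX]-7[HEX]" in got


def test_every_reference_precursor_has_its_identification(reference_table, space):
    for _, row in reference_table.iterrows():
        codes = {s.code for s in enumerate_candidates(row.exact_mz, 5, space)}
        assert row.code in codes, row.code


def test_compose_formula_reproduces_all_reference_formulas(reference_table, space):
    by_code = {s.code: s for s in space}
    for _, row in reference_table.iterrows():
        assert by_code[row.code].anion_formula.hill() == row.formula


def test_names():
    assert (
        GlycosideStructure(
            AGLYCONES["quercetin"],
            (SUGARS["hexose"], SUGARS["deoxyhexose"]),
            Linkage("1->6"),
        ).name()
        == "Quercetin 3-O-(6''-O-rhamnosyl)hexoside (Rutin)"
    )
    assert (
        _mono("kaempferol", "hexose", malonyl_on_6pp=True).name()
        == "Kaempferol 3-O-(6''-O-malonyl)hexoside"
    )
    assert (
        GlycosideStructure(
            AGLYCONES["isorhamnetin"], (SUGARS["hexose"],), position7=SUGARS["hexose"]
        ).name()
        == "Isorhamnetin 3,7-di-O-hexoside"
    )


def test_space_is_deterministically_ordered():
    a = [s.code for s in enumerate_structures()]
    b = [s.code for s in enumerate_structures()]
    assert a == b
    assert all(s.sugar_count <= 3 for s in enumerate_structures())
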