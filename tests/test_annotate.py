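import pytest

from flavoglyc.annotate import (
    annotate,
    annotate_table,
    assign_linkage,
    build_presence_matrix,
    call_aglycone,
)
from flavoglyc.spectrum import Spectrum


def _sp(precursor, peaks, ident="t"):
    return Spectrum(ident, precursor, tuple(peaks))


def test_call_aglycone_kaempferol_with_radical():
    sp = _sp(447.09424, [(327, 20), (285, 80), (284, 100), (255, 10)])
    call = call_aglycone(sp)
    assert call.aglycone.name == "kaempferol"
    assert call.radical_present


def test_call_aglycone_minimal_quercetin():
    call = call_aglycone(_sp(463.09, [(301, 100)]))
    assert call.aglycone.name == "quercetin"
    assert not call.radical_present


def test_call_aglycone_isorhamnetin_radical_dominant():
    sp = _sp(623.16211, [(608, 10), (477, 10), (459, 30), (315, 15), (314, 100), (299, 65)])
    call = call_aglycone(sp)
    assert call.aglycone.name == "isorhamnetin"
    assert call.radical_present


def test_call_aglycone_unassigned_without_aglycone_ions():
    assert not call_aglycone(_sp(609.0, [(489.0, 100.0)])).assigned


def test_assign_linkage(reference, space, rutin, q_2pp_rutinoside):
    assert assign_linkage(reference["11"], q_2pp_rutinoside).type == "1->2"
    assert assign_linkage(reference["15"], rutin).type == "1->6"
    empty = Spectrum("e", 609.14679, ())
    assert assign_linkage(empty, rutin).type == "unknown"


def test_assign_linkage_requires_disaccharide(reference, space):
    mono = next(s for s in space if s.code == "Q-3[HEX]")
    with pytest.raises(ValueError):
        assign_linkage(reference["20"], mono)


def test_annotate_rutin_pattern(space):
    sp = _sp(609.14679, [(343, 5), (301, 100), (300, 20), (271, 10), (255, 5)])
    res = annotate(sp, 5.0, space=space)
    assert res.top.code == "Q-3[RHA(1->6)HEX]"
    assert "Rutin" in res.name
    assert res.linkage_call.type == "1->6"


def test_annotate_malonyl_pattern(space):
    sp = _sp(533.09454, [(489, 100), (285, 5)])
    res = annotate(sp, 5.0, space=space)
    assert res.top.code == "K-3[HEX+MAL]"
    assert res.top.malonyl_on_6pp


def test_annotate_no_candidate_within_tolerance(space):
    res = annotate(_sp(150.0, [(120, 100)]), 5.0, space=space)
    assert not res.assigned
    assert "no structure" in res.diagnostic


def test_annotate_is_deterministic(reference, space):
    sp = reference["11"]
    a = annotate(sp, 5.0, space=space)
    b = annotate(sp, 5.0, space=space)
    assert [(c.code, s) for c, s, _ in a.candidates] == [
        (c.code, s) for c, s, _ in b.candidates
    ]


def test_scores_are_bounded(reference, space):
    for sp in reference:
        for _, score, _ in annotate(sp, 5.0, space=space).candidates:
            assert 0.0 <= score <= 1.0


def test_annotate_table_reproduces_reference(reference, reference_table):
    df = annotate_table(list(reference)).set_index("id")
    assert len(df) == 27
    for rid, row in reference_table.iterrows():
        assert df.loc[rid, "code"] == row.code
    # isomer numbering follows retention time for repeated structures
    assert df.loc["14", "name"].endswith("isomer 1")
    assert df.loc["19", "name"].endswith("isomer 2")
    assert df.loc["24", "name"].endswith("isomer 1")
    assert df.loc["26", "name"].endswith("isomer 2")


def test_annotate_table_input_validation(reference):
    with pytest.raises(ValueError):
        annotate_table([])
    sp = reference["15"]
    with pytest.raises(ValueError, match="duplicate"):
        annotate_table([sp, sp])


def test_build_presence_matrix(space):
    rutin_sp = _sp(609.14679, [(301, 100), (300, 20)], "a")
    mal_sp = _sp(533.09454, [(489, 100), (285, 5)], "b")
    res_a = annotate(rutin_sp, 5.0, space=space)
    res_b = annotate(mal_sp, 5.0, space=space)
    pm = build_presence_matrix({"P1": [res_a, res_b], "P2": [res_b], "P3": []})
    assert pm.shape == (3, 2)
    assert pm.loc["P1"].all()
    assert pm.loc["P2", "K-3[HEX+MAL]"] and not pm.loc["P2", res_a.top.code]
    assert not pm.loc["P3"].any()
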