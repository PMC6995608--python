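"""Negative-mode fragmentation grammar for flavonol glycosides.

The grammar encodes the neutral-loss behaviour of [M−H]⁻ flavonol
glycosides under CID:

* Y-series ions from sequential glycosidic cleavages down to the aglycone
  Y0⁻; homolytic cleavage of the 3-O bond additionally yields radical
  [Y−H]⁻• partners one Da below the even-electron ion, diagnostic of
  3-O-glycosylation.
* For 1→2-linked disaccharide chains, cross-ring (0,2)X scission of the
  terminal sugar (−120 Da) and loss of the intact terminal sugar molecule
  (residue + H2O: −180/−164/−150) — the diagnostic pair that separates
  sophorose-type from rutinose-type linkages, where neither ion appears.
* Cross-ring −120 from any state in which a single sugar sits directly on
  the 3-OH (this also explains ions such as m/z 327 from kaempferol
  monohexosides).
* −44 (CO2) when a malonyl group is present; −18/−28 small-molecule losses;
  −15 methyl-radical losses for methoxylated aglycones (isorhamnetin).

All fragment m/z values are nominal integers, matched with a ±0.5 Da
window; precursor matching elsewhere is ppm-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .structures import AGLYCONES, GlycosideStructure, SugarUnit

__all__ = ["FragmentIon", "predict_fragments", "classify_loss", "LOSS_VOCABULARY"]

#: nominal neutral-loss vocabulary: label → mass (Da, nominal)
LOSS_VOCABULARY: dict[str, int] = {
    "-162 (hexosyl)": 162,
    "-146 (rhamnosyl)": 146,
    "-132 (pentosyl)": 132,
    "-180 (hexose molecule)": 180,
    "-164 (rhamnose molecule)": 164,
    "-150 (pentose molecule)": 150,
    "-120 (0,2X cross-ring)": 120,
    "-86 (malonyl)": 86,
    "-44 (malonyl CO2)": 44,
    "-28 (CO)": 28,
    "-18 (H2O)": 18,
    "-15 (CH3 radical)": 15,
}

#: common secondary fragments of the deprotonated aglycones (ring
#: contractions, CO/CO2/CH3 losses), by aglycone name
AGLYCONE_SATELLITES: dict[str, tuple[int, ...]] = {
    "quercetin": (271, 255, 179, 151),
    "kaempferol": (255, 227),
    "isorhamnetin": (300, 299, 271, 255),
}

_SUGAR_MOLECULE_LOSS = {"hexose": 180, "deoxyhexose": 164, "pentose": 150}


@dataclass(frozen=True)
class FragmentIon:
    """A predicted product ion at nominal (integer) m/z."""

    nominal_mz: int
    loss_label: str
    radical: bool = False
    intensity_class: str = "weak"  # base | strong | weak

    def __post_init__(self):
        if self.nominal_mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.intensity_class not in ("base", "strong", "weak"):
            raise ValueError(f"unknown intensity class {self.intensity_class!r}")


def _add(ions: dict[tuple[int, bool], FragmentIon], ion: FragmentIon) -> None:
    """Keep the highest-priority class when the same ion arises twice."""
    rank = {"base": 2, "strong": 1, "weak": 0}
    key = (ion.nominal_mz, ion.radical)
    old = ions.get(key)
    if old is None or rank[ion.intensity_class] > rank[old.intensity_class]:
        ions[key] = ion


def predict_fragments(s: GlycosideStructure) -> list[FragmentIon]:
    """Predicted product ions of [M−H]⁻ for structure ``s``.

    Returns ions sorted by descending m/z. The intensity class is a prior
    read off typical evidence patterns (used for ranking and simulation,
    never as a hard filter).
    """
    M = s.nominal_mz
    agl = s.aglycone
    y0 = agl.y0_nominal
    ions: dict[tuple[int, bool], FragmentIon] = {}

    chain = s.position3
    is_chain = len(chain) == 2
    is_mono3 = len(chain) == 1
    link = s.linkage.type if s.linkage else None
    res7 = s.position7.nominal_mass if s.position7 else 0
    term = chain[1] if is_chain else None
    inner = chain[0] if chain else None
    # the inner position-3 unit leaves together with its malonyl decoration
    inner_loss = inner.nominal_mass + (86 if s.malonyl_on_6pp else 0) if inner else 0

    if s.is_bare_aglycone:
        for sat in AGLYCONE_SATELLITES[agl.name]:
            if sat < y0:
                _add(ions, FragmentIon(sat, "aglycone fragment"))
        if agl.has_methoxy:
            _add(ions, FragmentIon(y0 - 15, "-15 (CH3 radical)", radical=True))
        return sorted(ions.values(), key=lambda i: -i.nominal_mz)

    # ------------------------------------------------------------------ Y ions
    # glycan states: which of (terminal, inner(+mal), 7-sugar) have been lost
    removable: list[tuple[str, int]] = []
    if term:
        removable.append(("term", term.nominal_mass))
    if inner:
        removable.append(("inner", inner_loss))
    if s.position7:
        removable.append(("p7", res7))

    radical_cls = "weak"
    if is_chain:
        radical_cls = "base" if link == "1->2" else "weak"
        if s.position7:
            radical_cls = "strong" if link == "1->2" else "weak"
    elif is_mono3 and not s.position7 and not s.malonyl_on_6pp:
        radical_cls = "strong"

    y0_cls = "strong"
    if not chain and s.position7:
        y0_cls = "base"  # 7-O-only glycosides: Y0 dominates, no radical
    elif is_chain and link == "1->6" and not s.position7:
        y0_cls = "base"
    elif is_mono3 and not s.malonyl_on_6pp:
        y0_cls = "base"  # with or without a 7-O sugar, Y0 often dominates
    elif s.malonyl_on_6pp:
        y0_cls = "weak"

    names = [r[0] for r in removable]
    for k in range(1, len(removable) + 1):
        for combo in itertools.combinations(range(len(removable)), k):
            picked = [names[i] for i in combo]
            if "inner" in picked and "term" in names and "term" not in picked:
                continue  # inner sugar cannot leave before the terminal one
            mz = M - sum(removable[i][1] for i in combo)
            lost3 = "inner" in picked or (is_mono3 and "inner" in picked)
            at_aglycone = ("inner" not in names) or "inner" in picked
            label = "Y (-" + ",".join(str(removable[i][1]) for i in combo) + ")"
            if at_aglycone and mz == y0:
                cls = y0_cls
                label = "Y0"
            elif picked == ["p7"] and s.position7:
                # loss of the 7-O sugar: base peak for triglycosides
                cls = "base" if is_chain else "strong"
            elif picked == ["term"]:
                cls = "weak"
            elif is_mono3 and picked == ["inner"] and s.position7:
                cls = "strong"  # di-mono intermediate, e.g. m/z 463 from 625
            else:
                cls = "weak"
            _add(ions, FragmentIon(mz, label, intensity_class=cls))
            # homolytic 3-O cleavage radical partner
            if lost3:
                rcls = radical_cls if mz == y0 else ("strong" if is_mono3 else "weak")
                _add(ions, FragmentIon(mz - 1, label + " -H radical", True, rcls))

    # --------------------------------------------- linkage-diagnostic ions
    if is_chain and link == "1->2":
        diag_cls = "strong"
        _add(ions, FragmentIon(M - 120, "-120 (0,2X cross-ring)", intensity_class=diag_cls))
        _add(
            ions,
            FragmentIon(
                M - _SUGAR_MOLECULE_LOSS[term.kind],
                f"-{_SUGAR_MOLECULE_LOSS[term.kind]} ({term.kind} molecule)",
                intensity_class=diag_cls,
            ),
        )
        if s.position7:  # same pair after the 7-O sugar is gone
            _add(ions, FragmentIon(M - res7 - 120, "-120 after 7-O loss"))
            _add(
                ions,
                FragmentIon(
                    M - res7 - _SUGAR_MOLECULE_LOSS[term.kind],
                    f"-{_SUGAR_MOLECULE_LOSS[term.kind]} after 7-O loss",
                ),
            )
        # water loss from the sugar-molecule diagnostic (e.g. 755→575)
        _add(
            ions,
            FragmentIon(M - _SUGAR_MOLECULE_LOSS[term.kind] - 18, "sugar molecule -H2O"),
        )

    # cross-ring −120 from any state with a single sugar on the 3-OH
    mono_states = []
    if is_mono3 and not s.malonyl_on_6pp:
        mono_states.append(M - res7 if s.position7 else M)
        if s.position7:
            mono_states.append(M)  # precursor itself is a 3-mono state
    if is_chain:  # after the terminal sugar is lost
        base_state = M - term.nominal_mass
        mono_states.append(base_state - res7 if s.position7 else base_state)
    for state in mono_states:
        if state - 120 > y0 - 120:
            _add(ions, FragmentIon(state - 120, "-120 (0,2X cross-ring)"))

    # ------------------------------------------------------- small losses
    if s.malonyl_on_6pp:
        _add(ions, FragmentIon(M - 44, "-44 (malonyl CO2)", intensity_class="base"))
    _add(ions, FragmentIon(M - 18, "-18 (H2O)"))
    _add(ions, FragmentIon(M - 28, "-28 (CO)"))

    if agl.has_methoxy:
        _add(ions, FragmentIon(M - 15, "-15 (CH3 radical)", radical=True))
        # methyl-radical satellites of the aglycone pair and diagnostics
        for (mz, rad), ion in list(ions.items()):
            if mz in (y0, y0 - 1) or "0,2X" in ion.loss_label or "molecule" in ion.loss_label:
                if mz - 15 > 0:
                    _add(ions, FragmentIon(mz - 15, ion.loss_label + " -CH3", True))

    for sat in AGLYCONE_SATELLITES[agl.name]:
        _add(ions, FragmentIon(sat, "aglycone fragment"))

    return sorted(ions.values(), key=lambda i: (-i.nominal_mz, i.radical))


def classify_loss(precursor_mz: float, fragment_mz: float, max_steps: int = 2) -> list[str]:
    """All loss-label combinations whose nominal sum explains the difference.

    Combinations of up to ``max_steps`` losses from the vocabulary are
    considered; the empty list means the loss is unexplained by the grammar.
    """
    if fragment_mz >= precursor_mz:
        raise ValueError("fragment m/z must be below the precursor m/z")
    delta = round(precursor_mz - fragment_mz)
    labels = list(LOSS_VOCABULARY)
    out: list[str] = []
    for k in range(1, max_steps + 1):
        for combo in itertools.combinations_with_replacement(labels, k):
            if sum(LOSS_VOCABULARY[c] for c in combo) == delta:
                out.append(" + ".join(combo))
    return out
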