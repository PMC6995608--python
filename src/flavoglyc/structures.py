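"""Declarative model of the flavonol glycoside hypothesis space.

The space covers 3-O-glycosides of quercetin, kaempferol and isorhamnetin:
a chain of up to two sugars (hexose, deoxyhexose, pentose) on the 3-OH with
a 1→2 or 1→6 interglycosidic linkage, an optional single sugar on the 7-OH,
and an optional malonyl group on the 6″-OH of the position-3 inner sugar.
Malonylation requires a hexose inner sugar: deoxyhexoses and pentoses have
no free 6-OH to acylate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chem import MolecularFormula, anion_mz, parse_formula, within_tolerance

__all__ = [
    "Aglycone",
    "SugarUnit",
    "Linkage",
    "GlycosideStructure",
    "AGLYCONES",
    "SUGARS",
    "MALONYL_RESIDUE",
    "MALONYL_RESIDUE_MASS",
    "compose_formula",
    "enumerate_structures",
    "enumerate_candidates",
    "STANDARD_ALIASES",
]


@dataclass(frozen=True)
class Aglycone:
    """A flavonol core. ``y0_nominal`` is the integer m/z of its [M−H]⁻."""

    name: str
    neutral_formula: MolecularFormula
    y0_nominal: int
    has_methoxy: bool = False

    @property
    def anion_formula(self) -> MolecularFormula:
        f = dict(self.neutral_formula)
        f["H"] -= 1
        return MolecularFormula(f)

    @property
    def anion_mz(self) -> float:
        return anion_mz(self.anion_formula)

    @property
    def code(self) -> str:
        return self.name[0].upper()


@dataclass(frozen=True)
class SugarUnit:
    """A glycosyl residue (dehydrated sugar) as it occurs in a glycoside."""

    kind: str
    residue_formula: MolecularFormula
    code: str

    @property
    def residue_mass(self) -> float:
        from .chem import neutral_mass

        return round(neutral_mass(self.residue_formula), 5)

    @property
    def nominal_mass(self) -> int:
        return round(self.residue_mass)


@dataclass(frozen=True)
class Linkage:
    """Interglycosidic linkage between the two sugars of a 3-O-chain."""

    type: str  # "1->2", "1->6" or "unknown"

    def __post_init__(self):
        if self.type not in ("1->2", "1->6", "unknown"):
            raise ValueError(f"unknown linkage type {self.type!r}")


AGLYCONES: dict[str, Aglycone] = {
    "quercetin": Aglycone("quercetin", parse_formula("C15H10O7"), 301),
    "kaempferol": Aglycone("kaempferol", parse_formula("C15H10O6"), 285),
    "isorhamnetin": Aglycone("isorhamnetin", parse_formula("C16H12O7"), 315, has_methoxy=True),
}

SUGARS: dict[str, SugarUnit] = {
    "hexose": SugarUnit("hexose", parse_formula("C6H10O5"), "HEX"),
    "deoxyhexose": SugarUnit("deoxyhexose", parse_formula("C6H10O4"), "RHA"),
    "pentose": SugarUnit("pentose", parse_formula("C5H8O4"), "PEN"),
}

MALONYL_RESIDUE = parse_formula("C3H2O3")
MALONYL_RESIDUE_MASS = 86.00039

#: structure code → trivial name for standards-confirmed hexose stereochemistry
STANDARD_ALIASES: dict[str, str] = {
    "Q-3[HEX]": "Hyperoside",
    "K-3[HEX]": "Astragalin",
    "Q-3[RHA(1->6)HEX]": "Rutin",
}


class ModelError(ValueError):
    """Raised when a structure violates the hypothesis-space invariants."""


@dataclass(frozen=True)
class GlycosideStructure:
    """One structural hypothesis.

    ``position3`` is an ordered chain read aglycone-outward: element 0 is the
    inner sugar bound to the 3-OH, element 1 (if present) the terminal sugar
    attached to the inner one through ``linkage``.
    """

    aglycone: Aglycone
    position3: tuple[SugarUnit, ...] = ()
    linkage: Linkage | None = None
    position7: SugarUnit | None = None
    malonyl_on_6pp: bool = False

    def __post_init__(self):
        if len(self.position3) > 2:
            raise ModelError("at most two sugars in the position-3 chain")
        if len(self.position3) == 2 and self.linkage is None:
            raise ModelError("two-sugar chain requires a linkage")
        if len(self.position3) < 2 and self.linkage is not None:
            raise ModelError("linkage defined without a disaccharide chain")
        if self.sugar_count > 3:
            raise ModelError("at most three sugars in total")
        if self.malonyl_on_6pp:
            if not self.position3:
                raise ModelError("malonyl requires an occupied position 3")
            if self.position3[0].kind != "hexose":
                raise ModelError("malonyl requires a hexose inner sugar (free 6''-OH)")

    @property
    def sugar_count(self) -> int:
        return len(self.position3) + (1 if self.position7 else 0)

    @property
    def is_bare_aglycone(self) -> bool:
        return self.sugar_count == 0

    @property
    def code(self) -> str:
        """Compact text code, e.g. ``Q-3[RHA(1->2)HEX]-7[HEX]``."""
        parts = [self.aglycone.code]
        if self.position3:
            if len(self.position3) == 2:
                inner, term = self.position3
                chain = f"{term.code}({self.linkage.type}){inner.code}"
            else:
                chain = self.position3[0].code
            if self.malonyl_on_6pp:
                chain += "+MAL"
            parts.append(f"3[{chain}]")
        if self.position7:
            parts.append(f"7[{self.position7.code}]")
        return "-".join(parts)

    @property
    def anion_formula(self) -> MolecularFormula:
        return compose_formula(self)

    @property
    def anion_mz(self) -> float:
        return anion_mz(self.anion_formula)

    @property
    def nominal_mz(self) -> int:
        return round(self.anion_mz)

    def name(self) -> str:
        """Render the conventional name, e.g.
        ``Quercetin 3-O-(2''-O-rhamnosyl)hexoside-7-O-hexoside``."""
        osyl = {"hexose": "hexosyl", "deoxyhexose": "rhamnosyl", "pentose": "pentosyl"}
        oside = {"hexose": "hexoside", "deoxyhexose": "rhamnoside", "pentose": "pentoside"}
        agl = self.aglycone.name.capitalize()
        if self.is_bare_aglycone:
            return agl
        # 3,7-di-O form with the same single sugar at both positions
        if (
            len(self.position3) == 1
            and self.position7
            and self.position3[0].kind == self.position7.kind
            and not self.malonyl_on_6pp
        ):
            return f"{agl} 3,7-di-O-{oside[self.position7.kind]}"
        pieces = []
        if self.position3:
            if len(self.position3) == 2:
                inner, term = self.position3
                pos = {"1->2": "2''", "1->6": "6''"}.get(self.linkage.type, "x''")
                core = f"3-O-({pos}-O-{osyl[term.kind]}){oside[inner.kind]}"
            elif self.malonyl_on_6pp:
                core = f"3-O-(6''-O-malonyl){oside[self.position3[0].kind]}"
            else:
                core = f"3-O-{oside[self.position3[0].kind]}"
            if self.malonyl_on_6pp and len(self.position3) == 2:
                core += " (6''-O-malonyl)"
            pieces.append(core)
        if self.position7:
            pieces.append(f"7-O-{oside[self.position7.kind]}")
        alias = STANDARD_ALIASES.get(self.code)
        name = f"{agl} {'-'.join(pieces)}"
        return f"{name} ({alias})" if alias else name


def compose_formula(s: GlycosideStructure) -> MolecularFormula:
    """Anion atom composition: deprotonated aglycone plus all residues."""
    f = s.aglycone.anion_formula
    for sugar in s.position3:
        f = f + sugar.residue_formula
    if s.position7:
        f = f + s.position7.residue_formula
    if s.malonyl_on_6pp:
        f = f + MALONYL_RESIDUE
    return f


def enumerate_structures(
    max_chain: int = 2,
    include_bare: bool = True,
    chain_inner_kinds: tuple[str, ...] = ("hexose",),
) -> list[GlycosideStructure]:
    """Full hypothesis space, deterministically ordered (aglycone, then code).

    By default the inner sugar of a disaccharide chain is a hexose: natural
    flavonol 3-O-diglycosides (rutinose, neohesperidose, sophorose,
    sambubiose types) carry rhamnosyl/pentosyl/hexosyl termini on a
    3-O-bound hexose, and a swapped chain is indistinguishable from its
    partner by nominal neutral losses alone. Pass all sugar kinds to lift
    the restriction.
    """
    sugars = list(SUGARS.values())
    out: list[GlycosideStructure] = []
    chains: list[tuple[tuple[SugarUnit, ...], Linkage | None]] = [((), None)]
    chains += [((s,), None) for s in sugars]
    if max_chain >= 2:
        inners = [s for s in sugars if s.kind in chain_inner_kinds]
        for inner, term in itertools.product(inners, sugars):
            for lk in ("1->2", "1->6"):
                chains.append(((inner, term), Linkage(lk)))
    for agl in AGLYCONES.values():
        for (chain, lk), p7 in itertools.product(chains, [None] + sugars):
            for mal in (False, True):
                if mal and (not chain or chain[0].kind != "hexose"):
                    continue
                s = GlycosideStructure(agl, chain, lk, p7, mal)
                if s.is_bare_aglycone and not include_bare:
                    continue
                out.append(s)
    out.sort(key=lambda s: (s.aglycone.name, s.code))
    return out


def enumerate_candidates(
    precursor_mz: float, tol_ppm: float, space: list[GlycosideStructure] | None = None
) -> list[GlycosideStructure]:
    """All hypothesis-space structures whose [M−H]⁻ matches ``precursor_mz``.

    Matching is ppm-based; the returned order is deterministic (aglycone
    name, then structure code).
    """
    if space is None:
        space = enumerate_structures()
    return [s for s in space if within_tolerance(s.anion_mz, precursor_mz, tol_ppm)]
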