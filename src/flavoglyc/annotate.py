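"""Rule-based structural annotation of flavonol glycoside MS/MS spectra.

The decision procedure mirrors how a spectroscopist reads a negative-mode
evidence table:

1. exact-mass search of the hypothesis space at a ppm tolerance;
2. aglycone call from the Y0⁻ / [Y0−H]⁻• pair (301/300 quercetin, 285/284
   kaempferol, 315/314 isorhamnetin), the radical partner flagging
   3-O-glycosylation;
3. per-candidate fragment matching (±0.5 Da nominal window) scored by the
   matched-intensity fraction plus rule bonuses: aglycone agreement,
   base-peak class agreement, interglycosidic-linkage evidence, and a
   penalty for predicted high-intensity ions that are absent;
4. linkage call for disaccharide chains: 1→2 when the cross-ring −120 or
   terminal sugar-molecule loss is present above the presence threshold,
   1→6 when instead a Y-series ion dominates the spectrum.

Scores are deterministic; ties break toward fewer sugars, then the
lexicographically smaller structure code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .chem import anion_mz, ppm_error
from .fragments import _SUGAR_MOLECULE_LOSS, FragmentIon, predict_fragments
from .spectrum import Spectrum
from .structures import (
    AGLYCONES,
    Aglycone,
    GlycosideStructure,
    Linkage,
    enumerate_candidates,
    enumerate_structures,
)

__all__ = [
    "AglyconeCall",
    "AnnotationResult",
    "call_aglycone",
    "assign_linkage",
    "annotate",
    "annotate_table",
    "build_presence_matrix",
    "PRESENCE_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: minimum relative intensity (%) for a peak to trigger a fragmentation rule
PRESENCE_THRESHOLD = 5.0

_MATCH_WINDOW = 0.5

# score weights (normalised to [0, 1] at the end)
_W_AGLYCONE = 0.5
_W_BASEPEAK = 0.25
_W_LINKAGE = 0.15
_W_MISSING = 0.25
_SCORE_NORM = 1.0 + _W_AGLYCONE + _W_BASEPEAK + _W_LINKAGE


@dataclass(frozen=True)
class AglyconeCall:
    aglycone: Aglycone | None
    radical_present: bool
    evidence: dict[str, float] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.aglycone is not None


@dataclass
class AnnotationResult:
    """Ranked candidate structures for one spectrum."""

    spectrum_id: str
    candidates: list[tuple[GlycosideStructure, float, list[tuple[float, FragmentIon]]]]
    aglycone_call: AglyconeCall
    linkage_call: Linkage
    diagnostic: str = ""

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)

    @property
    def top(self) -> GlycosideStructure | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def score(self) -> float | None:
        return self.candidates[0][1] if self.candidates else None

    @property
    def name(self) -> str:
        return self.top.name() if self.candidates else "unassigned"


def call_aglycone(sp: Spectrum, presence_threshold: float = PRESENCE_THRESHOLD) -> AglyconeCall:
    """Identify the aglycone from its Y0⁻ / [Y0−H]⁻• nominal pair.

    The aglycone whose pair carries the greatest summed intensity wins; the
    radical flag is set when the [Y0−H]⁻• member is itself present above the
    threshold (diagnostic of 3-O-glycosylation).
    """
    if not sp.peaks:
        return AglyconeCall(None, False, {})
    evidence = {}
    radical = {}
    for agl in AGLYCONES.values():
        y0 = agl.y0_nominal
        evidence[agl.name] = sp.intensity_at(y0, _MATCH_WINDOW) + sp.intensity_at(
            y0 - 1, _MATCH_WINDOW
        )
        radical[agl.name] = sp.intensity_at(y0 - 1, _MATCH_WINDOW)
    best = max(evidence, key=evidence.get)
    if evidence[best] <= 0:
        return AglyconeCall(None, False, evidence)
    return AglyconeCall(
        AGLYCONES[best], radical[best] >= presence_threshold, evidence
    )


def _linkage_diagnostics(sp: Spectrum, candidate: GlycosideStructure) -> list[float]:
    """Observed intensities of the 1→2 diagnostic ions for ``candidate``."""
    M = candidate.nominal_mz
    term = candidate.position3[1]
    mol = _SUGAR_MOLECULE_LOSS[term.kind]
    targets = [M - 120, M - mol]
    if candidate.position7:
        res7 = candidate.position7.nominal_mass
        targets += [M - res7 - 120, M - res7 - mol]
    return [sp.intensity_at(t, _MATCH_WINDOW) for t in targets]


def assign_linkage(
    sp: Spectrum,
    candidate: GlycosideStructure,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> Linkage:
    """Call the interglycosidic linkage of a disaccharide chain.

    1→2 when the cross-ring −120 and/or terminal sugar-molecule loss is
    observed above the presence threshold; otherwise 1→6 when a Y-series ion
    of the candidate dominates the spectrum (is its base peak); otherwise
    unknown.
    """
    if len(candidate.position3) != 2:
        raise ValueError("linkage is only defined for a two-sugar position-3 chain")
    if not sp.peaks:
        return Linkage("unknown")
    if any(i >= presence_threshold for i in _linkage_diagnostics(sp, candidate)):
        return Linkage("1->2")
    y_mzs = {
        ion.nominal_mz
        for ion in predict_fragments(candidate)
        if ion.loss_label.startswith("Y") or ion.loss_label == "Y0"
    }
    base = sp.base_peak_mz
    if base is not None and any(abs(base - m) <= _MATCH_WINDOW for m in y_mzs):
        return Linkage("1->6")
    return Linkage("unknown")


def _score_candidate(
    sp: Spectrum,
    candidate: GlycosideStructure,
    agl_call: AglyconeCall,
    presence_threshold: float,
) -> tuple[float, list[tuple[float, FragmentIon]]]:
    predicted = predict_fragments(candidate)
    matched: list[tuple[float, FragmentIon]] = []
    matched_mz: set[float] = set()
    for ion in predicted:
        for mz, inten in sp.peaks:
            if abs(mz - ion.nominal_mz) <= _MATCH_WINDOW:
                matched.append((mz, ion))
                matched_mz.add(mz)
    total = sp.total_intensity
    f = sum(i for m, i in sp.peaks if m in matched_mz) / total if total else 0.0

    score = f
    if agl_call.assigned and candidate.aglycone.name == agl_call.aglycone.name:
        score += _W_AGLYCONE

    base = sp.base_peak_mz
    if base is not None and any(
        abs(base - ion.nominal_mz) <= _MATCH_WINDOW
        for ion in predicted
        if ion.intensity_class == "base"
    ):
        score += _W_BASEPEAK

    strong = [ion for ion in predicted if ion.intensity_class in ("base", "strong")]
    if strong:
        missing = sum(1 for ion in strong if sp.intensity_at(ion.nominal_mz) <= 0)
        score -= _W_MISSING * missing / len(strong)

    if len(candidate.position3) == 2:
        evidence = assign_linkage(sp, candidate, presence_threshold)
        if evidence.type != "unknown":
            score += _W_LINKAGE if evidence.type == candidate.linkage.type else -_W_LINKAGE
    elif len(candidate.position3) == 1 and candidate.position7:
        # 3,7-di-glycoside evidence: homolytic 3-O cleavage with the 7-sugar
        # still attached leaves the intermediate radical [M−res3−H]⁻•
        inter_radical = candidate.nominal_mz - candidate.position3[0].nominal_mass - 1
        if sp.intensity_at(inter_radical) >= presence_threshold:
            score += _W_LINKAGE
        else:
            score -= _W_LINKAGE

    return max(0.0, min(1.0, score / _SCORE_NORM)), matched


def annotate(
    sp: Spectrum,
    tol_ppm: float = 5.0,
    presence_threshold: float = PRESENCE_THRESHOLD,
    space: list[GlycosideStructure] | None = None,
) -> AnnotationResult:
    """Annotate one spectrum: exact-mass search, fragment scoring, ranking."""
    if space is None:
        space = enumerate_structures(include_bare=False)
    candidates = enumerate_candidates(sp.precursor_mz, tol_ppm, space)
    agl_call = call_aglycone(sp, presence_threshold)
    if not candidates:
        return AnnotationResult(
            sp.identifier,
            [],
            agl_call,
            Linkage("unknown"),
            diagnostic=f"no structure within {tol_ppm} ppm of m/z {sp.precursor_mz}",
        )
    scored = [
        (c, *_score_candidate(sp, c, agl_call, presence_threshold)) for c in candidates
    ]
    scored.sort(key=lambda t: (-t[1], t[0].sugar_count, t[0].code))
    ranked = [(c, s, m) for c, s, m in scored]
    top = ranked[0][0]
    linkage = (
        assign_linkage(sp, top, presence_threshold)
        if len(top.position3) == 2
        else Linkage("unknown")
    )
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "%s: aglycone=%s radical=%s linkage=%s top=%s score=%.3f matched=%s",
            sp.identifier,
            agl_call.aglycone.name if agl_call.assigned else "unassigned",
            agl_call.radical_present,
            linkage.type,
            top.code,
            ranked[0][1],
            sorted({int(m) for m, _ in ranked[0][2]}),
        )
    return AnnotationResult(sp.identifier, ranked, agl_call, linkage)


def annotate_table(
    spectra: list[Spectrum],
    tol_ppm: float = 5.0,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Annotate a collection into an identification table.

    One row per spectrum: retention time, anion formula, calculated and
    measured m/z, ppm error, structure code, rendered name and score.
    Structures annotated more than once get "isomer n" suffixes in
    retention-time order.
    """
    if not spectra:
        raise ValueError("empty spectrum list")
    ids = [s.identifier for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum identifiers")
    space = enumerate_structures(include_bare=False)
    rows = []
    results = []
    for sp in spectra:
        res = annotate(sp, tol_ppm, presence_threshold, space)
        results.append(res)
        top = res.top
        rows.append(
            {
                "id": sp.identifier,
                "rt_min": sp.retention_time,
                "formula": top.anion_formula.hill() + "-" if top else "",
                "calculated_mz": top.anion_mz if top else float("nan"),
                "measured_mz": sp.precursor_mz,
                "delta_ppm": ppm_error(top.anion_mz, sp.precursor_mz) if top else float("nan"),
                "code": top.code if top else "",
                "name": res.name,
                "linkage": res.linkage_call.type,
                "malonyl": bool(top.malonyl_on_6pp) if top else False,
                "aglycone": res.aglycone_call.aglycone.name if res.aglycone_call.assigned else "",
                "score": res.score,
                "n_matched": len({m for m, _ in res.candidates[0][2]}) if res.candidates else 0,
            }
        )
    df = pd.DataFrame(rows)
    # isomer numbering for repeated structures, ordered by retention time
    for code, grp in df[df.code != ""].groupby("code"):
        if len(grp) > 1:
            order = grp.sort_values("rt_min", na_position="last").index
            for n, idx in enumerate(order, start=1):
                df.loc[idx, "name"] = f"{df.loc[idx, 'name']} isomer {n}"
    return df


def build_presence_matrix(per_sample: dict[str, list[AnnotationResult]]) -> pd.DataFrame:
    """Samples × structure-codes boolean presence matrix."""
    codes = sorted(
        {res.top.code for results in per_sample.values() for res in results if res.assigned}
    )
    data = {
        sample: [
            any(res.assigned and res.top.code == c for res in results) for c in codes
        ]
        for sample, results in per_sample.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=codes).astype(bool)
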