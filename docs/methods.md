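# Methods

## Mass engine

Anion m/z values are sums of monoisotopic atomic masses (C 12 exactly,
H 1.00782503207, O 15.9949146196) over the anion's atom composition — the
formula of [M−H]⁻ already lacks one hydrogen relative to the neutral — plus
one electron mass (0.00054857990907 Da). Including the electron is not
cosmetic: it shifts a 600 Da ion by ~0.9 ppm, and it is the convention under
which the packaged reference masses reproduce exactly at five decimals.
Masses are rounded half-up to 5 decimals and ppm errors
((measured − calculated)/calculated × 10⁶) half-up to 2 decimals, matching
the precision of instrument-software reports; full-precision constants are
required (truncating H to eight significant figures already flips the fifth
decimal of C21H19O11⁻). Elements are limited to C/H/O/N/S, single negative
charge, no isotope patterns.

## Hypothesis space

A structure is: aglycone (quercetin, kaempferol or isorhamnetin) × a
position-3 chain of zero, one or two sugars (hexose 162.05282, deoxyhexose
146.05791, pentose 132.04226 Da residues) with a 1→2 or 1→6 interglycosidic
linkage × at most one 7-*O*-sugar × an optional malonyl (86.00039 Da) on the
6″-OH of the position-3 inner sugar. Two deliberate chemical constraints
narrow the combinatorial space:

* **Malonyl requires a hexose inner sugar.** Deoxyhexoses and pentoses have
  no free 6-OH to acylate. Besides being chemically forced, this removes
  exact isobars (quercetin 3-*O*-malonylrhamnoside would otherwise collide
  with kaempferol 3-*O*-malonylhexoside at 533.09368 to the last decimal).
* **Chain inner sugars default to hexose.** Natural flavonol
  3-*O*-diglycosides (rutinose, neohesperidose, sophorose, sambubiose types)
  put rhamnosyl/pentosyl/hexosyl termini on a 3-*O*-bound hexose, and a
  swapped chain predicts the same nominal neutral losses as its partner, so
  the two are not distinguishable from nominal-resolution fragment lists
  anyway. `enumerate_structures(chain_inner_kinds=...)` lifts the
  restriction.

The default space holds 201 glycosylated structures (345 with swapped
chains). Hexose stereochemistry (glucose vs galactose) is not modelled;
trivial names for standards-confirmed structures (rutin, hyperoside,
astragalin) are attached via an alias table.

## Fragmentation grammar

Predicted ions per structure: Y-series ions for every order-respecting
subset of glycosidic losses (a chain's inner sugar cannot leave before its
terminal one; a malonyl leaves with its sugar); radical [Y−H]⁻• partners
wherever the 3-O bond is cleaved homolytically (giving the aglycone radical
for chains, and additionally the intermediate [M−res−H]⁻• for
3,7-di-*O*-glycosides); the 1→2 diagnostics −120 (cross-ring ⁰,²X of the
terminal sugar) and −(residue+18) (terminal sugar molecule); −120 from any
state with a single sugar on the 3-OH (this explains ions like *m/z* 327
from kaempferol monohexosides); −44 for malonyl; −18/−28 from the precursor;
−15 methyl-radical satellites of precursor, aglycone pair and diagnostics
for isorhamnetin; and fixed aglycone secondary fragments (271/255/179/151
for quercetin, 255/227 for kaempferol, 300/299/271/255 for isorhamnetin).

Fragments are nominal integers matched at ±0.5 Da — evidence tables print
integer fragments — while precursors are matched in ppm. Each ion carries an
intensity-class prior (base/strong/weak) read off typical patterns: the
aglycone radical is the base peak for 1→2 chains but weak for 1→6; Y₀⁻
dominates 1→6 chains, monoglycosides and 7-*O*-glycosides; [M−H−44]⁻
dominates malonyl conjugates; the 7-*O*-sugar loss dominates triglycosides;
di-*O*-glycosides show strong intermediate Y ions with their own radicals.
Classes steer ranking and simulation only, never hard filtering.
`classify_loss` explains an arbitrary precursor→fragment difference as
combinations of up to two vocabulary losses. On the packaged reference
library every printed fragment at ≥10% relative intensity is explained by
the grammar or the loss vocabulary except two (peak 8's *m/z* 409 and peak
16's *m/z* 577, which would need deeper loss chains); the test suite freezes
that exception list.

## Annotation procedure

For one spectrum: enumerate mass-matching candidates (default 5 ppm); call
the aglycone as the Y₀/[Y₀−H] nominal pair (301/300, 285/284, 315/314) with
the greatest summed intensity, flagging 3-*O*-substitution when the radical
member is at or above the presence threshold (default 5%, the smallest
intensity printed in the reference data); score each candidate as

    score ∝ matched-intensity fraction
            + 0.5 · [aglycone agrees]
            + 0.25 · [observed base peak is a predicted 'base'-class ion]
            ± 0.15 · [linkage / di-glycoside evidence agrees / contradicts]
            − 0.25 · (fraction of predicted base/strong ions absent)

normalized to [0, 1]. Linkage evidence is 1→2 iff a −120 or −(residue+18)
diagnostic (also evaluated past the 7-*O* loss for triglycosides) is present
at ≥ the threshold, 1→6 when instead a Y-series ion is the base peak;
di-*O*-glycoside evidence is the intermediate radical [M−res3−H]⁻•. Ties
break toward fewer sugars, then lexicographic structure code. The procedure
is fully deterministic. Identification tables add "isomer n" suffixes in
retention-time order when one structure is annotated repeatedly; retention
time is carried as metadata only.

The weights were chosen so that each rule dominates exactly the ambiguity it
is meant to resolve (aglycone >> base-peak class >> linkage evidence) and
verified against the full 27-row reference library; they are constants, not
fitted parameters.

## HPTLC pipeline

Profiles are lane-averaged single-channel (R/G/B) intensities oriented from
the application line (R_F 0) to the solvent front (R_F 1) and resampled to
526 points, the variable count of the reference design (24 lanes × 526
pixels). Preprocessing order is frozen: median filter, radius 2 px (window
5; "2 pixels" is read as a radius, configurable) → row normalization to unit
sum → COW → mean centering. Normalization before warping makes segment
correlations scale-free; centering last keeps PCA covariance exact.

COW splits the axis into segments of ~50 points whose interior boundaries
may shift ±5 points (defaults; the slack must be under half the segment
length so warps stay monotone), interpolates each candidate segment to the
target grid, and maximizes the summed per-segment Pearson correlation by
dynamic programming over boundary offsets. Endpoints are fixed, length is
preserved, constant segments contribute zero correlation. A profile that is
a small circular shift of the target realigns to correlation ≥ 0.99.

PCA uses SVD of the centered matrix; explained variance percentages are
S²/ΣS². The Kaiser criterion is scale-dependent on raw pixel covariances, so
eigenvalues are scaled to mean 1 (the correlation-matrix convention) before
applying the ">1" cut-off — documented prominently because a raw-eigenvalue
cut-off would retain essentially everything or nothing depending on image
bit depth. Loading-peak reporting returns the R_F positions of the largest
|loading| local maxima per component.

## Synthetic generators

Spectra: predicted ions get intensities drawn per class (base 90–110,
strong 20–80, weak 3–15, before renormalizing the maximum to 100%) with
multiplicative log-normal noise (CV 0.25); spurious peaks arrive
Poisson(rate 2 by default) uniform in m/z between (aglycone − 50) and the
precursor at 1–10% intensity — deliberately straddling the 5% rule threshold
so noise actually stresses the rules; the precursor is jittered uniformly
within ±3 ppm, matching the ≤2.83 ppm accuracy of the reference
measurements. Densitograms: five classes by default, each a five-band
pattern at R_F 0.04/0.11/0.15/0.23/0.63 (the zones that drive class
separation in the reference loadings) with one zone emphasised per class
(amplitude 1.0 vs 0.25), Gaussian band σ 0.015 R_F, lane shifts
N(0, 0.004 R_F) ≈ 2 px, additive noise σ 0.01, clipped non-negative, 5
lanes per class. All generators are deterministic given a seed and return
truth records sufficient for scoring.

What the generators do **not** emulate: isotope patterns, adducts, in-source
fragmentation, collision-energy-dependent intensities, chimeric spectra;
plate-image artefacts (uneven illumination, baseline drift, lane curvature,
colour cross-talk) and non-Gaussian band shapes. Passing round-trip and
class-recovery tests therefore demonstrates the internal consistency of the
rules and pipeline under realistic noise magnitudes, not instrument-level
validation on raw data.

## Problem sizes and determinism

The round-trip benchmark uses 500 simulated spectra per noise level
(0/2/8 spurious peaks), where the annotator recovers ≥95% of structures
noiselessly with monotone degradation; the fingerprint benchmark uses 25
lanes × 526 variables. Both run in seconds. Remaining noiseless failures are
exact isobars: CH₂ swaps between a methoxylated aglycone and a
pentose→deoxyhexose exchange in 4-unit malonylated triglycosides, which no
nominal-mass evidence can separate.

## Known limitations

* Nominal fragment matching cannot separate glucose from galactose, nor
  positional isomers beyond 3-*O*/7-*O*; such pairs are reported as isomers
  with retention-time ordering.
* The intensity-class priors are heuristics from one instrument class
  (ion-trap/Orbitrap CID, negative mode); other platforms may need
  re-weighting.
* Quantification is out of scope: scores measure evidence coverage, not
  abundance.
* The Kaiser count on mean-scaled eigenvalues is a convention; with few
  samples it tends to retain most above-noise components.
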