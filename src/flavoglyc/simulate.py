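"""Ground-truthed synthetic inputs for the annotation and HPTLC pipelines.

``simulate_spectrum`` draws a product-ion spectrum from a glycoside
structure: the grammar's predicted ions receive class-driven relative
intensities (base ≈ 100%, strong ≈ 20–80%, weak ≈ 3–15%) with multiplicative
log-normal noise, spurious peaks arrive as a Poisson process uniform in m/z
between (aglycone − 50) and the precursor with intensities of 1–10% — below
most rule thresholds, so recovery-vs-noise curves probe the annotator's
margins — and the precursor m/z is jittered uniformly within a ppm window
matched to the instrument accuracy of the reference data (|Δ| ≤ 3 ppm).

``simulate_densitograms`` emulates multi-class plate fingerprints: each
class is a pattern of Gaussian bands at characteristic R_F zones (defaults
at 0.04/0.11/0.15/0.23/0.63, one zone emphasised per class) on a 526-point
axis, with per-lane retention shifts and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import predict_fragments
from .hptlc import N_VARIABLES, ProfileMatrix
from .spectrum import Spectrum, SpectrumCollection
from .structures import GlycosideStructure, enumerate_structures

__all__ = [
    "SpectrumSimConfig",
    "DensitogramSimConfig",
    "simulate_spectrum",
    "simulate_collection",
    "simulate_densitograms",
]

_CLASS_INTENSITY = {"base": (90.0, 110.0), "strong": (20.0, 80.0), "weak": (3.0, 15.0)}


@dataclass(frozen=True)
class SpectrumSimConfig:
    noise_peak_rate: float = 2.0  # expected spurious peaks per spectrum
    mz_jitter_ppm: float = 3.0  # matches the reference data's |Δ| ≤ 2.83 ppm
    intensity_noise_cv: float = 0.25
    seed: int | None = None

    def __post_init__(self):
        if min(self.noise_peak_rate, self.mz_jitter_ppm, self.intensity_noise_cv) < 0:
            raise ValueError("simulation parameters must be non-negative")


@dataclass(frozen=True)
class DensitogramSimConfig:
    n_classes: int = 5
    samples_per_class: int = 5
    band_positions: tuple[tuple[float, ...], ...] | None = None  # per class, R_F
    band_amplitudes: tuple[tuple[float, ...], ...] | None = None
    band_width: float = 0.015  # Gaussian sigma, R_F units
    shift_sd: float = 0.004  # lane-to-lane retention shift, R_F units
    noise_sd: float = 0.01
    n_points: int = N_VARIABLES
    seed: int | None = None

    def __post_init__(self):
        if self.band_positions is not None:
            for cls in self.band_positions:
                if any(not 0 < p < 1 for p in cls):
                    raise ValueError("band positions must lie in (0, 1)")
        if min(self.band_width, self.shift_sd, self.noise_sd) < 0:
            raise ValueError("noise parameters must be non-negative")

    def resolved_bands(self) -> tuple[tuple[tuple[float, ...], ...], tuple[tuple[float, ...], ...]]:
        """Per-class band positions and amplitudes (defaults if unset)."""
        if self.band_positions is not None:
            pos = self.band_positions
            amp = self.band_amplitudes or tuple(tuple(1.0 for _ in c) for c in pos)
            return pos, amp
        zones = (0.04, 0.11, 0.15, 0.23, 0.63)
        pos, amp = [], []
        for k in range(self.n_classes):
            pos.append(zones)
            # each class emphasises one zone and keeps a weak common pattern
            amp.append(tuple(1.0 if i == k % len(zones) else 0.25 for i in range(len(zones))))
        return tuple(pos), tuple(amp)


def simulate_spectrum(
    s: GlycosideStructure,
    cfg: SpectrumSimConfig = SpectrumSimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[Spectrum, dict]:
    """Simulate one spectrum; returns (spectrum, truth record)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    peaks: dict[int, float] = {}
    for ion in predict_fragments(s):
        lo, hi = _CLASS_INTENSITY[ion.intensity_class]
        inten = rng.uniform(lo, hi)
        if cfg.intensity_noise_cv > 0:
            inten *= rng.lognormal(0.0, cfg.intensity_noise_cv)
        peaks[ion.nominal_mz] = max(peaks.get(ion.nominal_mz, 0.0), inten)
    y0 = s.aglycone.y0_nominal
    precursor_nominal = s.nominal_mz
    for _ in range(rng.poisson(cfg.noise_peak_rate)):
        mz = int(rng.integers(max(y0 - 50, 50), precursor_nominal))
        inten = rng.uniform(1.0, 10.0)
        peaks[mz] = max(peaks.get(mz, 0.0), inten)
    top = max(peaks.values())
    peak_list = tuple((float(mz), i / top * 100.0) for mz, i in sorted(peaks.items()))
    jitter = rng.uniform(-cfg.mz_jitter_ppm, cfg.mz_jitter_ppm) * 1e-6
    precursor = s.anion_mz * (1.0 + jitter)
    sp = Spectrum("sim", precursor, peak_list)
    truth = {"code": s.code, "anion_mz": s.anion_mz, "name": s.name()}
    return sp, truth


def simulate_collection(
    n: int,
    cfg: SpectrumSimConfig = SpectrumSimConfig(),
    seed: int | None = None,
    space: list[GlycosideStructure] | None = None,
) -> tuple[SpectrumCollection, pd.DataFrame]:
    """Simulate ``n`` spectra from structures drawn uniformly from the space."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if space is None:
        space = enumerate_structures(include_bare=False)
    spectra, rows = [], []
    for i in range(n):
        s = space[int(rng.integers(len(space)))]
        sp, truth = simulate_spectrum(s, cfg, rng)
        sp = Spectrum(f"sim_{i:04d}", sp.precursor_mz, sp.peaks, None)
        truth["id"] = sp.identifier
        spectra.append(sp)
        rows.append(truth)
    return SpectrumCollection(spectra, source="simulated"), pd.DataFrame(rows).set_index("id")


def simulate_densitograms(
    cfg: DensitogramSimConfig = DensitogramSimConfig(),
) -> tuple[ProfileMatrix, pd.Series]:
    """Simulate a multi-class densitogram set; returns (matrix, class labels)."""
    rng = np.random.default_rng(cfg.seed)
    pos, amp = cfg.resolved_bands()
    rf = np.linspace(0.0, 1.0, cfg.n_points)
    rows, ids, labels = [], [], []
    for k in range(cfg.n_classes):
        for j in range(cfg.samples_per_class):
            shift = rng.normal(0.0, cfg.shift_sd) if cfg.shift_sd > 0 else 0.0
            y = np.zeros_like(rf)
            for p, a in zip(pos[k], amp[k]):
                y += a * np.exp(-0.5 * ((rf - (p + shift)) / cfg.band_width) ** 2)
            if cfg.noise_sd > 0:
                y += rng.normal(0.0, cfg.noise_sd, size=y.size)
            rows.append(np.clip(y, 0.0, None))
            ids.append(f"S{k * cfg.samples_per_class + j + 1:02d}")
            labels.append(k)
    df = pd.DataFrame(rows, index=ids, columns=rf)
    return ProfileMatrix(df, channel="G"), pd.Series(labels, index=ids, name="class")
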