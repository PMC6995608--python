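"""Containers for centroided negative-mode MS/MS peak lists."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Spectrum", "SpectrumCollection"]


@dataclass(frozen=True)
class Spectrum:
    """One product-ion spectrum of a deprotonated precursor.

    Peaks are (m/z, relative intensity in % of base peak) pairs, kept sorted
    by m/z. Fragment m/z values are typically nominal (integer) — the
    resolution at which evidence tables print them — but floats are accepted.
    """

    identifier: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    retention_time: float | None = None  # minutes

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for m, i in pk:
            if not (0 < i <= 100):
                raise ValueError(f"relative intensity {i} outside (0, 100] at m/z {m}")
        if pk and abs(max(i for _, i in pk) - 100.0) > 1e-9:
            raise ValueError("non-empty spectrum must contain a base peak at 100%")
        object.__setattr__(self, "peaks", pk)

    @property
    def base_peak_mz(self) -> float | None:
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p[1])[0]

    @property
    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)

    def intensity_at(self, mz: float, window: float = 0.5) -> float:
        """Summed intensity of peaks within ``window`` Da of ``mz``."""
        return sum(i for m, i in self.peaks if abs(m - mz) <= window)

    def normalized(self) -> "Spectrum":
        """Rescale intensities so the base peak is exactly 100%."""
        if not self.peaks:
            return self
        top = max(i for _, i in self.peaks)
        pk = tuple((m, i / top * 100.0) for m, i in self.peaks)
        return Spectrum(self.identifier, self.precursor_mz, pk, self.retention_time)


@dataclass
class SpectrumCollection:
    """A list of spectra with unique identifiers."""

    spectra: list[Spectrum] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        ids = [s.identifier for s in self.spectra]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate spectrum identifiers: {dup}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, identifier: str) -> Spectrum:
        for s in self.spectra:
            if s.identifier == identifier:
                return s
        raise KeyError(identifier)
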