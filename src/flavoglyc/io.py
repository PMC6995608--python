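"""Peak-list readers/writers (MGF, MSP) and the packaged reference library.

The MGF dialect is BEGIN IONS / END IONS blocks with TITLE as the spectrum
identifier, PEPMASS, CHARGE=1- and optional RTINSECONDS; peak lines are
"m/z intensity" pairs with intensities as percent of the base peak.

The packaged reference library holds 27 negative-mode MS/MS spectra of
flavonol 3-O-glycosides detected in bee-pollen extracts (precursor exact
masses, retention times and printed fragment lists), together with a
metadata table (anion formula, calculated mass, ppm error and the published
identification rendered as a structure code).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .spectrum import Spectrum, SpectrumCollection

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_msp",
    "write_msp",
    "load_reference_spectra",
    "load_reference_table",
]


class ParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")


def read_mgf(path: str | Path) -> SpectrumCollection:
    path = Path(path)
    spectra: list[Spectrum] = []
    in_block = False
    title = pepmass = rt = None
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise ParseError(path, line_no, "nested BEGIN IONS")
                in_block, title, pepmass, rt, peaks = True, None, None, None, []
            elif line == "END IONS":
                if not in_block:
                    raise ParseError(path, line_no, "END IONS without BEGIN IONS")
                if pepmass is None:
                    raise ParseError(path, line_no, "spectrum block missing PEPMASS")
                spectra.append(
                    Spectrum(
                        identifier=title or f"spectrum_{len(spectra) + 1}",
                        precursor_mz=pepmass,
                        peaks=tuple(peaks),
                        retention_time=rt,
                    )
                )
                in_block = False
            elif not in_block:
                raise ParseError(path, line_no, f"unexpected content outside block: {line!r}")
            elif "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    try:
                        pepmass = float(value.split()[0])
                    except ValueError:
                        raise ParseError(path, line_no, f"bad PEPMASS {value!r}") from None
                elif key == "RTINSECONDS":
                    rt = float(value) / 60.0
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(path, line_no, f"bad peak line {line!r}")
                try:
                    peaks.append((float(fields[0]), float(fields[1])))
                except ValueError:
                    raise ParseError(path, line_no, f"bad peak line {line!r}") from None
    if in_block:
        raise ParseError(path, line_no, "unterminated BEGIN IONS block")
    return SpectrumCollection(spectra, source=str(path))


def write_mgf(collection: SpectrumCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in collection:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.identifier}\n")
            fh.write(f"PEPMASS={sp.precursor_mz}\n")
            fh.write("CHARGE=1-\n")
            if sp.retention_time is not None:
                fh.write(f"RTINSECONDS={sp.retention_time * 60.0:g}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:g} {inten:g}\n")
            fh.write("END IONS\n")


def read_msp(path: str | Path) -> SpectrumCollection:
    path = Path(path)
    spectra: list[Spectrum] = []
    name = pepmass = rt = None
    peaks: list[tuple[float, float]] = []
    n_expected = None

    def flush(line_no):
        nonlocal name, pepmass, rt, peaks, n_expected
        if name is None and pepmass is None and not peaks:
            return
        if pepmass is None:
            raise ParseError(path, line_no, "record missing PrecursorMZ")
        if n_expected is not None and n_expected != len(peaks):
            raise ParseError(path, line_no, f"expected {n_expected} peaks, got {len(peaks)}")
        spectra.append(
            Spectrum(name or f"spectrum_{len(spectra) + 1}", pepmass, tuple(peaks), rt)
        )
        name = pepmass = rt = None
        peaks = []
        n_expected = None

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(line_no)
                continue
            key, _, value = line.partition(":")
            lk = key.lower()
            if lk == "name":
                name = value.strip()
            elif lk in ("precursormz", "precursor_mz"):
                pepmass = float(value)
            elif lk in ("rt", "retentiontime"):
                rt = float(value)
            elif lk == "num peaks":
                n_expected = int(value)
            else:
                fields = line.split()
                try:
                    peaks.append((float(fields[0]), float(fields[1])))
                except (ValueError, IndexError):
                    raise ParseError(path, line_no, f"bad line {line!r}") from None
        flush(line_no)
    return SpectrumCollection(spectra, source=str(path))


def write_msp(collection: SpectrumCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in collection:
            fh.write(f"Name: {sp.identifier}\n")
            fh.write(f"PrecursorMZ: {sp.precursor_mz}\n")
            if sp.retention_time is not None:
                fh.write(f"RT: {sp.retention_time:g}\n")
            fh.write(f"Num Peaks: {len(sp.peaks)}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:g} {inten:g}\n")
            fh.write("\n")


def _data_path(name: str):
    return importlib.resources.files("flavoglyc").joinpath("data").joinpath(name)


def load_reference_spectra() -> SpectrumCollection:
    """The packaged 27-spectrum flavonol glycoside reference library."""
    with importlib.resources.as_file(_data_path("reference_spectra.mgf")) as p:
        coll = read_mgf(p)
    coll.source = "reference"
    return coll


def load_reference_table() -> pd.DataFrame:
    """Metadata for the reference library, indexed by peak number (as str)."""
    with importlib.resources.as_file(_data_path("reference_table.csv")) as p:
        df = pd.read_csv(p, dtype={"id": str})
    return df.set_index("id")
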