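import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from flavoglyc.io import load_reference_spectra, load_reference_table
from flavoglyc.structures import SUGARS, AGLYCONES, GlycosideStructure, Linkage, enumerate_structures


@pytest.fixture(scope="session")
def reference():
    return load_reference_spectra()


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def space():
    return enumerate_structures(include_bare=False)


@pytest.fixture(scope="session")
def rutin():
    return GlycosideStructure(
        AGLYCONES["quercetin"],
        (SUGARS["hexose"], SUGARS["deoxyhexose"]),
        Linkage("1->6"),
    )


@pytest.fixture(scope="session")
def q_2pp_rutinoside():
    return GlycosideStructure(
        AGLYCONES["quercetin"],
        (SUGARS["hexose"], SUGARS["deoxyhexose"]),
        Linkage("1->2"),
    )
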