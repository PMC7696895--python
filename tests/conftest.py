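import numpy as np
import pytest

from identmix import (
    AlkaneLadder,
    CompoundLibrary,
    LibraryEntry,
    MixDesign,
    Spectrum,
)
from identmix.synth import SimulationConfig, generate_peaklists, generate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(20201112)


@pytest.fixture
def table2():
    """The bundled 13-compound sugar panel with its design."""
    return generate_truth(SimulationConfig(preset="table2", seed=0))


@pytest.fixture
def table2_batch():
    """Zero-noise, zero-dropout synthetic runs of the table2 panel."""
    cfg = SimulationConfig(preset="table2", noise_sd=0.0, dropout_rate=0.0, seed=0)
    lib, design = generate_truth(cfg)
    runs, ladders = generate_peaklists(lib, design, cfg)
    return lib, design, runs, ladders


@pytest.fixture
def simple_ladder():
    return AlkaneLadder.from_pairs([(10, 300.0), (12, 420.0)])


@pytest.fixture
def uneven_ladder():
    """Alkane set with uneven carbon gaps, as used in-run (C18 → C17)."""
    carbons = [10, 12, 15, 17, 19, 22, 28, 32, 36]
    return AlkaneLadder.from_pairs([(c, 100.0 + 60.0 * (c - 10)) for c in carbons])


@pytest.fixture
def spectral_library(rng):
    entries = []
    for i in range(4):
        n = int(rng.integers(5, 12))
        mz = np.sort(rng.choice(np.arange(60, 400), size=n, replace=False)).astype(float)
        inten = rng.lognormal(4, 1, size=n)
        entries.append(
            LibraryEntry(
                compound_name=f"Std{i}",
                derivatisation_state="(TMS)",
                expected_ri=1000.0 + 100 * i,
                spectrum=Spectrum(mz, inten),
            )
        )
    return CompoundLibrary(entries=entries)
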