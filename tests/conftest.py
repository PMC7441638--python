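import numpy as np
import pandas as pd
import pytest

from queendx import LfqMatrix, SimulationConfig


@pytest.fixture
def tiny_maxquant_path(tmp_path):
    """3-protein, 2-sample MaxQuant-style proteinGroups TSV, one reverse row."""
    text = (
        "Majority protein IDs\tReverse\tPotential contaminant\t"
        "Only identified by site\tLFQ intensity S1\tLFQ intensity S2\n"
        "XP_0001.1;XP_0002.1\t\t\t\t1024\t2048\n"
        "REV__XP_0003.1\t+\t\t\t512\t0\n"
        "XP_0004.1\t\t\t\t0\t4096\n"
    )
    path = tmp_path / "proteinGroups.txt"
    path.write_text(text)
    return path


@pytest.fixture
def small_matrix():
    """Deterministic 4-protein, 6-sample log-ready matrix, two groups."""
    rng = np.random.default_rng(42)
    samples = [f"ctl_{i}" for i in range(3)] + [f"hs_{i}" for i in range(3)]
    vals = 2.0 ** rng.uniform(20, 24, size=(4, 6))
    intensities = pd.DataFrame(vals, index=["A", "B", "C", "D"], columns=samples)
    metadata = pd.DataFrame({"group": ["control"] * 3 + ["heatshock"] * 3}, index=samples)
    return LfqMatrix(intensities=intensities, metadata=metadata)


@pytest.fixture
def heat_config():
    """One heat marker at lfc 3, 7 vs 7 queens, no censoring (clean recovery)."""
    return SimulationConfig(
        n_proteins=120,
        groups=(("control", 7), ("heatshock", 7)),
        marker_effects={"XP_001120006.2": ("heatshock", 3.0)},
        missingness=(0.0, 3.0),
        n_decoys=4,
        n_contaminants=2,
        seed=7,
    )
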