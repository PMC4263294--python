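import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from oxomap.io_formats import ProbeSignal
from oxomap.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture
def random_probes():
    """1,000 probes at random positions on two chromosomes, sorted."""
    rng = np.random.default_rng(42)
    probes = []
    for chrom, n in (("chr1", 600), ("chr2", 400)):
        starts = np.sort(rng.integers(0, 5_000_000, n))
        for s in starts:
            probes.append(ProbeSignal(chrom, int(s), int(s) + 60, float(rng.normal())))
    return probes


def write_lines(path: Path, lines) -> Path:
    path.write_text("\n".join(lines) + "\n")
    return path
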