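import numpy as np
import pytest

import umiforge as uf


@pytest.fixture(scope="session")
def panel():
    """Two random 100-nt amplicons, pairwise distinguishable at any k."""
    return uf.demo_amplicons(n=2, length=100, seed=7)


@pytest.fixture(scope="session")
def small_library(panel):
    """A small noisy library with one spiked variant and off-target reads."""
    amp = panel[0]
    off = 40
    ref = amp.sequence[off]
    alt = "A" if ref != "A" else "C"
    cfg = uf.SimConfig(
        pattern=uf.parse_pattern("N" * 12, "reference"),
        molecules_per_amplicon=120,
        truth_variants=[uf.TruthVariant(amp.name, off, ref, alt, 0.1)],
        seq_error_rate=0.001,
        off_target_fraction=0.1,
        seed=11,
    )
    reads, truth = uf.simulate_library(panel, cfg)
    return cfg, reads, truth


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))
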