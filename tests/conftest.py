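import numpy as np
import pytest

from imprintseq import synthetic_data as sd
from imprintseq.core_io import GeneAnnotation, SignalTrack


@pytest.fixture()
def toy_track():
    """20-bp single-chromosome track whose + strand value equals the genomic position."""
    track = SignalTrack({"chrT": 20})
    track.values("chrT", "+")[:] = np.arange(20, dtype=float)
    track.values("chrT", "-")[:] = np.arange(20, dtype=float)
    return track


@pytest.fixture()
def plus_gene():
    return GeneAnnotation("gp", "chrT", "+", 5, 15)


@pytest.fixture()
def minus_gene():
    return GeneAnnotation("gm", "chrT", "-", 15, 5)


@pytest.fixture(scope="session")
def sim_small():
    """120-gene simulated study with a planted cross-linking track."""
    sim = sd.generate_genome(n_genes=120, length_range=(800, 1800), seed=11)
    track = sd.plant_crac_track(sim, seed=12)
    return sim, track


@pytest.fixture(scope="session")
def sim_study():
    """Full 600-gene study-scale simulation (shared; treat as read-only)."""
    sim = sd.generate_genome(n_genes=600, seed=101)
    track = sd.plant_crac_track(sim, seed=102)
    return sim, track
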