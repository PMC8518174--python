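import numpy as np
import pytest

from c3dscan import (
    PeakCallConfig,
    call_peaks_stranded,
    generate_genome,
    plant_truth,
    simulate_fragments,
    split_by_class,
)
from c3dscan.synthetic import SimConfig


@pytest.fixture(scope="session")
def small_study():
    """500-kb genome, 40 planted motifs/peaks, 3 donors x 5e4 fragments."""
    genome, motifs = generate_genome(500_000, 1, 0.4, 40, seed=7)
    cfg = SimConfig(n_fragments_per_donor=50_000, n_donors=3, seed=11)
    truth = plant_truth(genome, motifs, n_donors=3, config=cfg, seed=5)
    frags = simulate_fragments(genome, truth, cfg)
    return dict(genome=genome, motifs=motifs, truth=truth, frags=frags, config=cfg)


@pytest.fixture(scope="session")
def standard_study():
    """The 2-Mb benchmark: 100 planted strand-specific peaks, 5 donors x 2e5."""
    genome, motifs = generate_genome(2_000_000, 1, 0.4, 100, seed=42)
    cfg = SimConfig(n_fragments_per_donor=200_000, n_donors=5, seed=43)
    truth = plant_truth(genome, motifs, n_donors=5, config=cfg, seed=44)
    frags = simulate_fragments(genome, truth, cfg)
    return dict(genome=genome, motifs=motifs, truth=truth, frags=frags, config=cfg)


@pytest.fixture(scope="session")
def standard_peaks(standard_study):
    """Per-donor C3D peak calls on the 2-Mb benchmark."""
    genome = standard_study["genome"]
    out = {}
    for donor, fs in standard_study["frags"].items():
        c3d = split_by_class(fs)["C3D"]
        out[donor] = call_peaks_stranded(c3d, genome, PeakCallConfig())
    return out
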