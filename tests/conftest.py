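import numpy as np
import pytest

from ribomorph.formats import SequenceRecord
from ribomorph.pipeline import PipelineConfig, run_ref_pipeline
from ribomorph.simulate import ReadProfile, SimParams, simulate_dataset


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_sim():
    """A small three-morph array with reads, shared across pipeline tests."""
    params = SimParams(
        n_sources=4,
        morph_length=1500,
        n_morphs=3,
        copy_count_law=("uniform", 2, 6),
        seed=11,
    )
    ont_profile = ReadProfile(8000, 0.4, 0.025, 0.012, 0.013, 1.5)
    array, reference, hifi, ont = simulate_dataset(
        params, hifi_coverage=30, ont_coverage=40, ont_profile=ont_profile
    )
    return params, array, reference, hifi, ont


@pytest.fixture(scope="session")
def small_pipeline_result(small_sim):
    params, array, reference, hifi, ont = small_sim
    config = PipelineConfig(
        reference=reference,
        hifi=hifi,
        ont=ont,
        approx_morph_size=1500,
        min_pts=3,
        report_min_coverage=10,
    )
    return config, array, run_ref_pipeline(config)


@pytest.fixture(scope="session")
def single_morph_setup():
    """Error-free reads over a single-morph tandem array."""
    rng = np.random.default_rng(5)
    unit = random_dna(rng, 1500)
    array_seq = unit * 10
    hifi = [
        SequenceRecord(f"h{i}", array_seq[p : p + 3000])
        for i, p in enumerate(range(0, len(array_seq) - 3000, 200))
    ]
    ont = [
        SequenceRecord(f"o{i}", array_seq[p : p + 6000])
        for i, p in enumerate(range(0, len(array_seq) - 6000, 400))
    ]
    reference = SequenceRecord("ref", unit)
    return unit, array_seq, reference, hifi, ont
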