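import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tmp_dataset(tmp_path):
    """A small recent-HT dataset on disk, for pipeline-level tests."""
    from httdetect.synthetic_data import default_ht_scenario, generate_dataset

    return generate_dataset(default_ht_scenario(seed=42, n_genes=8), tmp_path / "ds")


def random_alignment(rng, n_seqs=4, length=60, gap_rate=0.0, n_rate=0.0, mutation=0.1):
    """Alignment of diverged variants of a common ancestor (so pairwise
    distances stay below JC saturation), with optional gaps and Ns."""
    from httdetect.io_formats import Alignment, SequenceRecord

    bases = np.array(list("ACGT"))
    root = bases[rng.integers(0, 4, size=length)]
    rows = []
    for i in range(n_seqs):
        chars = root.copy()
        mask = rng.random(length) < mutation
        chars[mask] = bases[rng.integers(0, 4, size=int(mask.sum()))]
        mask = rng.random(length) < gap_rate
        chars[mask] = "-"
        mask = rng.random(length) < n_rate
        chars[mask] = "N"
        rows.append(SequenceRecord(f"s{i}", "".join(chars)))
    return Alignment(tuple(rows))
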