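import numpy as np
import pytest

from ecglearn import dataio, synthetic


def make_record(record_id="r0", labels=frozenset({"NORM"}), n_leads=2,
                n_samples=8, rate=100, value=0.0):
    """Lightweight record for container/filter tests (not a real waveform)."""
    sig = np.full((n_leads, n_samples), value, dtype=np.float64)
    return dataio.ECGRecord(record_id=record_id, signal=sig,
                            sampling_rate=rate, labels=labels)


@pytest.fixture(scope="session")
def tiny_dataset() -> dataio.Dataset:
    """60-record, 4 s synthetic dataset shared across tests (seeded)."""
    return synthetic.generate_dataset(synthetic.preset_config("tiny", seed=1))


@pytest.fixture(scope="session")
def tiny_labeled(tiny_dataset) -> dataio.Dataset:
    return dataio.filter_null_labels(tiny_dataset)
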