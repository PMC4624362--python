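import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from crisprlocus.simulate import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset at seed 42: genome, targets, truth."""
    return generate_dataset(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def default_spacer_records(default_dataset):
    from crisprlocus.seqcore import SeqRecord

    _, _, truth = default_dataset
    return [SeqRecord(id=f"Sp{i + 1}", seq=s) for i, s in enumerate(truth.spacer_seqs)]
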