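import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from amplimine import DetectionMethod, PcrParams, SequenceRecord, make_panel


@pytest.fixture
def params():
    return PcrParams()


@pytest.fixture
def panel():
    return make_panel(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def method_factory(rng):
    """Build ad-hoc methods with freshly drawn primers/probes."""

    counter = {"n": 0}

    def make(specificity="event", probe=True, primer_len=20, probe_len=24):
        counter["n"] += 1
        return DetectionMethod(
            method_id=f"TST-{counter['n']:02d}",
            specificity=specificity,
            target_name="test target",
            fw_primer=random_dna(rng, primer_len),
            rv_primer=random_dna(rng, primer_len),
            probe=random_dna(rng, probe_len) if probe else None,
        )

    return make


def make_record(seq: str, record_id="r1", label="ds", description="") -> SequenceRecord:
    return SequenceRecord(record_id=record_id, description=description,
                          sequence=seq, dataset_label=label)
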