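import numpy as np
import pytest

from colodefense.cohort import QpcrReaction
from colodefense.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plasma_triplet():
    """Factory for a subject's three plasma reactions from Ct triples."""

    def make(
        actb=(28.0, 29.0, 30.0),
        sept=(None, None, None),
        sdc=(None, None, None),
        subject_id="X",
    ):
        return [
            QpcrReaction(
                subject_id=subject_id,
                specimen="plasma",
                replicate_index=i + 1,
                ct_actb=actb[i],
                ct_msept9=sept[i],
                ct_msdc2=sdc[i],
            )
            for i in range(3)
        ]

    return make


@pytest.fixture
def small_config():
    """A 15-subject simulation config that keeps IO/CLI tests fast."""

    def make(seed=0):
        cfg = SimulationConfig(seed=seed)
        cfg.group_sizes = {
            "CRC": 5,
            "Ade": 3,
            "HP": 2,
            "OtherTumor": 1,
            "Control": 4,
        }
        cfg.crc_stage_mix = {"0": 1, "I": 1, "II": 1, "III": 1, "IV": 1, "unknown": 0}
        return cfg

    return make
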