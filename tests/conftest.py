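import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scnkit.synthetic_data import CohortConfig, generate_cohort
from scnkit.volumetrics import VolumeTable


def null_config(**kwargs) -> CohortConfig:
    """A cohort config with nothing planted (no effects, no correlation)."""
    defaults = dict(
        effect_table={},
        behavior_link={},
        community_assignment={},
        within_community_r=0.0,
        between_community_r=0.0,
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


@pytest.fixture
def default_cohort():
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def null_cohort():
    return generate_cohort(null_config(seed=12))


def make_table(volumes: dict[str, list[float]], tbv, groups, group_order=None) -> VolumeTable:
    """Hand-build a small volume table."""
    n = len(tbv)
    ids = [f"m{i:02d}" for i in range(n)]
    frame = pd.DataFrame(
        {"group": groups, "tbv": tbv, **volumes},
        index=pd.Index(ids, name="animal_id"),
    )
    order = group_order or tuple(dict.fromkeys(groups))
    return VolumeTable(frame, order)


@pytest.fixture
def rng():
    return np.random.default_rng(20230706)
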