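import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from freeop.agents import GROUP_PRESETS, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def young_cohort():
    """15 younger-control sessions, fixed seed (shared across tests)."""
    return simulate_cohort(
        GROUP_PRESETS["younger_control"], 15, 2024, group="younger_control"
    )


@pytest.fixture(scope="session")
def older_cohort():
    return simulate_cohort(
        GROUP_PRESETS["older_control"], 15, 2025, group="older_control"
    )


def toy_splitplot_table(group_sizes=(4, 4), k=3, seed=0, integers=True):
    """Small random complete split-plot table for oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for j, n in enumerate(group_sizes):
        for _ in range(n):
            base = rng.integers(-3, 4) if integers else rng.normal()
            for lev in range(k):
                eps = rng.integers(-2, 3) if integers else rng.normal()
                rows.append(
                    dict(
                        subject=f"s{sid:02d}",
                        group=f"g{j}",
                        level=lev,
                        y=float(base + (j + 1) * lev + eps),
                    )
                )
            sid += 1
    return pd.DataFrame(rows)
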