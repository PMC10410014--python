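import numpy as np
import pandas as pd
import pytest

from metafrail.mr import HarmonizedInstruments


def make_hset(beta_x, se_x, beta_y, se_y, snp_ids=None) -> HarmonizedInstruments:
    """Build a harmonized instrument set directly from effect arrays."""
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.broadcast_to(np.asarray(se_x, dtype=float), beta_x.shape)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), beta_x.shape)
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:04d}" for j in range(len(beta_x))]
    table = pd.DataFrame(
        {
            "variant_id": snp_ids,
            "beta_x": beta_x,
            "se_x": se_x,
            "beta_y": beta_y,
            "se_y": se_y,
            "eaf_x": 0.3,
            "eaf_y": 0.3,
            "ratio": beta_y / beta_x,
            "ratio_se": se_y / np.abs(beta_x),
            "flipped": False,
        }
    )
    return HarmonizedInstruments(
        table, pd.DataFrame(columns=["variant_id", "reason"])
    )


@pytest.fixture
def two_snp_hset() -> HarmonizedInstruments:
    """The hand-checked two-instrument example: theta-hat 0.3, Q = 2."""
    return make_hset([1.0, 1.0], 0.01, [0.2, 0.4], 0.1)
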