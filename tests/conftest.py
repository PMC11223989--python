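import numpy as np
import pandas as pd
import pytest

from lpaoh import ModelParams, SimConfig, generate_panel, simulate_sample


TINY_GENOME = {"chrA": 30_000_000, "chrB": 20_000_000}


@pytest.fixture
def tiny_genome():
    return dict(TINY_GENOME)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def tiny_panel(tiny_genome):
    cfg = SimConfig(chrom_lengths=tiny_genome, seed=123)
    return generate_panel(cfg)


def prejoin(panel: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Observations for counts simulated on this panel (row-aligned)."""
    return pd.DataFrame(
        {
            "chrom": panel["chrom"],
            "pos": panel["pos"],
            "af": panel["af"],
            "r": counts["ref_count"].to_numpy(),
            "a": counts["alt_count"].to_numpy(),
        }
    )


def make_obs(chrom, pos, af, r, a):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "af": af, "r": r, "a": a})
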