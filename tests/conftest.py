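import numpy as np
import pandas as pd
import pytest

import memorydiff as md
from memorydiff.config import default_config_a


@pytest.fixture(scope="session")
def small_config():
    """Species-A design at reduced gene count: fast but exercises every
    planted role."""
    from memorydiff.config import default_effects_a

    cfg = md.SimulationConfig(
        seed=11,
        n_genes=150,
        design=default_config_a().design,
        planted_effects=default_effects_a(n_per_role=4),
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_bundle(small_config):
    proteins, transcripts, gene_map, truth = md.generate_reference(small_config)
    hits = md.generate_alignment_table(truth, small_config)
    return {
        "config": small_config,
        "proteins": proteins,
        "transcripts": transcripts,
        "gene_map": gene_map,
        "truth": truth,
        "hits": hits,
    }


@pytest.fixture(scope="session")
def small_counts(small_bundle):
    counts, meta = md.generate_counts(small_bundle["truth"], small_bundle["config"])
    return counts, meta


def two_group_meta(n_reps: int = 3) -> pd.DataFrame:
    """Minimal unconditioned-vs-treated metadata with replicate labels."""
    n = 2 * n_reps
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "species": "sp",
            "conditioning_type": ["unconditioned"] * n_reps + ["T"] * n_reps,
            "time_point": ["none"] * n_reps + ["1h"] * n_reps,
            "replicate": [f"r{i + 1}" for i in range(n_reps)] * 2,
        }
    )


@pytest.fixture(scope="session")
def two_group_design():
    return md.build_design(two_group_meta())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
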