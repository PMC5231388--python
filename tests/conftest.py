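import numpy as np
import pandas as pd
import pytest

import evoenrich as ev


def tiny_generator(seed=11, **overrides):
    """Desk-scale generator settings shared across test modules."""
    kw = dict(
        n_snps=3000,
        n_samples=60,
        chrom_lengths={"1": 8_000_000, "6": 8_000_000},
        tau={"SD": 1e-4},
        seed=seed,
    )
    kw.update(overrides)
    return ev.GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def small_study():
    return ev.generate_study(tiny_generator())


@pytest.fixture(scope="session")
def small_scores(small_study):
    """(aligned index, score table, LD neighborhood) for the shared study."""
    idx = ev.align(small_study.stats, small_study.panel)
    table, nbhd = ev.build_score_table(small_study.panel, idx, small_study.tracks)
    return idx, table, nbhd


@pytest.fixture()
def score_frame():
    """Hand-built score table for unit tests that need exact control."""
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(6)],
            "chrom": ["1"] * 6,
            "pos": [100, 200, 300, 400, 500, 600],
            "maf": [0.1, 0.2, 0.3, 0.4, 0.25, 0.15],
            "ld_HAR": [0.0, 0.5, 1.0, 1.5, 0.0, 2.0],
            "tot_ld": [1.0, 1.5, 2.0, 2.5, 1.0, 3.0],
        }
    )
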