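"""Shared fixtures: small simulated cohort pairs reused across the suite."""

import numpy as np
import pytest

import isodrift as iso
from isodrift.types import CohortPair


@pytest.fixture(scope="session")
def neutral_small():
    """A small neutral symmetric pair (2 x 2 Mb) with its minimum-set
    frequency table; shared by oracle and invariance tests."""
    cfg = iso.neutral_symmetric_config(
        seed=123, n_chroms=2, chrom_length_bp=2_000_000, n_coding_sites_per_chrom=4_000
    )
    vt, gm, truth = iso.simulate_cohort_pair(cfg)
    pair = CohortPair(cfg.isolate_label, cfg.general_label)
    gm_min = iso.subsample_cohorts(gm, "minimum", seed=1)
    ft_min = iso.allele_frequencies(gm_min, vt, [pair.isolate, pair.general])
    return {"cfg": cfg, "vt": vt, "gm": gm, "gm_min": gm_min, "ft": ft_min, "pair": pair, "truth": truth}


@pytest.fixture(scope="session")
def selected_pair():
    """A bottleneck-with-selection pair at default (2 x 5 Mb) scale."""
    cfg = iso.bottleneck_selected_config(seed=7)
    vt, gm, truth = iso.simulate_cohort_pair(cfg)
    pair = CohortPair(cfg.isolate_label, cfg.general_label)
    gm_min = iso.subsample_cohorts(gm, "minimum", seed=1)
    ft_min = iso.allele_frequencies(gm_min, vt, [pair.isolate, pair.general])
    return {"cfg": cfg, "vt": vt, "gm": gm, "gm_min": gm_min, "ft": ft_min, "pair": pair, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
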