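"""Shared fixtures: small simulated regions and read sets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from csatk.simulate import SimConfig, make_target_sites, simulate_clones, \
    simulate_reads, simulate_region


@pytest.fixture(scope="session")
def small_truth():
    """A 20-kb two-haplotype region with moderate variant density."""
    cfg = SimConfig(region_len=20_000, snp_rate=1e-3, indel_rate=2e-4,
                    seq_error_rate=0.0, duplicate_frac=0.0, seed=11)
    return cfg, simulate_region(cfg)


@pytest.fixture(scope="session")
def small_clone_reads():
    """One ~6-kb clone with error-free 60x reads (fast to assemble)."""
    cfg = SimConfig(region_len=20_000, seed=2, coverage=60.0, seq_error_rate=0.0,
                    duplicate_frac=0.0, clone_len_min=5000, clone_len_mode=6000,
                    clone_len_max=7000, clones_per_site=1)
    truth = simulate_region(cfg)
    rec, meta = simulate_clones(truth, cfg, [(9000, 9600)])[0]
    pairs, origins = simulate_reads(rec, cfg, 500)
    return cfg, rec, pairs, origins


@pytest.fixture
def rng():
    return np.random.default_rng(0)
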