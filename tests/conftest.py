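"""Shared fixtures: small simulated datasets and cached experiment grids."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from ghostpop.coalescent import LocusAlignment
from ghostpop.experiments import ExperimentConfig, contrast_from_table, run_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_alignment(rng, n_hap=12, n_sites=8, pops=("pop0", "pop1"), length=100):
    """A random biallelic alignment with balanced population labels."""
    per = n_hap // len(pops)
    labels = tuple(p for p in pops for _ in range(per))
    alleles = rng.integers(0, 2, size=(len(labels), n_sites)).astype(np.int8)
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    return LocusAlignment(alleles, positions, labels, length)


@functools.lru_cache(maxsize=None)
def grid_table(seed: int):
    """Full model grid (a-e x recent/deep x 10 replicates) for one root seed."""
    cfg = ExperimentConfig(seed=seed)
    return cfg, run_grid(cfg)


@functools.lru_cache(maxsize=None)
def grid_contrasts(seed: int):
    """Permutation contrasts (mean FST, mean pi) for both divergence depths."""
    cfg, table = grid_table(seed)
    return {
        div: contrast_from_table(
            table, div, n_perm=cfg.n_permutations, seed=cfg.seed
        )
        for div in ("recent", "deep")
    }


@pytest.fixture(scope="session")
def deep_grid():
    """The seed-1 deep-divergence half of the grid, reused across tests."""
    _, table = grid_table(1)
    return table[table.divergence == "deep"]
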