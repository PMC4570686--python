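"""Shared fixtures: tiny worked-example profiles and synthetic catalogs."""

import pytest

from crossgwas.catalog import TraitProfile
from crossgwas.synthetic import SyntheticSpec, generate_catalog


@pytest.fixture
def chao_profiles():
    """The worked Chao-estimator example: {a:1,b:2,c:3} vs {a:2,b:1,d:1}."""
    p1 = TraitProfile("t1", "snp", {"a": 1, "b": 2, "c": 3})
    p2 = TraitProfile("t2", "snp", {"a": 2, "b": 1, "d": 1})
    return p1, p2


@pytest.fixture
def morisita_profiles():
    """The worked Morisita example: {a:2,b:1} vs {a:1,c:3}."""
    p1 = TraitProfile("t1", "snp", {"a": 2, "b": 1})
    p2 = TraitProfile("t2", "snp", {"a": 1, "c": 3})
    return p1, p2


@pytest.fixture
def planted_catalog(tmp_path):
    """A small synthetic catalog with two planted overlapping pairs."""
    spec = SyntheticSpec(
        n_traits=10,
        pool_size=500,
        snps_per_trait=12,
        planted_pairs=[(0, 1, 6), (2, 3, 7)],
        seed=11,
    )
    path = tmp_path / "catalog.tsv"
    truth = generate_catalog(spec, path)
    return path, truth, spec


def random_profile(rng, trait, pool_size=200, n_items=(3, 15), max_abund=4):
    """A random trait profile drawn from a shared item pool."""
    n = int(rng.integers(*n_items))
    items = rng.choice(pool_size, size=n, replace=False)
    return TraitProfile(
        trait,
        "snp",
        {f"rs{i}": int(rng.integers(1, max_abund + 1)) for i in items},
    )
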