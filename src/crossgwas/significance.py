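"""Significance of trait-pair overlaps and of catalog-wide cross-phenotype counts.

Two routes assign significance to an observed overlap of k items between
traits with n1 and n2 items drawn from a universe of N_t:

* a theoretical one-tailed p from the hypergeometric distribution,
  P(X >= k | N_t, n1, n2) — equivalent to a one-tailed Fisher exact test;
* an empirical p from permutation: both traits are resampled without
  replacement from the item pool and the overlap re-counted.

Pairwise p-values are Bonferroni-corrected across all evaluated pairs.  A
separate catalog-wide permutation builds the null distribution of the number
of cross-phenotype items (items hit by two or more traits) when every trait
draws its items at random from a common pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .similarity import (
    OverlapSummary,
    PairIndexValues,
    pair_index_values,
    summarize_overlap,
)

__all__ = [
    "PairResult",
    "PermutationNull",
    "hypergeom_p_at_least",
    "expected_overlap",
    "overlap_variance",
    "fold_enrichment",
    "empirical_pair_p",
    "bonferroni_adjust",
    "catalog_crossphenotype_null",
    "significant_pairs",
]


@dataclass
class PermutationNull:
    """A permutation null distribution for an overlap/cross-phenotype count."""

    replicate_counts: np.ndarray
    n_replicates: int
    observed: int
    p_value: float
    seed: int

    @property
    def exceedance_fraction(self) -> float:
        """Raw fraction of replicates with count >= observed (no +1 smoothing)."""
        return float(np.mean(self.replicate_counts >= self.observed))


@dataclass
class PairResult:
    """Overlap, index values and significance for one trait pair."""

    summary: OverlapSummary
    index_values: PairIndexValues
    p_hyper: float
    p_bonferroni: float
    expected_k: float
    variance_k: float
    n_universe: int
    p_empirical: float | None = None
    significant: bool = False

    @property
    def trait1(self) -> str:
        return self.summary.trait1

    @property
    def trait2(self) -> str:
        return self.summary.trait2

    @property
    def fold_enrichment(self) -> float:
        return self.summary.k / self.expected_k if self.expected_k > 0 else float("nan")


def hypergeom_p_at_least(k, n1, n2, n_universe):
    """Upper-tail P(X >= k) for overlap under the hypergeometric model.

    X is the overlap when n1 items are drawn without replacement from a
    universe of ``n_universe`` of which n2 are "marked".  The tail includes
    k itself (one-tailed Fisher convention); k = 0 returns 1.  Arguments may
    be scalars or broadcastable arrays.
    """
    k = np.asarray(k)
    n1a, n2a, na = np.asarray(n1), np.asarray(n2), np.asarray(n_universe)
    if np.any(k < 0) or np.any(k > np.minimum(n1a, n2a)):
        raise ValueError("need 0 <= k <= min(n1, n2)")
    if np.any(n1a > na) or np.any(n2a > na):
        raise ValueError("need n1, n2 <= n_universe")
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    out = stats.hypergeom.sf(k - 1, na, n2a, n1a)
    return float(out) if out.ndim == 0 else out


def expected_overlap(n1: int, n2: int, n_universe: int) -> float:
    """E(k) = n1*n2/N_t under the hypergeometric model."""
    if n_universe < 2:
        raise ValueError("n_universe must be >= 2")
    if n1 > n_universe or n2 > n_universe:
        raise ValueError("need n1, n2 <= n_universe")
    return n1 * n2 / n_universe


def overlap_variance(n1: int, n2: int, n_universe: int) -> float:
    """V(k) = n1*(n2/N_t)*((N_t-n2)/N_t)*((N_t-n1)/(N_t-1))."""
    if n_universe < 2:
        raise ValueError("n_universe must be >= 2")
    if n1 > n_universe or n2 > n_universe:
        raise ValueError("need n1, n2 <= n_universe")
    nt = n_universe
    return n1 * (n2 / nt) * ((nt - n2) / nt) * ((nt - n1) / (nt - 1))


def fold_enrichment(observed_k: float, expected_k: float) -> float:
    """Observed over expected overlap (e.g. 2 observed / 0.0006 expected > 3000x)."""
    if expected_k <= 0:
        raise ValueError("expected_k must be positive")
    return observed_k / expected_k


def _rng(seed: int, counter: int) -> np.random.Generator:
    # one stream per replicate, derived from (seed, counter)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(counter)]))


def empirical_pair_p(
    n1: int,
    n2: int,
    observed_k: int,
    pool_size: int,
    n_rep: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Permutation null for a pairwise overlap.

    Each replicate draws n1 and n2 items independently without replacement
    from a pool of ``pool_size`` items and records their overlap.  The
    reported p is (1 + #{replicates >= observed_k}) / (n_rep + 1), so a
    finite number of permutations never yields p = 0.  Deterministic for a
    fixed seed.
    """
    if not isinstance(pool_size, (int, np.integer)):
        pool_size = len(pool_size)  # accept an explicit pool of items
    if n1 > pool_size or n2 > pool_size:
        raise ValueError("pool smaller than a trait's item count")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    counts = np.empty(n_rep, dtype=np.int64)
    for b in range(n_rep):
        rng = _rng(seed, b)
        s1 = rng.choice(pool_size, size=n1, replace=False)
        s2 = rng.choice(pool_size, size=n2, replace=False)
        counts[b] = np.intersect1d(s1, s2).size
    r = int(np.sum(counts >= observed_k))
    return PermutationNull(
        replicate_counts=counts,
        n_replicates=n_rep,
        observed=int(observed_k),
        p_value=(1 + r) / (n_rep + 1),
        seed=seed,
    )


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Bonferroni correction: p -> min(1, p*m); m defaults to len(p_values)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in p_values]


def catalog_crossphenotype_null(
    trait_sizes,
    pool_size: int,
    n_rep: int = 10000,
    observed: int = 0,
    seed: int = 0,
) -> PermutationNull:
    """Null distribution of the catalog-wide cross-phenotype item count.

    Each replicate assigns every trait a random draw of its own number of
    unique items, without replacement within the trait, from a common pool,
    then counts the items appearing in two or more traits.  The p-value for
    the observed count uses the same (1+r)/(B+1) estimator as the pairwise
    permutation.
    """
    trait_sizes = [int(s) for s in trait_sizes]
    if not isinstance(pool_size, (int, np.integer)):
        pool_size = len(pool_size)
    if any(s > pool_size for s in trait_sizes):
        raise ValueError("a trait draws more items than the pool holds")
    counts = np.empty(n_rep, dtype=np.int64)
    hits = np.zeros(pool_size, dtype=np.int32)
    for b in range(n_rep):
        rng = _rng(seed, b)
        hits[:] = 0
        for size in trait_sizes:
            hits[rng.choice(pool_size, size=size, replace=False)] += 1
        counts[b] = int(np.sum(hits >= 2))
    r = int(np.sum(counts >= observed))
    return PermutationNull(
        replicate_counts=counts,
        n_replicates=n_rep,
        observed=int(observed),
        p_value=(1 + r) / (n_rep + 1),
        seed=seed,
    )


def significant_pairs(
    profiles,
    alpha: float = 0.05,
    n_universe: int | None = None,
    with_empirical: bool = False,
    n_rep: int = 1000,
    seed: int = 0,
) -> list[PairResult]:
    """Evaluate every unordered trait pair and flag Bonferroni-significant ones.

    The Bonferroni multiplier m is the number of unordered pairs evaluated
    (all of them, not only overlapping ones — conservative).  Pairs with
    k = 0 are not reported; the returned list is sorted by p_hyper ascending
    with ties broken by (trait1, trait2).  ``n_universe`` defaults to the
    number of unique items across the profiles.
    """
    profiles = sorted(profiles, key=lambda p: p.trait)
    if len(profiles) < 2:
        return []
    if n_universe is None:
        universe: set[str] = set()
        for p in profiles:
            universe |= p.items
        n_universe = len(universe)

    m = len(profiles) * (len(profiles) - 1) // 2
    results: list[PairResult] = []
    pair_counter = 0
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            pair_counter += 1
            s = summarize_overlap(profiles[i], profiles[j])
            if s.k == 0:
                continue
            p_hyper = hypergeom_p_at_least(s.k, s.n1_unique, s.n2_unique, n_universe)
            p_bonf = min(1.0, p_hyper * m)
            p_emp = None
            if with_empirical:
                p_emp = empirical_pair_p(
                    s.n1_unique,
                    s.n2_unique,
                    s.k,
                    n_universe,
                    n_rep=n_rep,
                    seed=seed + pair_counter,
                ).p_value
            results.append(
                PairResult(
                    summary=s,
                    index_values=pair_index_values(s, n_universe=n_universe),
                    p_hyper=p_hyper,
                    p_bonferroni=p_bonf,
                    expected_k=expected_overlap(s.n1_unique, s.n2_unique, n_universe),
                    variance_k=overlap_variance(s.n1_unique, s.n2_unique, n_universe),
                    n_universe=n_universe,
                    p_empirical=p_emp,
                    significant=p_bonf < alpha,
                )
            )
    results.sort(key=lambda r: (r.p_hyper, r.trait1, r.trait2))
    return results
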