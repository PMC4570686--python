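"""Similarity indices between trait profiles.

Eleven indices are supported.  Six presence/absence indices are functions of
the shared-item count k and the per-trait unique-item counts n1, n2:

    Jaccard      S_J   = k / (n1 + n2 - k)
    Sorensen     S_s   = 2k / (n1 + n2)
    Cosine       S_C   = k / sqrt(n1 * n2)
    Simpson      S_Sim = k / min(n1, n2)
    Geometric    S_G   = k^2 / sqrt(n1 * n2)
    Pearson      S_P   = (k*n_y - n1*n2) / sqrt(n1*n2*(n_y-n1)*(n_y-n2))

where n_y is the size of the item universe.  The geometric form above is
implemented as stated even though it is not bounded by 1 (the conventional
k^2/(n1*n2) is available behind a flag).

Four abundance-based indices additionally use the report counts X_i, Y_i of
each item in the two traits (n1, n2 then denote total report counts):

    Morisita, Morisita-Horn, and the Chao-adjusted Jaccard and Sorensen
    estimators, which correct for unseen shared items through the counts of
    shared items seen exactly once or twice in each trait (f+1, f+2, f1+,
    f2+), after Chao et al.'s abundance-based approach.

The eleventh, the connection specificity index (CSI), is defined on a whole
Pearson matrix: CSI(1,2) is the fraction of all traits whose correlation with
both members of the pair falls below PCC(1,2) - epsilon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OverlapSummary",
    "PairIndexValues",
    "INDEX_NAMES",
    "SIMPLE_INDEX_NAMES",
    "summarize_overlap",
    "simple_index",
    "chao_estimators",
    "chao_index",
    "morisita_index",
    "csi_matrix",
    "pair_index_values",
    "similarity_matrix",
]

SIMPLE_INDEX_NAMES = ("jaccard", "sorensen", "cosine", "simpson", "geometric", "pearson")
INDEX_NAMES = SIMPLE_INDEX_NAMES + (
    "csi",
    "morisita",
    "morisita_horn",
    "chao_jaccard",
    "chao_sorensen",
)

#: Indices guaranteed to lie in [0, 1].
BOUNDED_INDEX_NAMES = frozenset(INDEX_NAMES) - {"geometric", "pearson"}


@dataclass(frozen=True)
class OverlapSummary:
    """Counts and f-statistics describing the overlap of two trait profiles.

    ``shared_items`` holds (item, X_i, Y_i) for each shared item, where X_i
    and Y_i are the item's report abundances in trait 1 and trait 2.  The
    f-statistics count shared items by how often they were seen: ``f_plus1``
    and ``f_plus2`` are the shared items with Y_i = 1 resp. 2 (singletons and
    doubletons in trait 2); ``f_1plus`` and ``f_2plus`` the same for X_i.
    ``s_t = n1_unique + n2_unique - k`` is the pooled unique-item count.
    """

    trait1: str
    trait2: str
    k: int
    n1_unique: int
    n2_unique: int
    n1_total: int
    n2_total: int
    shared_items: tuple[tuple[str, int, int], ...]
    f_plus1: int
    f_plus2: int
    f_1plus: int
    f_2plus: int
    # full-profile abundance sums needed by the Morisita family (sums over
    # all items of each trait; absent items would contribute 0 anyway)
    sum_x2: int = 0
    sum_y2: int = 0
    sum_x_xm1: int = 0
    sum_y_ym1: int = 0

    @property
    def s_t(self) -> int:
        return self.n1_unique + self.n2_unique - self.k


@dataclass
class PairIndexValues:
    """All eleven index values for one trait pair (csi filled matrix-wide)."""

    values: dict[str, float] = field(default_factory=dict)
    U_hat: float = 0.0
    V_hat: float = 0.0

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def summarize_overlap(profile1, profile2) -> OverlapSummary:
    """Compute the :class:`OverlapSummary` of two profiles of the same unit."""
    if profile1.unit != profile2.unit:
        raise ValueError(
            f"profiles have different units: {profile1.unit!r} vs {profile2.unit!r}"
        )
    a1, a2 = profile1.abundance, profile2.abundance
    shared = sorted(set(a1) & set(a2))
    items = tuple((s, a1[s], a2[s]) for s in shared)
    return OverlapSummary(
        trait1=profile1.trait,
        trait2=profile2.trait,
        k=len(shared),
        n1_unique=profile1.n_unique,
        n2_unique=profile2.n_unique,
        n1_total=profile1.n_total,
        n2_total=profile2.n_total,
        shared_items=items,
        f_plus1=sum(1 for _, _, y in items if y == 1),
        f_plus2=sum(1 for _, _, y in items if y == 2),
        f_1plus=sum(1 for _, x, _ in items if x == 1),
        f_2plus=sum(1 for _, x, _ in items if x == 2),
        sum_x2=sum(v * v for v in a1.values()),
        sum_y2=sum(v * v for v in a2.values()),
        sum_x_xm1=sum(v * (v - 1) for v in a1.values()),
        sum_y_ym1=sum(v * (v - 1) for v in a2.values()),
    )


_geometric_warned = False


def simple_index(
    summary: OverlapSummary,
    name: str,
    n_universe: int | None = None,
    conventional_geometric: bool = False,
) -> float:
    """Evaluate a presence/absence index on an overlap summary.

    ``n_universe`` (n_y) is required for ``pearson`` and must exceed both
    trait sizes.  ``geometric`` follows the k²/√(n1·n2) form and warns once
    when a value exceeds 1; pass ``conventional_geometric=True`` for the
    normalised k²/(n1·n2).
    """
    global _geometric_warned
    k = summary.k
    n1, n2 = summary.n1_unique, summary.n2_unique
    if n1 < 1 or n2 < 1:
        raise ValueError("simple indices need n1_unique, n2_unique >= 1")
    if name == "jaccard":
        return k / (n1 + n2 - k)
    if name == "sorensen":
        return 2 * k / (n1 + n2)
    if name == "cosine":
        return k / math.sqrt(n1 * n2)
    if name == "simpson":
        return k / min(n1, n2)
    if name == "geometric":
        if conventional_geometric:
            return k * k / (n1 * n2)
        v = k * k / math.sqrt(n1 * n2)
        if v > 1.0 and not _geometric_warned:
            _geometric_warned = True
            warnings.warn(
                "geometric index k^2/sqrt(n1*n2) exceeded 1; this form is "
                "unnormalised by design (use conventional_geometric=True for "
                "k^2/(n1*n2))",
                stacklevel=2,
            )
        return v
    if name == "pearson":
        if n_universe is None:
            raise ValueError("pearson requires n_universe (n_y)")
        if n_universe <= n1 or n_universe <= n2:
            raise ValueError(
                f"pearson requires n_universe > max(n1, n2); got {n_universe} vs ({n1}, {n2})"
            )
        num = k * n_universe - n1 * n2
        den = math.sqrt(n1 * n2 * (n_universe - n1) * (n_universe - n2))
        return num / den
    raise ValueError(f"unknown simple index {name!r}")


def chao_estimators(summary: OverlapSummary) -> tuple[float, float]:
    """Abundance-based estimates (U_hat, V_hat) of the shared report fractions.

    U_hat estimates the fraction of trait 1's reports belonging to items
    shared with trait 2; the second term extrapolates unseen shared items
    from the shared items seen only once in trait 2 (Chao et al.'s
    singleton/doubleton correction):

        U_hat = sum_shared X_i/n1
              + ((n2-1)/n2) * (f+1 / (2*f+2)) * sum_{shared, Y_i=1} X_i/n1

    with n1, n2 the total report counts, f+2 replaced by 1 when zero, and the
    whole term 0 when f+1 = 0.  V_hat is symmetric.  Both are capped at 1.
    k = 0 gives (0, 0).
    """
    if summary.k == 0:
        return 0.0, 0.0
    n1, n2 = summary.n1_total, summary.n2_total
    if n1 < 1 or n2 < 1:
        raise ValueError("chao_estimators needs positive total abundances")
    sum_x = sum(x for _, x, _ in summary.shared_items)
    sum_y = sum(y for _, _, y in summary.shared_items)
    sum_x_ysingle = sum(x for _, x, y in summary.shared_items if y == 1)
    sum_y_xsingle = sum(y for _, x, y in summary.shared_items if x == 1)

    u = sum_x / n1
    if summary.f_plus1 > 0:
        u += (
            ((n2 - 1) / n2)
            * (summary.f_plus1 / (2 * max(summary.f_plus2, 1)))
            * (sum_x_ysingle / n1)
        )
    v = sum_y / n2
    if summary.f_1plus > 0:
        v += (
            ((n1 - 1) / n1)
            * (summary.f_1plus / (2 * max(summary.f_2plus, 1)))
            * (sum_y_xsingle / n2)
        )
    return min(u, 1.0), min(v, 1.0)


def chao_index(u_hat: float, v_hat: float, variant: str = "chao_sorensen") -> float:
    """Combine (U_hat, V_hat) into the Chao-adjusted Jaccard or Sorensen index."""
    if not (0.0 <= u_hat <= 1.0 and 0.0 <= v_hat <= 1.0):
        raise ValueError("U_hat and V_hat must lie in [0, 1]")
    if u_hat == 0.0 or v_hat == 0.0:
        return 0.0
    uv = u_hat * v_hat
    if variant == "chao_jaccard":
        return uv / (u_hat + v_hat - uv)
    if variant == "chao_sorensen":
        return 2 * uv / (u_hat + v_hat)
    raise ValueError(f"unknown Chao variant {variant!r}")


def morisita_index(summary: OverlapSummary, variant: str = "morisita_horn") -> float:
    """Morisita or Morisita-Horn abundance overlap.

    Sums nominally run over all s_t pooled unique items, but items absent
    from a trait have abundance 0 and contribute nothing to the cross terms;
    per-trait squared terms run over that trait's own items.  n1, n2 are
    total report counts.  The classic Morisita form divides by n-1 and so
    requires n1_total, n2_total >= 2.
    """
    n1, n2 = summary.n1_total, summary.n2_total
    cross = sum(x * y for _, x, y in summary.shared_items)
    if cross == 0:
        return 0.0
    if variant == "morisita":
        if n1 < 2 or n2 < 2:
            raise ValueError(
                "morisita needs total abundance >= 2 in both traits "
                "(use morisita_horn for sparser profiles)"
            )
        den = (n2 / (n1 - 1)) * summary.sum_x_xm1 + (n1 / (n2 - 1)) * summary.sum_y_ym1
        if den == 0:  # every abundance is 1: the classic form is undefined
            return float("nan")
        return 2 * cross / den
    if variant == "morisita_horn":
        den = (n2 / n1) * summary.sum_x2 + (n1 / n2) * summary.sum_y2
        return 2 * cross / den
    raise ValueError(f"unknown Morisita variant {variant!r}")


def csi_matrix(pearson_matrix: pd.DataFrame, epsilon: float = 0.05) -> pd.DataFrame:
    """Connection specificity index from a trait-by-trait Pearson matrix.

    CSI(1,2) = |{t != 1,2 : PCC(t,1) < PCC(1,2)-eps and PCC(t,2) < PCC(1,2)-eps}| / N_E
    where N_E is the total number of traits.  The diagonal is set to 1.
    """
    if pearson_matrix.shape[0] != pearson_matrix.shape[1]:
        raise ValueError("pearson matrix must be square")
    traits = list(pearson_matrix.index)
    n = len(traits)
    p = pearson_matrix.to_numpy(dtype=float)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            thr = p[i, j] - epsilon
            count = 0
            for t in range(n):
                if t == i or t == j:
                    continue
                if p[t, i] < thr and p[t, j] < thr:
                    count += 1
            out[i, j] = out[j, i] = count / n
    return pd.DataFrame(out, index=traits, columns=traits)


def pair_index_values(
    summary: OverlapSummary,
    n_universe: int,
    conventional_geometric: bool = False,
) -> PairIndexValues:
    """Evaluate every per-pair index (all but CSI) on one overlap summary.

    Every index short-circuits to 0 when k = 0, except Pearson which is
    computed exactly and may be negative.
    """
    vals: dict[str, float] = {}
    for name in SIMPLE_INDEX_NAMES:
        if summary.k == 0 and name != "pearson":
            vals[name] = 0.0
        else:
            vals[name] = simple_index(
                summary, name, n_universe=n_universe,
                conventional_geometric=conventional_geometric,
            )
    u, v = chao_estimators(summary)
    vals["chao_jaccard"] = chao_index(u, v, "chao_jaccard")
    vals["chao_sorensen"] = chao_index(u, v, "chao_sorensen")
    if summary.n1_total >= 2 and summary.n2_total >= 2:
        vals["morisita"] = morisita_index(summary, "morisita")
    else:
        vals["morisita"] = float("nan")
    vals["morisita_horn"] = morisita_index(summary, "morisita_horn")
    return PairIndexValues(values=vals, U_hat=u, V_hat=v)


def similarity_matrix(
    profiles,
    index_name: str,
    n_universe: int | None = None,
    epsilon: float = 0.05,
) -> tuple[pd.DataFrame, list[OverlapSummary]]:
    """Square trait-by-trait similarity matrix for one index.

    ``n_universe`` defaults to the number of unique items across all the
    profiles.  CSI is derived from the internally computed Pearson matrix.
    The diagonal holds each index's self-similarity (1 for bounded indices).
    Returns the matrix together with the per-pair overlap summaries
    (upper-triangle order).
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    if len(profiles) < 2:
        raise ValueError("similarity_matrix needs at least 2 profiles")
    profiles = sorted(profiles, key=lambda p: p.trait)
    traits = [p.trait for p in profiles]
    if n_universe is None:
        universe: set[str] = set()
        for p in profiles:
            universe |= p.items
        n_universe = len(universe)

    base = index_name if index_name != "csi" else "pearson"
    n = len(profiles)
    mat = np.zeros((n, n))
    summaries: list[OverlapSummary] = []

    def value(s: OverlapSummary) -> float:
        if base in SIMPLE_INDEX_NAMES:
            if s.k == 0 and base != "pearson":
                return 0.0
            return simple_index(s, base, n_universe=n_universe)
        if base in ("chao_jaccard", "chao_sorensen"):
            u, v = chao_estimators(s)
            return chao_index(u, v, base)
        if base == "morisita" and (s.n1_total < 2 or s.n2_total < 2):
            return float("nan")
        return morisita_index(s, base)

    for i in range(n):
        mat[i, i] = value(summarize_overlap(profiles[i], profiles[i]))
        for j in range(i + 1, n):
            s = summarize_overlap(profiles[i], profiles[j])
            summaries.append(s)
            mat[i, j] = mat[j, i] = value(s)

    df = pd.DataFrame(mat, index=traits, columns=traits)
    if index_name == "csi":
        df = csi_matrix(df, epsilon=epsilon)
    return df, summaries
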