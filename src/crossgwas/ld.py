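"""LD clumping: merge SNPs into groups wherever pairwise r² exceeds a threshold.

The input is a pre-computed pairwise LD table in the PLINK ``.ld`` text
dialect (whitespace-delimited, header with at least SNP_A, SNP_B, R2).  SNPs
are merged transitively: groups are the connected components of the graph
whose edges are SNP pairs with r² strictly above the threshold (0.6 by
default), so two SNPs in one group need not themselves exceed the threshold —
this matches clumping practice.  Any SNP absent from the table is a singleton
group.  Which population the r² values describe (e.g. CEU) is a property of
the supplied table, not of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["LDPair", "LDGroups", "parse_ld_table", "build_groups", "ld_overlap_count"]


class LDFormatError(ValueError):
    """Raised when the LD table violates the PLINK .ld dialect."""


@dataclass(frozen=True)
class LDPair:
    snp_a: str
    snp_b: str
    r2: float


@dataclass
class LDGroups:
    """A partition of a SNP universe into LD groups.

    ``member_of`` maps each SNP in the universe to its group id, which is the
    lexicographically smallest member rsID.  SNPs outside the universe are
    treated as their own singleton group by :meth:`group_of`.
    """

    member_of: dict[str, str]
    members: dict[str, set[str]]
    r2_threshold: float
    n_ignored_pairs: int = 0

    def group_of(self, snp: str) -> str:
        return self.member_of.get(snp, snp)

    @property
    def n_groups(self) -> int:
        return len(self.members)


def parse_ld_table(path) -> list[LDPair]:
    """Read a PLINK ``.ld`` file; only SNP_A, SNP_B and R2 are consumed.

    Duplicate unordered pairs keep the maximum r²; self-pairs are dropped.
    Raises :class:`LDFormatError` for a missing column and :class:`ValueError`
    for an r² outside [0, 1], naming the offending row.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise LDFormatError(f"missing column {col!r} in LD table {path}")
    best: dict[tuple[str, str], float] = {}
    for i, (a, b, r2s) in enumerate(zip(df["SNP_A"], df["SNP_B"], df["R2"])):
        r2 = float(r2s)
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2={r2} outside [0,1] at LD table row {i + 1}")
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if r2 > best.get(key, -1.0):
            best[key] = r2
    return [LDPair(a, b, r2) for (a, b), r2 in sorted(best.items())]


def build_groups(
    pairs: list[LDPair],
    snp_universe: set[str],
    r2_threshold: float = 0.6,
) -> LDGroups:
    """Partition ``snp_universe`` into LD groups.

    Groups are connected components over edges with r² strictly greater than
    ``r2_threshold``; a pair at exactly the threshold does not merge.  Pairs
    mentioning SNPs outside the universe are ignored (counted, with a
    warning).  Output is invariant to the order of input pairs.
    """
    if not (0.0 <= r2_threshold < 1.0):
        raise ValueError(f"r2_threshold must be in [0, 1), got {r2_threshold}")
    g = nx.Graph()
    g.add_nodes_from(snp_universe)
    n_ignored = 0
    for p in pairs:
        if p.snp_a not in snp_universe or p.snp_b not in snp_universe:
            n_ignored += 1
            continue
        if p.r2 > r2_threshold:
            g.add_edge(p.snp_a, p.snp_b)
    if n_ignored:
        warnings.warn(
            f"{n_ignored} LD pairs referenced SNPs outside the universe and were ignored",
            stacklevel=2,
        )
    member_of: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for comp in nx.connected_components(g):
        gid = min(comp)
        members[gid] = set(comp)
        for snp in comp:
            member_of[snp] = gid
    return LDGroups(
        member_of=member_of,
        members=members,
        r2_threshold=r2_threshold,
        n_ignored_pairs=n_ignored,
    )


def ld_overlap_count(profile1, profile2, groups: LDGroups) -> int:
    """Number of LD groups hit by both traits (the SNP_LD overlap).

    Counts groups containing at least one SNP from each trait, so SNPs in
    high LD reported by different studies count as overlapping even when the
    exact rsIDs differ.  With all-singleton groups this equals the exact-SNP
    overlap; in general it is never smaller.
    """
    if profile1.unit != "snp" or profile2.unit != "snp":
        raise ValueError("ld_overlap_count expects unit='snp' profiles")
    g1 = {groups.group_of(s) for s in profile1.items}
    g2 = {groups.group_of(s) for s in profile2.items}
    return len(g1 & g2)
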