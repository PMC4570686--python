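"""Synthetic GWAS catalogs, LD tables, gene sets and user SNP lists.

Every generator plants known structure and returns a truth record alongside
the file it writes, so every pipeline stage can be validated end to end
without downloading real data.  Catalogs use a disjoint-block construction:
the SNPs a trait does not share with a planted partner are globally unique,
so each pair's overlap equals its planted count exactly (zero for unplanted
pairs).  Report replication follows 1 + Poisson(lambda): most associations
are reported by a single study, a minority replicated, qualitatively
matching real catalogs.  Association p-values are drawn below 1e-7 so the
threshold filter is neutral; optional decoy records with weaker p-values
exercise it.  All generators are deterministic functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticSpec",
    "generate_catalog",
    "generate_ld",
    "generate_gene_sets",
    "generate_user_list",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic catalog with planted overlap structure.

    ``planted_pairs`` holds (trait_index_i, trait_index_j, n_shared) triples;
    ``ld_group_spec`` holds (group_size, (r2_low, r2_high)) entries whose
    members are taken from the catalog's SNPs.  ``n_decoys`` plants extra
    associations with p >= 1e-7 that the threshold filter must remove.
    ``intergenic_fraction`` of SNPs map to two flanking genes.
    """

    n_traits: int = 20
    pool_size: int = 1000
    snps_per_trait: int | list[int] = 10
    planted_pairs: list[tuple[int, int, int]] = field(default_factory=list)
    abundance_lambda: float = 0.3
    ld_group_spec: list[tuple[int, tuple[float, float]]] = field(default_factory=list)
    n_decoys: int = 0
    intergenic_fraction: float = 0.0
    seed: int = 0

    @property
    def sizes(self) -> list[int]:
        if isinstance(self.snps_per_trait, int):
            return [self.snps_per_trait] * self.n_traits
        return list(self.snps_per_trait)

    def validate(self) -> None:
        sizes = self.sizes
        if len(sizes) != self.n_traits:
            raise ValueError("snps_per_trait list length must equal n_traits")
        shared_per_trait = [0] * self.n_traits
        for i, j, s in self.planted_pairs:
            if not (0 <= i < self.n_traits and 0 <= j < self.n_traits) or i == j:
                raise ValueError(f"invalid planted pair ({i}, {j})")
            if s > min(sizes[i], sizes[j]):
                raise ValueError(
                    f"planted overlap {s} exceeds a trait size for pair ({i}, {j})"
                )
            shared_per_trait[i] += s
            shared_per_trait[j] += s
        for t, tot in enumerate(shared_per_trait):
            if tot > sizes[t]:
                raise ValueError(
                    f"trait {t} has {tot} planted shared SNPs but only {sizes[t]} slots"
                )
        n_needed = sum(sizes) - sum(s for _, _, s in self.planted_pairs)
        if n_needed > self.pool_size:
            raise ValueError(
                f"pool_size {self.pool_size} too small for {n_needed} distinct SNPs"
            )
        if sum(g for g, _ in self.ld_group_spec) > self.pool_size:
            raise ValueError("LD group sizes exceed pool size")


def _trait_name(i: int) -> str:
    return f"trait_{i:03d}"


def _snp_name(i: int) -> str:
    return f"rs{i + 1:07d}"


def generate_catalog(spec: SyntheticSpec, path) -> dict:
    """Write a catalog TSV with planted overlaps; return the truth record.

    The truth record maps each trait to its SNP set and per-SNP report
    multiplicity, lists the planted pairs by trait name, and records decoy
    rows.  The same (spec, seed) always produces byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes
    pool = [_snp_name(i) for i in rng.permutation(spec.pool_size)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = pool[cursor : cursor + n]
        cursor += n
        return out

    trait_snps: dict[str, list[str]] = {_trait_name(i): [] for i in range(spec.n_traits)}
    for i, j, s in spec.planted_pairs:
        block = take(s)
        trait_snps[_trait_name(i)].extend(block)
        trait_snps[_trait_name(j)].extend(block)
    for t in range(spec.n_traits):
        name = _trait_name(t)
        trait_snps[name].extend(take(sizes[t] - len(trait_snps[name])))

    # per-SNP gene assignment, optionally intergenic (two flanking genes)
    snp_genes: dict[str, str] = {}
    for snp in sorted({s for snps in trait_snps.values() for s in snps}):
        if rng.random() < spec.intergenic_fraction:
            snp_genes[snp] = f"GL_{snp} - GR_{snp}"
        else:
            snp_genes[snp] = f"G_{snp}"

    rows: list[tuple[str, str, str, str, str]] = []
    multiplicity: dict[str, dict[str, int]] = {}
    study_counter = 0
    for trait in sorted(trait_snps):
        multiplicity[trait] = {}
        for snp in trait_snps[trait]:
            m = 1 + int(rng.poisson(spec.abundance_lambda))
            multiplicity[trait][snp] = m
            for _ in range(m):
                study_counter += 1
                p = 10.0 ** -rng.uniform(8.0, 20.0)
                rows.append((snp, trait, f"{p:.3e}", snp_genes[snp], f"{study_counter}"))

    decoys = []
    for d in range(spec.n_decoys):
        study_counter += 1
        trait = _trait_name(int(rng.integers(spec.n_traits)))
        snp = f"rsDECOY{d + 1:04d}"
        p = 10.0 ** -rng.uniform(3.0, 6.5)  # never below the 1e-7 threshold
        rows.append((snp, trait, f"{p:.3e}", f"G_{snp}", f"{study_counter}"))
        decoys.append({"snp": snp, "trait": trait, "p": f"{p:.3e}"})

    with open(path, "w") as fh:
        fh.write("SNPs\tDisease/Trait\tp-Value\tMapped_gene\tPUBMEDID\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    return {
        "traits": {t: sorted(s) for t, s in trait_snps.items()},
        "multiplicity": multiplicity,
        "planted_pairs": [
            [_trait_name(i), _trait_name(j), s] for i, j, s in spec.planted_pairs
        ],
        "snp_genes": snp_genes,
        "decoys": decoys,
        "seed": spec.seed,
    }


def generate_ld(spec: SyntheticSpec, path, snps: list[str] | None = None) -> dict:
    """Write a PLINK-dialect .ld file realising ``spec.ld_group_spec``.

    Group members are taken from ``snps`` (default: the spec's SNP pool in
    seed order).  All within-group pairs are written with r2 drawn uniformly
    from the group's range (above 0.6 by default usage); no between-group
    pairs are emitted, so the truth grouping is exactly the planted one plus
    singletons.  Returns {"groups": [[members...], ...]}.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if snps is None:
        snps = [_snp_name(i) for i in rng.permutation(spec.pool_size)]
    else:
        snps = [snps[i] for i in rng.permutation(len(snps))]
    total = sum(g for g, _ in spec.ld_group_spec)
    if total > len(snps):
        raise ValueError("LD group sizes exceed available SNPs")
    cursor = 0
    groups: list[list[str]] = []
    lines = []
    for size, (lo, hi) in spec.ld_group_spec:
        members = sorted(snps[cursor : cursor + size])
        cursor += size
        groups.append(members)
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                r2 = rng.uniform(lo, hi)
                lines.append(
                    f"1\t0\t{members[a_i]}\t1\t0\t{members[b_i]}\t{r2:.4f}"
                )
    with open(path, "w") as fh:
        fh.write("CHR_A\tBP_A\tSNP_A\tCHR_B\tBP_B\tSNP_B\tR2\n")
        for line in lines:
            fh.write(line + "\n")
    return {"groups": groups, "seed": spec.seed}


def generate_gene_sets(
    path,
    n_sets: int,
    set_size: int,
    universe: list[str],
    planted: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> dict:
    """Write a GMT file of random gene sets plus optional planted pathways.

    ``planted`` maps pathway names to gene lists included verbatim (these
    are the pathways an enrichment run should recover).  Random sets draw
    ``set_size`` genes from ``universe`` without replacement.
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    lines = []
    truth: dict[str, list[str]] = {}
    for name, genes in sorted((planted or {}).items()):
        genes = sorted(set(genes))
        truth[name] = genes
        lines.append(f"{name}\tplanted\t" + "\t".join(genes))
    for s in range(n_sets):
        name = f"RANDOM_SET_{s + 1:03d}"
        genes = sorted(rng.choice(universe, size=set_size, replace=False))
        truth[name] = list(genes)
        lines.append(f"{name}\tsynthetic random set\t" + "\t".join(genes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return {"sets": truth, "seed": seed}


def generate_user_list(
    path,
    trait_snps: list[str],
    n_snps: int,
    n_shared: int,
    seed: int = 0,
) -> dict:
    """Write a user SNP list sharing exactly ``n_shared`` rsIDs with a trait.

    Lines are "rsID<TAB>p-value".  The non-shared entries are fresh rsIDs
    absent from any catalog, so the overlap with the target trait is exactly
    ``n_shared`` and zero sharing is added elsewhere.
    """
    if n_shared > min(n_snps, len(trait_snps)):
        raise ValueError("n_shared exceeds the list size or the trait size")
    rng = np.random.default_rng(seed)
    shared = sorted(rng.choice(sorted(trait_snps), size=n_shared, replace=False))
    novel = [f"rsUSER{i + 1:05d}" for i in range(n_snps - n_shared)]
    entries = [(s, 10.0 ** -rng.uniform(8.0, 12.0)) for s in shared + novel]
    with open(path, "w") as fh:
        for snp, p in entries:
            fh.write(f"{snp}\t{p:.3e}\n")
    return {"snps": [s for s, _ in entries], "shared": shared, "seed": seed}
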