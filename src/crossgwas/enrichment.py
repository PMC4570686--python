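"""Gene-set enrichment of the genes shared by a significant trait pair.

The genes behind a pair's shared associations are tested against each gene
set of a GMT collection with the one-tailed hypergeometric (Fisher exact)
upper tail P(X >= k | N_t, n_a, n_b), where n_a is the number of shared
genes, n_b the pathway size and N_t the background gene count (default
22,836 protein-coding genes).  Only pathways actually intersecting the
shared-gene set are tested; Bonferroni correction is applied over that
number of tests, per pair.  The tail is computed by the same backend as the
pairwise overlap test.
"""

from __future__ import annotations

from dataclasses import dataclass

from .significance import hypergeom_p_at_least

__all__ = ["GeneSet", "EnrichmentResult", "parse_gmt", "enrich_shared_genes"]

#: Default background: protein-coding gene count (Ensembl v75 scale).
DEFAULT_GENE_BACKGROUND = 22836


class GMTFormatError(ValueError):
    """Raised for malformed GMT lines."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    pair: tuple[str, str]
    pathway: str
    overlap_genes: frozenset[str]
    k: int
    n_a: int
    n_b: int
    n_background: int
    p: float
    p_bonferroni: float


def parse_gmt(path) -> list[GeneSet]:
    """Read an MSigDB-style GMT file: name, description, then gene symbols.

    Genes duplicated within a line are deduplicated; lines whose gene list
    is empty after deduplication are dropped.  A line with fewer than three
    tab-separated fields raises :class:`GMTFormatError` with its line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"GMT line {lineno} has {len(fields)} fields; expected "
                    "name, description and at least one gene"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if genes:
                sets.append(GeneSet(name=name, genes=genes, source=desc))
    return sets


def enrich_shared_genes(
    shared_genes,
    collections: list[GeneSet],
    pair: tuple[str, str] = ("", ""),
    n_background: int = DEFAULT_GENE_BACKGROUND,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test a pair's shared genes against every intersecting gene set.

    Returns one result per pathway with >= 1 overlapping gene, sorted by p
    ascending (ties by pathway name); the Bonferroni multiplier is the
    number of pathways tested for this pair.
    """
    shared = set(shared_genes)
    if not shared:
        raise ValueError("shared gene set is empty")
    biggest = max((len(gs) for gs in collections), default=0)
    if n_background < biggest:
        raise ValueError("background smaller than the largest gene set")
    n_a = len(shared)
    hits = []
    for gs in collections:
        overlap = shared & gs.genes
        if overlap:
            hits.append((gs, overlap))
    m = len(hits)
    results = []
    for gs, overlap in hits:
        k, n_b = len(overlap), len(gs)
        p = hypergeom_p_at_least(k, n_a, n_b, n_background)
        results.append(
            EnrichmentResult(
                pair=pair,
                pathway=gs.name,
                overlap_genes=frozenset(overlap),
                k=k,
                n_a=n_a,
                n_b=n_b,
                n_background=n_background,
                p=p,
                p_bonferroni=min(1.0, p * m),
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway))
    return results
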