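"""Parse and curate GWAS-catalog association tables and build per-trait profiles.

The association table is the NHGRI GWAS Catalog tab-separated dialect: one row
per reported SNP-trait association, with an rsID column (possibly holding
several SNPs separated by ";"), a trait name, the reported p-value, the
catalog's mapped-gene assignment (intergenic SNPs carry both flanking genes),
and a study identifier.  Column names drift across catalog releases, so they
are configurable through :class:`CatalogDialect`.

A :class:`TraitProfile` is the multiset of analysis units (SNPs, LD groups or
genes) associated with one trait; the abundance of a unit is the number of
distinct studies reporting it, which is what the abundance-based similarity
estimators consume.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "CatalogDialect",
    "AssociationRecord",
    "ParseReport",
    "TraitProfile",
    "CATEGORY_VOCABULARY",
    "parse_catalog",
    "filter_by_pvalue",
    "curate_traits",
    "build_profiles",
    "pleiotropy_table",
]

#: The nine broad trait categories used for entropy-based cluster evaluation.
CATEGORY_VOCABULARY = frozenset(
    {
        "autoimmune",
        "infectious disease",
        "cardiovascular/metabolic",
        "body size",
        "eyes",
        "kidneys",
        "nervous system",
        "cancer",
        "others",
    }
)


class CatalogFormatError(ValueError):
    """Raised when the association table violates the expected dialect."""


@dataclass(frozen=True)
class CatalogDialect:
    """Column names and separators of the association table.

    Defaults follow the 2013-era NHGRI TSV headers.
    """

    snp_col: str = "SNPs"
    trait_col: str = "Disease/Trait"
    pvalue_col: str = "p-Value"
    gene_col: str = "Mapped_gene"
    study_col: str = "PUBMEDID"
    snp_sep: str = ";"
    intergenic_sep: str = " - "

    @property
    def required(self) -> tuple[str, ...]:
        return (self.snp_col, self.trait_col, self.pvalue_col, self.study_col)


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait-study association."""

    snp_id: str
    trait_raw: str
    p_value: float
    mapped_genes: tuple[str, ...] = ()
    study_id: str = ""
    trait_modified: str | None = None
    categories: tuple[str, ...] = ()

    @property
    def trait(self) -> str:
        """The analysis trait label: curated name when present, else raw."""
        return self.trait_modified if self.trait_modified is not None else self.trait_raw


@dataclass
class ParseReport:
    """Bookkeeping from a parse: rows kept, dropped, and why."""

    n_rows: int = 0
    n_records: int = 0
    n_dropped_pvalue: int = 0
    n_dropped_empty_snp: int = 0


@dataclass
class TraitProfile:
    """A trait's multiset of analysis units with study-level abundances."""

    trait: str
    unit: str  # "snp" | "ld_group" | "gene"
    abundance: dict[str, int] = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.abundance)

    @property
    def n_total(self) -> int:
        return sum(self.abundance.values())

    @property
    def items(self) -> set[str]:
        return set(self.abundance)


_WS = re.compile(r"\s+")


def _norm_trait(name: str) -> str:
    """Trim and collapse internal whitespace; case is preserved."""
    return _WS.sub(" ", name.strip())


def parse_catalog(
    path,
    dialect: CatalogDialect | None = None,
    category_map: dict[str, tuple[str, ...]] | None = None,
) -> tuple[list[AssociationRecord], ParseReport]:
    """Read an association table into records.

    Multi-SNP cells are split into one record per SNP (sharing trait and
    study); rows whose p-value does not parse as a positive float are dropped
    and counted in the report.  Raises :class:`CatalogFormatError` if a
    mandatory column is missing or the file is empty.
    """
    dialect = dialect or CatalogDialect()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        raise CatalogFormatError(f"empty catalog file: {path}") from None
    for col in dialect.required:
        if col not in df.columns:
            raise CatalogFormatError(f"missing mandatory column {col!r} in {path}")
    has_genes = dialect.gene_col in df.columns

    report = ParseReport(n_rows=len(df))
    records: list[AssociationRecord] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            p = float(row[dialect.pvalue_col])
        except (TypeError, ValueError):
            report.n_dropped_pvalue += 1
            continue
        if not (0.0 < p <= 1.0):
            report.n_dropped_pvalue += 1
            continue
        trait = _norm_trait(row[dialect.trait_col])
        study = str(row[dialect.study_col]).strip()
        genes: tuple[str, ...] = ()
        if has_genes:
            raw_genes = row[dialect.gene_col]
            parts = re.split(re.escape(dialect.intergenic_sep) + r"|;", raw_genes)
            genes = tuple(g.strip() for g in parts if g.strip())
        cats = tuple(category_map.get(trait, ())) if category_map else ()
        snps = [s.strip() for s in row[dialect.snp_col].split(dialect.snp_sep)]
        snps = [s for s in snps if s]
        if not snps:
            report.n_dropped_empty_snp += 1
            continue
        for snp in snps:
            records.append(
                AssociationRecord(
                    snp_id=snp,
                    trait_raw=trait,
                    p_value=p,
                    mapped_genes=genes,
                    study_id=study,
                    categories=cats,
                )
            )
    report.n_records = len(records)
    return records, report


def filter_by_pvalue(
    records: list[AssociationRecord], p_max: float = 1e-7
) -> list[AssociationRecord]:
    """Keep records with reported p strictly below ``p_max``.

    The strict inequality matches the catalog-curation rule p < 1e-7 used to
    exclude weakly supported associations.
    """
    if not (0.0 < p_max <= 1.0):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    return [r for r in records if r.p_value < p_max]


def curate_traits(
    records: list[AssociationRecord],
    merge_map: dict[str, str] | None = None,
    drop_list: set[str] | None = None,
) -> list[AssociationRecord]:
    """Merge trait subclasses and drop combined-disease labels.

    ``merge_map`` sends raw trait names to curated ("modified") names, e.g.
    several macular-degeneration subtypes to one label; traits in
    ``drop_list`` (typically labels combining multiple diseases, such as
    "Crohn's disease and celiac disease") are removed outright.  Unknown
    traits pass through with ``trait_modified`` equal to the raw name.
    """
    merge_map = {_norm_trait(k): _norm_trait(v) for k, v in (merge_map or {}).items()}
    drop = {_norm_trait(t) for t in (drop_list or set())}
    out = []
    for r in records:
        if r.trait_raw in drop:
            continue
        out.append(replace(r, trait_modified=merge_map.get(r.trait_raw, r.trait_raw)))
    return out


def build_profiles(
    records: list[AssociationRecord],
    unit: str = "snp",
    ld_groups=None,
) -> list[TraitProfile]:
    """Aggregate records into one :class:`TraitProfile` per trait.

    The abundance of an item is the number of distinct (study, item) reports
    for the trait — replication across studies, deduplicated within a study.
    ``unit``:

    * ``"snp"`` — items are rsIDs;
    * ``"ld_group"`` — items are LD-group ids (requires ``ld_groups``, an
      :class:`~crossgwas.ld.LDGroups`); a group's abundance is the sum over
      its member SNPs, preserving report counts;
    * ``"gene"`` — items are mapped-gene symbols; an intergenic record with
      two flanking genes contributes one report to each; records with no
      mapped gene are skipped.
    """
    if unit not in {"snp", "ld_group", "gene"}:
        raise ValueError(f"unknown unit {unit!r}")
    if unit == "ld_group" and ld_groups is None:
        raise ValueError("unit='ld_group' requires an LDGroups mapping")

    # distinct (study, item) pairs per trait
    seen: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for r in records:
        if unit == "gene":
            items = r.mapped_genes
        elif unit == "ld_group":
            items = (ld_groups.group_of(r.snp_id),)
        else:
            items = (r.snp_id,)
        for item in items:
            seen[r.trait].add((r.study_id, item))

    profiles = []
    for trait in sorted(seen):
        counts = Counter(item for _study, item in seen[trait])
        if counts:
            profiles.append(TraitProfile(trait=trait, unit=unit, abundance=dict(counts)))
    return profiles


def pleiotropy_table(profiles: list[TraitProfile]) -> pd.DataFrame:
    """Count, per item, the number of distinct traits it is associated with.

    Items with count >= 2 are cross-phenotype; the table is sorted by
    descending trait count (the "pleiotropic index"), then by item id.
    """
    units = {p.unit for p in profiles}
    if len(units) > 1:
        raise ValueError(f"profiles mix units: {sorted(units)}")
    counts: Counter[str] = Counter()
    for p in profiles:
        counts.update(p.items)
    df = pd.DataFrame(
        {"item": list(counts.keys()), "n_traits": list(counts.values())}
    )
    if df.empty:
        return pd.DataFrame(columns=["item", "n_traits", "cross_phenotype"])
    df["cross_phenotype"] = df["n_traits"] >= 2
    return df.sort_values(
        ["n_traits", "item"], ascending=[False, True], ignore_index=True
    )
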