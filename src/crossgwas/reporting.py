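"""Stable tabular output schemas shared by the CLI commands.

Every file starts with a single comment line recording the package version,
a hash of the run configuration, and the seeds used, so identical runs are
byte-identical and any two output files can be traced to their run.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from . import __version__
from .similarity import INDEX_NAMES

__all__ = [
    "run_header",
    "write_tsv",
    "pair_results_frame",
    "matrix_frame",
    "heterogeneity_frame",
    "permutation_frame",
    "enrichment_frame",
]


def run_header(config: dict) -> str:
    """Comment header: version, config hash, seed."""
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha1(payload.encode()).hexdigest()[:12]
    seed = config.get("seed", "none")
    return f"# crossgwas v{__version__} | config={digest} | seed={seed}\n"


def write_tsv(df: pd.DataFrame, path, config: dict, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(run_header(config))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def pair_results_frame(results, unit: str, csi: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format table of :class:`~crossgwas.significance.PairResult`."""
    rows = []
    for r in results:
        s = r.summary
        row = {
            "trait1": s.trait1,
            "trait2": s.trait2,
            "unit": unit,
            "k": s.k,
            "n1_unique": s.n1_unique,
            "n2_unique": s.n2_unique,
            "n1_total": s.n1_total,
            "n2_total": s.n2_total,
        }
        for name in INDEX_NAMES:
            if name == "csi":
                row["csi"] = (
                    float(csi.loc[s.trait1, s.trait2]) if csi is not None else float("nan")
                )
            else:
                row[name] = r.index_values[name]
        row.update(
            {
                "U_hat": r.index_values.U_hat,
                "V_hat": r.index_values.V_hat,
                "p_hyper": r.p_hyper,
                "p_empirical": r.p_empirical if r.p_empirical is not None else float("nan"),
                "p_bonferroni": r.p_bonferroni,
                "expected_k": r.expected_k,
                "fold_enrichment": r.fold_enrichment,
                "significant": r.significant,
                "shared_items": ";".join(item for item, _, _ in s.shared_items),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def matrix_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix.rename_axis("trait")


def heterogeneity_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "K": p.K,
                "entropy_kind": p.entropy_kind,
                "E_K": p.E_K,
                "E_K_weighted": p.E_K_weighted,
            }
            for p in profiles
        ]
    )


def permutation_frame(null) -> pd.DataFrame:
    """Histogram of a permutation null plus the observed count and p."""
    counts = pd.Series(null.replicate_counts).value_counts().sort_index()
    df = pd.DataFrame({"count": counts.index, "n_replicates": counts.values})
    df["observed"] = null.observed
    df["p_value"] = null.p_value
    return df


def enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait1": r.pair[0],
                "trait2": r.pair[1],
                "pathway": r.pathway,
                "k": r.k,
                "n_shared_genes": r.n_a,
                "n_pathway_genes": r.n_b,
                "p": r.p,
                "p_bonferroni": r.p_bonferroni,
                "overlap_genes": ";".join(sorted(r.overlap_genes)),
            }
            for r in results
        ]
    )
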