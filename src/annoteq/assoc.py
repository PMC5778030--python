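"""Concordance between disease-gene literature and molecular evidence.

Works on a long-format table with one row per (disease, gene) association
carrying the number of supporting publications, a standardized expression
effect size (Hedges' g) with its false-discovery rate from multi-cohort
meta-analysis, the gene's non-IEA GO annotation count, and optionally a
best SNP p-value.  The questions asked of it: do heavily published genes
rank well by molecular evidence (Spearman), and what fraction of highly
published associations replicate at a given FDR threshold?
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "ConcordanceResult",
    "read_associations",
    "write_associations",
    "rank_by_fdr",
    "filter_min_publications",
    "concordance",
    "replicated_fraction",
    "top_k_by_rank",
]

#: Canonical column order of the long-format association table.
COLUMNS = [
    "disease",
    "gene_symbol",
    "n_publications",
    "effect_size",
    "effect_fdr",
    "n_go_annotations",
    "snp_p",
]


@dataclass
class ConcordanceResult:
    """Spearman rank concordance between two association fields."""

    variable_pair: str
    spearman_rho: float
    p_value: float
    n_pairs: int
    filter_applied: str = ""

    def to_dict(self) -> dict:
        return {
            "variable_pair": self.variable_pair,
            "spearman_rho": self.spearman_rho,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "filter_applied": self.filter_applied,
        }


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["disease"] = df["disease"].astype(str).str.strip().str.lower()
    df["gene_symbol"] = df["gene_symbol"].astype(str).str.strip().str.upper()
    return df


def read_associations(source) -> pd.DataFrame:
    """Read a long-format association TSV (missing values as empty fields).

    Disease and gene identifiers are case-normalised so joins across sources
    are exact string matches.
    """
    df = pd.read_csv(source, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    missing = {"disease", "gene_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"association table lacks columns: {sorted(missing)}")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return _normalise(df)


def write_associations(df: pd.DataFrame, path_or_buf) -> None:
    cols = [c for c in COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in COLUMNS
    ]
    df[cols].to_csv(path_or_buf, sep="\t", index=False)


def rank_by_fdr(df: pd.DataFrame, per_disease: bool = True) -> pd.DataFrame:
    """Assign ascending ``fdr_rank`` by effect FDR, ties averaged.

    Rows without an FDR are excluded (and logged).  Ranking is within each
    disease by default.
    """
    n_missing = int(df["effect_fdr"].isna().sum())
    if n_missing:
        logger.info("rank_by_fdr: excluding %d row(s) without effect_fdr", n_missing)
    out = df[df["effect_fdr"].notna()].copy()
    if per_disease:
        out["fdr_rank"] = out.groupby("disease")["effect_fdr"].rank(method="average")
    else:
        out["fdr_rank"] = out["effect_fdr"].rank(method="average")
    return out


def filter_min_publications(df: pd.DataFrame, min_pubs: int = 10) -> pd.DataFrame:
    """Keep associations with at least `min_pubs` supporting publications."""
    return df[df["n_publications"] >= min_pubs].copy()


def concordance(
    df: pd.DataFrame,
    x_field: str,
    y_field: str,
    method: str = "asymptotic",
    n_permutations: int = 10000,
    seed: int | None = None,
    filter_applied: str = "",
) -> ConcordanceResult:
    """Spearman rank correlation between two fields, pairwise-complete.

    `method` is ``asymptotic`` (large-sample t approximation) or
    ``permutation`` (seeded two-sided permutation p, for small n).
    """
    sub = df[[x_field, y_field]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"fewer than 3 complete pairs for {x_field} vs {y_field}")
    x = sub[x_field].to_numpy(dtype=float)
    y = sub[y_field].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, y)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            r_perm, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    elif method != "asymptotic":
        raise ValueError(f"unknown p-value method: {method!r}")
    return ConcordanceResult(
        variable_pair=f"{x_field}:{y_field}",
        spearman_rho=float(rho),
        p_value=float(p),
        n_pairs=n,
        filter_applied=filter_applied,
    )


def replicated_fraction(
    df: pd.DataFrame, fdr_threshold: float = 0.05, inclusive: bool = False
) -> float:
    """Fraction of associations whose expression FDR clears the threshold.

    Strict ``effect_fdr < threshold`` by default (set `inclusive` for <=).
    The input should already be publication-filtered; rows without an FDR
    are excluded from both numerator and denominator.
    """
    sub = df[df["effect_fdr"].notna()]
    if len(sub) == 0:
        raise ValueError("no associations with an effect FDR")
    if inclusive:
        return float((sub["effect_fdr"] <= fdr_threshold).mean())
    return float((sub["effect_fdr"] < fdr_threshold).mean())


def top_k_by_rank(df: pd.DataFrame, k: int = 10000) -> pd.DataFrame:
    """Per disease, keep the k best-FDR-ranked associations (plot export only;
    correlation calculations use the unrestricted table)."""
    if "fdr_rank" not in df.columns:
        raise ValueError("assign fdr_rank before top_k_by_rank")
    return df[df["fdr_rank"] <= k].copy()
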