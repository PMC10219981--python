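"""Stage 5: gene essentiality versus enhancer co-activity.

Joins per-gene co-activity summaries (observed combinations, significant
pairs, total nearby enhancers) with per-gene constraint scores — LOEUF
(lower = stronger selective constraint) and the enhancer-domain score
(higher = more redundant regulatory architecture) — and reports Spearman
correlations for every feature x score combination, dropping genes without
a score pairwise per correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import assoc_stats as ast

logger = logging.getLogger("coact")

FEATURES = ["n_observed_combinations", "n_significant_pairs", "n_nearby_enhancers"]
SCORES = ["loeuf", "eds"]


def read_score_table(path, score_col: str) -> pd.DataFrame:
    """Read a gene_id -> score TSV (header required); duplicate gene ids
    are an input error."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or score_col not in df.columns:
        raise ValueError(f"{path}: expected columns gene_id and {score_col}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise ValueError(f"{path}: duplicate gene_id entries, e.g. {dups}")
    return df[["gene_id", score_col]]


def build_gene_summaries(
    combination_summaries: pd.DataFrame,
    pair_records: pd.DataFrame,
    cis_pairs: pd.DataFrame,
    loeuf: pd.DataFrame | None = None,
    eds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per gene with >= 1 significantly associated enhancer.

    ``cis_pairs`` (stage-0 gene x cis-enhancer table) provides
    ``n_nearby_enhancers`` regardless of association significance; the
    combination summary provides observed-combination counts; pair records
    provide significant-pair counts.  Score tables join by ``gene_id``;
    genes missing from a table keep NaN and drop out of that score's
    correlation only.
    """
    for tbl, col in ((loeuf, "loeuf"), (eds, "eds")):
        if tbl is not None and tbl["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene_id in {col} score table")
    out = combination_summaries[
        ["gene_id", "n_observed", "n_significant_pairs"]
    ].rename(columns={"n_observed": "n_observed_combinations"})
    nearby = cis_pairs.groupby("gene_id").size().rename("n_nearby_enhancers")
    out = out.merge(nearby, on="gene_id", how="left")
    out["n_nearby_enhancers"] = out["n_nearby_enhancers"].fillna(0).astype(int)
    if not pair_records.empty:
        sig_pairs = (
            pair_records[pair_records["significant"].astype(bool)]
            .groupby("gene_id")
            .size()
            .rename("n_significant_pairs_check")
        )
        out = out.merge(sig_pairs, on="gene_id", how="left")
        out["n_significant_pairs"] = (
            out["n_significant_pairs"].fillna(out["n_significant_pairs_check"]).fillna(0)
        )
        out = out.drop(columns="n_significant_pairs_check")
    out["n_significant_pairs"] = out["n_significant_pairs"].fillna(0).astype(int)
    if loeuf is not None:
        out = out.merge(loeuf, on="gene_id", how="left")
        n_miss = int(out["loeuf"].isna().sum())
        if n_miss:
            logger.info("build_gene_summaries: %d genes without LOEUF", n_miss)
    if eds is not None:
        out = out.merge(eds, on="gene_id", how="left")
    return out


def essentiality_correlations(summaries: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each co-activity feature with each score.

    Returns a tidy frame (feature, score, spearman_r, p, n); undefined
    correlations (constant feature, < 3 scored genes) are NaN-flagged.
    """
    rows = []
    for score in SCORES:
        if score not in summaries.columns:
            continue
        for feature in FEATURES:
            if feature not in summaries.columns:
                continue
            sub = summaries[[feature, score]].dropna()
            n = len(sub)
            if n < 3 or sub[feature].nunique() < 2 or sub[score].nunique() < 2:
                rows.append((feature, score, np.nan, np.nan, n))
                continue
            r, p = ast.spearman(sub[feature].to_numpy(), sub[score].to_numpy())
            rows.append((feature, score, r, p, n))
    return pd.DataFrame(rows, columns=["feature", "score", "spearman_r", "p", "n"])
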