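"""Stage 2: gene-centric enhancer-enhancer co-activity.

For each gene with at least two significantly associated enhancers and at
least ``min_cells`` expressing cells, every unordered pair of its
associated enhancers is correlated across the cells expressing the gene.
Partial correlation conditioning on gene expression is computed across
*all* cells — within the expressing-cell background the binarised gene
vector is constant-1 and carries no variance to condition on.

p-values for pair tests default to the analytic two-sided t transform;
a permutation mode (shuffling the first enhancer's activity) is available
for users who want the same null construction as stage 1.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from . import assoc_stats as ast
from . import genomic_io as gio
from .genomic_io import BinaryCellMatrix

logger = logging.getLogger("coact")

PAIR_COLUMNS = [
    "gene_id",
    "enhancer_a",
    "enhancer_b",
    "n_cells",
    "r",
    "p",
    "q",
    "significant",
    "pair_distance_bp",
]


def expressing_cells(
    expr: BinaryCellMatrix, gene_id: str, min_cells: int = 100
) -> np.ndarray:
    """Boolean mask of cells with non-zero binarised expression of the gene.

    Returns the mask regardless of size; genes expressed in fewer than
    ``min_cells`` cells (strictly less — a gene at exactly the threshold is
    retained) are the caller's responsibility to exclude.
    """
    mask = expr.column(gene_id).astype(bool)
    if mask.sum() < min_cells:
        logger.info(
            "gene %s expressed in %d cells (< %d)", gene_id, int(mask.sum()), min_cells
        )
    return mask


def _midpoint_of(enhancer_id: str) -> int:
    return gio.parse_interval_name(enhancer_id).midpoint


def _pair_distance(a: str, b: str) -> int:
    ia = gio.parse_interval_name(a)
    ib = gio.parse_interval_name(b)
    if ia.chrom != ib.chrom:
        return -1
    return abs(ia.midpoint - ib.midpoint)


def _correlate_gene_pairs(
    expr: BinaryCellMatrix,
    enh: BinaryCellMatrix,
    gene_to_enhancers: dict[str, list[str]],
    min_cells: int,
    permute: int | None,
    seed: int,
) -> tuple[pd.DataFrame, list[str]]:
    rows = []
    skipped_genes: list[str] = []
    gene_order = {g: i for i, g in enumerate(sorted(gene_to_enhancers))}
    for gene_id in sorted(gene_to_enhancers):
        enh_ids = sorted(gene_to_enhancers[gene_id])
        if len(enh_ids) < 2:
            continue
        mask = expressing_cells(expr, gene_id, min_cells)
        n_cells = int(mask.sum())
        if n_cells < min_cells:
            skipped_genes.append(gene_id)
            continue
        M = enh.columns(enh_ids)[mask]
        R = ast.pairwise_binary_pearson(M)
        if permute:
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(gene_order[gene_id],))
            )
        for i, j in combinations(range(len(enh_ids)), 2):
            r = R[i, j]
            if not np.isfinite(r):
                p = np.nan
            elif permute:
                p = ast.permutation_pvalue(M[:, i], M[:, j], permute, rng)
            else:
                p = float(ast.analytic_pvalues(r, n_cells))
            rows.append(
                (
                    gene_id,
                    enh_ids[i],
                    enh_ids[j],
                    n_cells,
                    float(r),
                    p,
                    _pair_distance(enh_ids[i], enh_ids[j]),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "enhancer_a",
            "enhancer_b",
            "n_cells",
            "r",
            "p",
            "pair_distance_bp",
        ],
    )
    return df, skipped_genes


def _finalize(df: pd.DataFrame, q_max: float, r_min: float) -> pd.DataFrame:
    if df.empty:
        df = df.reindex(columns=PAIR_COLUMNS)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df = df.copy()
    df["q"] = ast.bh_fdr(df["p"].to_numpy())
    df["significant"] = (df["q"] < q_max) & (df["r"].abs() > r_min)
    df["significant"] = df["significant"].fillna(False)
    return df[PAIR_COLUMNS + [c for c in df.columns if c not in PAIR_COLUMNS]]


def pair_scan(
    expr: BinaryCellMatrix,
    enh: BinaryCellMatrix,
    associations: pd.DataFrame,
    min_cells: int = 100,
    q_max: float = 0.05,
    r_min: float = 0.05,
    permute: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate all pairs of associated enhancers per gene.

    ``associations`` is stage-1 output (or an external table with the same
    schema); only rows flagged significant enter.  Emits exactly
    ``sum_g C(k_g, 2)`` records over genes passing the expressing-cell
    filter, with BH q-values pooled over every pair test.
    """
    sig = associations[associations["significant"].astype(bool)]
    gene_to_enh = {g: list(grp["enhancer_id"]) for g, grp in sig.groupby("gene_id")}
    df, skipped = _correlate_gene_pairs(expr, enh, gene_to_enh, min_cells, permute, seed)
    out = _finalize(df, q_max, r_min)
    out.attrs["skipped_low_cell_genes"] = skipped
    return out


def baseline_pair_scan(
    expr: BinaryCellMatrix,
    enh: BinaryCellMatrix,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    associations: pd.DataFrame,
    window: int = 1_000_000,
    min_cells: int = 100,
    q_max: float = 0.05,
    r_min: float = 0.05,
    max_tests: int = 5_000_000,
) -> pd.DataFrame:
    """Pair scan over *all* cis enhancers of each gene (association-agnostic
    baseline).

    Each record carries ``n_associated`` (0, 1 or 2): how many of the two
    enhancers are significantly associated with the gene, partitioning
    pairs into neither/one/both-associated classes.
    """
    enh_df = enhancers.reset_index(drop=True).copy()
    enh_df["name"] = gio.interval_names(enh_df)
    enh_df = enh_df[enh_df["name"].isin(set(enh.feature_ids))].reset_index(drop=True)
    genes_in = genes[genes["gene_id"].isin(set(expr.feature_ids))]
    cis = gio.cis_window_pairs(genes_in, enh_df, window)
    gene_to_enh = {
        g: list(enh_df["name"].iloc[grp["enhancer_index"]])
        for g, grp in cis.groupby("gene_id")
    }
    n_tests = sum(len(v) * (len(v) - 1) // 2 for v in gene_to_enh.values())
    if n_tests > max_tests:
        raise ValueError(
            f"baseline scan would run {n_tests} tests (cap {max_tests}); "
            "raise max_tests explicitly to proceed"
        )
    df, skipped = _correlate_gene_pairs(expr, enh, gene_to_enh, min_cells, None, 0)
    sig = associations[associations["significant"].astype(bool)]
    assoc_set = set(zip(sig["gene_id"], sig["enhancer_id"]))
    df["n_associated"] = [
        int((g, a) in assoc_set) + int((g, b) in assoc_set)
        for g, a, b in zip(df["gene_id"], df["enhancer_a"], df["enhancer_b"])
    ]
    out = _finalize(df, q_max, r_min)
    out.attrs["skipped_low_cell_genes"] = skipped
    return out


def partial_scan(
    expr_all: BinaryCellMatrix,
    enh_all: BinaryCellMatrix,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Fill ``r_partial``/``p_partial``/``q_partial`` for pair records.

    Correlations are taken across *all* cells; conditioning is on the
    gene's binarised expression.  Degenerate conditioning (constant gene,
    perfect gene-enhancer correlation) flags the record (NaN + ``partial_
    undefined``) without aborting the scan.
    """
    if pairs.empty:
        out = pairs.copy()
        for c in ("r_partial", "p_partial", "q_partial"):
            out[c] = pd.Series(dtype=float)
        out["partial_undefined"] = pd.Series(dtype=bool)
        return out
    n = expr_all.n_cells
    r_partials = np.full(len(pairs), np.nan)
    for gene_id, grp in pairs.groupby("gene_id"):
        x = expr_all.column(gene_id).astype(np.float64)
        enh_ids = sorted(set(grp["enhancer_a"]) | set(grp["enhancer_b"]))
        M = enh_all.columns(enh_ids).astype(np.float64)
        idx = {e: i for i, e in enumerate(enh_ids)}
        r_with_gene = ast.binary_pearson_vec(x, M)
        R = ast.pairwise_binary_pearson(M)
        for row, (a, b) in zip(grp.index, zip(grp["enhancer_a"], grp["enhancer_b"])):
            ia, ib = idx[a], idx[b]
            r_partials[pairs.index.get_loc(row)] = ast.partial_from_marginals(
                R[ia, ib], r_with_gene[ia], r_with_gene[ib]
            )
    out = pairs.copy()
    out["r_partial"] = r_partials
    out["p_partial"] = ast.analytic_pvalues(r_partials, n, df_offset=3)
    out["q_partial"] = ast.bh_fdr(out["p_partial"].to_numpy())
    out["partial_undefined"] = ~np.isfinite(r_partials)
    return out


def combination_summary(
    expr: BinaryCellMatrix,
    enh: BinaryCellMatrix,
    associations: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    min_cells: int = 100,
) -> pd.DataFrame:
    """Per-gene enumeration of observed enhancer-activity combinations.

    For a gene with k associated enhancers there are ``2^k - 1`` possible
    non-empty activity patterns; a pattern counts as observed when at least
    one gene-expressing cell exhibits exactly it.  Patterns are collected
    as integer bit-sets over the k enhancers (k <= 62 enforced), so counting
    never enumerates the full pattern space.
    """
    sig = associations[associations["significant"].astype(bool)]
    sig_pairs = None
    if pairs is not None and not pairs.empty:
        sig_pairs = pairs[pairs["significant"].astype(bool)].groupby("gene_id").size()
    rows = []
    for gene_id, grp in sig.groupby("gene_id"):
        enh_ids = sorted(grp["enhancer_id"])
        k = len(enh_ids)
        if k > 62:
            raise ValueError(f"gene {gene_id}: k={k} exceeds the 62-enhancer bit-set width")
        mask = expressing_cells(expr, gene_id, min_cells)
        if mask.sum() < min_cells:
            continue
        M = enh.columns(enh_ids)[mask].astype(np.uint64)
        codes = M @ (np.uint64(1) << np.arange(k, dtype=np.uint64))
        observed = np.unique(codes[codes > 0])
        n_possible = (1 << k) - 1
        rows.append(
            (
                gene_id,
                k,
                n_possible,
                int(observed.size),
                100.0 * observed.size / n_possible,
                k * (k - 1) // 2,
                int(sig_pairs.get(gene_id, 0)) if sig_pairs is not None else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "k",
            "n_possible",
            "n_observed",
            "pct_observed",
            "n_possible_pairs",
            "n_significant_pairs",
        ],
    )


def enhancer_centric_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Group pair records by unordered enhancer pair across genes and count
    in how many genes each pair was tested / significant."""
    if pairs.empty:
        return pd.DataFrame(
            columns=["enhancer_a", "enhancer_b", "n_genes_tested", "n_genes_significant", "fraction_significant"]
        )
    grp = pairs.groupby(["enhancer_a", "enhancer_b"])
    out = grp.agg(
        n_genes_tested=("gene_id", "nunique"),
        n_genes_significant=("significant", "sum"),
    ).reset_index()
    out["n_genes_significant"] = out["n_genes_significant"].astype(int)
    out["fraction_significant"] = out["n_genes_significant"] / out["n_genes_tested"]
    return out
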