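"""Stage 1: gene-enhancer association scan.

For every gene, enhancers whose midpoint lies within the cis window
(default +/- 1 Mb) of the TSS are tested for association with the gene's
binarised expression across *all* shared cells using Pearson correlation
(the phi coefficient on binary data).  Significance comes from a
permutation null (the gene-expression vector is shuffled ``n_perm`` times),
Benjamini-Hochberg correction over all cis tests pooled, and a correlation
cutoff.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import assoc_stats as ast
from . import genomic_io as gio
from .genomic_io import BinaryCellMatrix

logger = logging.getLogger("coact")

ASSOCIATION_COLUMNS = [
    "gene_id",
    "enhancer_id",
    "r",
    "p_empirical",
    "q",
    "significant",
    "distance_bp",
]


def map_peaks_to_enhancers(
    peak_matrix: BinaryCellMatrix,
    peaks: pd.DataFrame,
    enhancers: pd.DataFrame,
    min_fraction: float = 0.5,
) -> BinaryCellMatrix:
    """Collapse an ATAC peak matrix to enhancer-level activity.

    A peak maps to an enhancer when >= ``min_fraction`` of the peak lies
    inside it (bedtools ``-F`` semantics); an enhancer is active in a cell
    iff any mapped peak is (union rule).  Enhancers without a mapped peak
    are dropped.
    """
    if len(peaks) != peak_matrix.n_features:
        raise ValueError(
            f"peak interval list ({len(peaks)}) does not match matrix features "
            f"({peak_matrix.n_features})"
        )
    enh = enhancers.reset_index(drop=True)
    hits = gio.overlap_fraction(peaks, enh, min_fraction)
    if hits.empty:
        logger.warning("map_peaks_to_enhancers: no peak maps to any enhancer")
        return BinaryCellMatrix(
            peak_matrix.cell_ids,
            np.array([], dtype=object),
            np.zeros((peak_matrix.n_cells, 0)),
        )
    names = gio.interval_names(enh)
    cols = []
    kept = []
    for t_idx, grp in hits.groupby("target_index"):
        peak_cols = peak_matrix.X[:, grp["query_index"].to_numpy()]
        merged = (peak_cols.sum(axis=1) > 0).astype(np.uint8)
        cols.append(np.asarray(merged).ravel())
        kept.append(names.iloc[t_idx])
    X = np.column_stack(cols)
    return BinaryCellMatrix(peak_matrix.cell_ids, np.asarray(kept, dtype=object), X)


def scan_gene_enhancer(
    expr: BinaryCellMatrix,
    enh: BinaryCellMatrix,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    q_max: float = 0.05,
    r_min: float = 0.05,
    two_sided_r: bool = True,
) -> pd.DataFrame:
    """Run the cis association scan and return one row per tested pair.

    ``enhancers`` must carry the coordinates of every feature in ``enh``
    (matched by ``chrom:start-end`` name).  Permutation seeds are derived
    per gene from ``seed`` so results do not depend on iteration order.
    ``two_sided_r=True`` applies the correlation cutoff on ``|r|``; with
    ``False`` only positive correlations can be significant.

    Genes or enhancers that are constant across cells are skipped (counted
    in the returned frame's ``attrs['n_skipped_constant']``), never scored
    as r = 0.
    """
    if not np.array_equal(expr.cell_ids, enh.cell_ids):
        raise ValueError("expression and enhancer matrices have different cell sets")
    enh_df = enhancers.reset_index(drop=True).copy()
    enh_df["name"] = gio.interval_names(enh_df)
    present = enh_df["name"].isin(set(enh.feature_ids))
    enh_df = enh_df[present].reset_index(drop=True)
    genes_in = genes[genes["gene_id"].isin(set(expr.feature_ids))].reset_index(drop=True)
    cis = gio.cis_window_pairs(genes_in, enh_df, window)

    rows = []
    n_skipped = 0
    root = np.random.SeedSequence(seed)
    gene_order = {g: i for i, g in enumerate(genes_in["gene_id"])}
    for gene_id, grp in cis.groupby("gene_id", sort=False):
        x = expr.column(gene_id)
        names = enh_df["name"].iloc[grp["enhancer_index"]].to_numpy()
        Y = enh.columns(names)
        r = ast.binary_pearson_vec(x, Y)
        if np.all(~np.isfinite(r)):
            n_skipped += len(names)
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(gene_order[gene_id],))
        )
        p = ast.permutation_pvalues_matrix(x, Y, n_perm, rng)
        for name, ri, pi, dist in zip(names, r, p, grp["distance_bp"]):
            if not np.isfinite(ri):
                n_skipped += 1
                continue
            rows.append((gene_id, name, float(ri), float(pi), int(dist)))
    out = pd.DataFrame(rows, columns=["gene_id", "enhancer_id", "r", "p_empirical", "distance_bp"])
    if out.empty:
        out = out.reindex(columns=ASSOCIATION_COLUMNS)
        out.attrs["n_skipped_constant"] = n_skipped
        logger.warning("scan_gene_enhancer: no testable cis pairs")
        return out
    out["q"] = ast.bh_fdr(out["p_empirical"].to_numpy())
    effect = out["r"].abs() if two_sided_r else out["r"]
    out["significant"] = (out["q"] < q_max) & (effect > r_min)
    out = out[ASSOCIATION_COLUMNS]
    out.attrs["n_skipped_constant"] = n_skipped
    return out


def read_association_table(path) -> pd.DataFrame:
    """Load an externally produced association table (same schema as
    :func:`scan_gene_enhancer` output), e.g. published gene-enhancer links
    used as stage-1 input."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ASSOCIATION_COLUMNS) - set(df.columns)
    if missing - {"p_empirical", "q", "distance_bp"}:
        raise ValueError(f"association table {path} missing columns: {sorted(missing)}")
    return df
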