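"""Genomic interval handling and matrix/annotation I/O.

Conventions
-----------
All intervals are 0-based half-open (``[start, end)``), matching BED and
bedtools semantics.  GTF input (1-based inclusive) is converted on read.
Interval sets are carried as :class:`pandas.DataFrame` objects with at least
``chrom``, ``start`` and ``end`` columns; scalar records use the
:class:`GenomicInterval` and :class:`GeneModel` dataclasses.

Binary single-cell matrices (cells x features, values in {0, 1}) are wrapped
in :class:`BinaryCellMatrix`, a thin container over a ``scipy.sparse`` CSC
matrix with aligned barcode and feature identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("coact")

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23)) | frozenset(
    str(i) for i in range(1, 23)
)

#: MHC region excluded from gene models (hg19 coordinates).
MHC_REGION = ("chr6", 29_500_000, 33_600_000)

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class ParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene-level record with a stable identifier and strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


def tss(gene) -> int:
    """Strand-aware transcription start site of a gene-level record.

    ``+`` strand genes start transcription at ``start``; ``-`` strand genes
    at ``end - 1`` (0-based position of the first transcribed base).
    """
    strand = gene.strand if hasattr(gene, "strand") else gene["strand"]
    if strand == "+":
        return int(gene.start if hasattr(gene, "start") else gene["start"])
    if strand == "-":
        return int(gene.end if hasattr(gene, "end") else gene["end"]) - 1
    raise ValueError(f"cannot define a TSS for strand {strand!r}")


def tss_positions(genes: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`tss` over a gene-model frame."""
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} genes with undefined strand")
    return np.where(
        genes["strand"].to_numpy() == "+",
        genes["start"].to_numpy(),
        genes["end"].to_numpy() - 1,
    )


def midpoints(intervals: pd.DataFrame) -> np.ndarray:
    return (intervals["start"].to_numpy() + intervals["end"].to_numpy()) // 2


# ---------------------------------------------------------------------------
# Annotation readers / writers
# ---------------------------------------------------------------------------


def read_gene_models(
    path: str | Path,
    allowed_biotypes: Iterable[str] = ("protein_coding",),
    excluded_regions: Sequence[tuple[str, int, int]] = (MHC_REGION,),
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Read gene-level records from a Gencode-dialect GTF.

    Keeps genes with a biotype in ``allowed_biotypes``, drops non-autosomal
    genes when ``autosomes_only`` and genes overlapping any of
    ``excluded_regions`` (by default the MHC region, whose dense linkage and
    gene clustering distort cis association scans).

    Returns a frame with columns ``gene_id, chrom, start, end, strand,
    biotype``, ordered by ``(chrom, start, gene_id)``.
    """
    import pyranges as pr

    try:
        gr = pr.read_gtf(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ParseError(f"failed to parse GTF {path}: {exc}") from exc
    df = gr.df
    if "Feature" not in df.columns or "gene_id" not in df.columns:
        raise ParseError(f"{path}: not a Gencode-style GTF (missing gene_id)")
    df = df[df["Feature"] == "gene"].copy()
    biotype_col = "gene_type" if "gene_type" in df.columns else "gene_biotype"
    if biotype_col not in df.columns:
        raise ParseError(f"{path}: no gene_type/gene_biotype attribute")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(np.int64),
            "end": df["End"].astype(np.int64),
            "strand": df["Strand"].astype(str),
            "biotype": df[biotype_col].astype(str),
        }
    )
    out = out[out["biotype"].isin(set(allowed_biotypes))]
    if autosomes_only:
        out = out[out["chrom"].isin(AUTOSOMES)]
    for chrom, start, end in excluded_regions:
        hit = (out["chrom"] == chrom) & (out["start"] < end) & (out["end"] > start)
        out = out[~hit]
    out = out.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)
    if out.empty:
        logger.warning("read_gene_models(%s): zero genes after filtering", path)
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/4/6 file into an interval frame (extra columns kept)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [
        f"col{i}" for i in range(len(names), df.shape[1])
    ]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).sum())
        raise ParseError(f"{path}: {bad} intervals with start >= end")
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def interval_names(intervals: pd.DataFrame) -> pd.Series:
    """``chrom:start-end`` identifiers (the pipeline's enhancer ids)."""
    return (
        intervals["chrom"].astype(str)
        + ":"
        + intervals["start"].astype(str)
        + "-"
        + intervals["end"].astype(str)
    )


def parse_interval_name(name: str) -> GenomicInterval:
    chrom, rest = name.rsplit(":", 1)
    start, end = rest.split("-")
    return GenomicInterval(chrom, int(start), int(end))


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------


def merge_bookended(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping *or abutting* intervals per chromosome.

    Matches ``bedtools merge`` with default parameters: intervals with
    ``end_i == start_j`` (book-ended) are joined.  Output is sorted and
    neither overlapping nor abutting.
    """
    if intervals.empty:
        return intervals[INTERVAL_COLUMNS].copy()
    out_rows = []
    df = intervals.sort_values(["chrom", "start", "end"])
    for chrom, grp in df.groupby("chrom", sort=True, observed=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out_rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out_rows, columns=INTERVAL_COLUMNS)


def overlap_fraction(
    queries: pd.DataFrame, targets: pd.DataFrame, min_fraction: float
) -> pd.DataFrame:
    """Map each query interval to targets covering >= ``min_fraction`` of it.

    Implements ``bedtools intersect -F`` semantics: a query maps to a target
    iff the overlap length is at least ``min_fraction`` times the *query*
    length.  A query may map to several targets.

    Returns a frame with columns ``query_index, target_index`` (positional
    indices into the input frames).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    q = queries.reset_index(drop=True)
    t = targets.reset_index(drop=True)
    hits_q: list[int] = []
    hits_t: list[int] = []
    t_by_chrom = {c: g for c, g in t.groupby("chrom", observed=True)}
    for chrom, qg in q.groupby("chrom", observed=True):
        tg = t_by_chrom.get(chrom)
        if tg is None:
            continue
        qs = qg["start"].to_numpy()[:, None]
        qe = qg["end"].to_numpy()[:, None]
        ts = tg["start"].to_numpy()[None, :]
        te = tg["end"].to_numpy()[None, :]
        ov = np.minimum(qe, te) - np.maximum(qs, ts)
        need = min_fraction * (qe - qs)
        # strict bedtools -F: overlap must reach the fraction exactly
        qi, ti = np.nonzero(ov >= need)
        hits_q.extend(qg.index.to_numpy()[qi])
        hits_t.extend(tg.index.to_numpy()[ti])
    out = pd.DataFrame({"query_index": hits_q, "target_index": hits_t})
    return out.sort_values(["query_index", "target_index"]).reset_index(drop=True)


def contained_overlap(queries: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Full-containment mapping (``bedtools intersect -F1``)."""
    return overlap_fraction(queries, targets, 1.0)


def cis_window_pairs(
    genes: pd.DataFrame, enhancers: pd.DataFrame, window: int
) -> pd.DataFrame:
    """All (gene, enhancer) pairs with the enhancer midpoint within
    ``window`` bp of the gene TSS on the same chromosome (boundary
    inclusive).

    Returns columns ``gene_id, enhancer_index, distance_bp`` where
    ``distance_bp = midpoint - TSS`` (signed) and ``enhancer_index`` is the
    positional index into ``enhancers``; ordered by (gene order, enhancer
    position).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    enh = enhancers.reset_index(drop=True)
    mids = midpoints(enh)
    rows = []
    enh_by_chrom = {
        c: (g.index.to_numpy(), mids[g.index.to_numpy()])
        for c, g in enh.groupby("chrom", observed=True)
    }
    gene_tss = tss_positions(genes)
    for (pos, gene), t0 in zip(genes.reset_index(drop=True).iterrows(), gene_tss):
        got = enh_by_chrom.get(gene["chrom"])
        if got is None:
            continue
        idx, m = got
        d = m.astype(np.int64) - int(t0)
        keep = np.abs(d) <= window
        order = np.argsort(m[keep], kind="stable")
        for i, dist in zip(idx[keep][order], d[keep][order]):
            rows.append((gene["gene_id"], int(i), int(dist)))
    return pd.DataFrame(rows, columns=["gene_id", "enhancer_index", "distance_bp"])


# ---------------------------------------------------------------------------
# Binary cell matrix
# ---------------------------------------------------------------------------


@dataclass
class BinaryCellMatrix:
    """Cells x features 0/1 activity matrix with aligned identifiers.

    ``X`` is stored sparse (CSC, uint8); iteration over non-zeros never
    densifies the full matrix.
    """

    cell_ids: np.ndarray
    feature_ids: np.ndarray
    X: sp.csc_matrix
    _feature_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.X = sp.csc_matrix(self.X, dtype=np.uint8)
        if self.X.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids are not unique")
        if self.X.nnz and self.X.data.max() > 1:
            raise ValueError("matrix is not binary; call binarize() on counts")
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def column(self, feature_id: str) -> np.ndarray:
        """Dense 0/1 vector over cells for one feature."""
        try:
            j = self._feature_index[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return np.asarray(self.X[:, j].todense(), dtype=np.uint8).ravel()

    def columns(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Dense cells x k block for a small set of features."""
        js = [self._feature_index[f] for f in feature_ids]
        return np.asarray(self.X[:, js].todense(), dtype=np.uint8)

    def subset_features(self, feature_ids: Sequence[str]) -> "BinaryCellMatrix":
        js = [self._feature_index[f] for f in feature_ids]
        return BinaryCellMatrix(self.cell_ids, np.asarray(feature_ids, dtype=object), self.X[:, js])

    def subset_cells(self, mask: np.ndarray) -> "BinaryCellMatrix":
        return BinaryCellMatrix(self.cell_ids[mask], self.feature_ids, sp.csc_matrix(self.X[mask]))


def binarize(counts: sp.spmatrix) -> sp.csc_matrix:
    """Binarise a count matrix: any count >= 1 becomes 1, zeros stay 0.

    Idempotent on already-binary input.
    """
    out = sp.csc_matrix(counts, copy=True)
    out.data = (out.data >= 1).astype(np.uint8)
    out.eliminate_zeros()
    return out


def read_binary_matrix(
    matrix_path: str | Path,
    feature_path: str | Path,
    barcode_path: str | Path,
) -> BinaryCellMatrix:
    """Read a MatrixMarket count matrix (features x cells, CellRanger
    orientation) plus feature/barcode TSVs and binarise it."""
    M = scipy.io.mmread(str(matrix_path))
    features = pd.read_csv(feature_path, sep="\t", header=None)[0].astype(str).to_numpy()
    barcodes = pd.read_csv(barcode_path, sep="\t", header=None)[0].astype(str).to_numpy()
    M = sp.csc_matrix(M)
    if M.shape == (len(features), len(barcodes)):
        M = M.T.tocsc()
    elif M.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix {matrix_path} has shape {M.shape}, inconsistent with "
            f"{len(features)} features ({feature_path}) and "
            f"{len(barcodes)} barcodes ({barcode_path})"
        )
    return BinaryCellMatrix(barcodes, features, binarize(M))


def write_binary_matrix(
    matrix: BinaryCellMatrix,
    matrix_path: str | Path,
    feature_path: str | Path,
    barcode_path: str | Path,
) -> None:
    """Write in CellRanger orientation (features x cells)."""
    scipy.io.mmwrite(str(matrix_path), matrix.X.T.tocoo())
    pd.Series(matrix.feature_ids).to_csv(feature_path, sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(barcode_path, sep="\t", header=False, index=False)
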