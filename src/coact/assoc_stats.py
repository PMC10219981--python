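"""Statistical core: binary-vector correlation, permutation nulls, FDR,
partial correlation.

On binarised single-cell matrices the Pearson correlation of two features
equals the phi coefficient of their 2x2 contingency table, so all
correlations here reduce to co-occurrence counts and are computed without
densifying anything larger than the vectors involved.

Significance conventions
------------------------
* Analytic two-sided p-values use the t transform
  ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom
  (``n - 3`` for first-order partial correlation).
* Permutation p-values use the add-one estimator
  ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)`` so that p is never 0;
  only the gene-expression vector is shuffled.
* Degenerate inputs (constant vectors, perfectly collinear conditioning)
  yield NaN results flagged as undefined rather than silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_analytic: float
    p_empirical: float | None = None
    q: float | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


@dataclass
class PartialCorrelationResult:
    r_partial: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r_partial)


def _t_pvalue(r: np.ndarray | float, n: int, df_offset: int = 2) -> np.ndarray | float:
    """Two-sided p for a correlation coefficient via the t transform."""
    df = n - df_offset
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - np.square(r)))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # |r| == 1 gives t = inf -> sf = 0; keep the open-interval contract
    return np.where(np.isfinite(r), np.clip(p, np.finfo(float).tiny, 1.0), np.nan) if np.ndim(r) else (
        float(np.clip(p, np.finfo(float).tiny, 1.0)) if np.isfinite(r) else float("nan")
    )


def binary_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r of two equal-length binary vectors from their 2x2 counts."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxy = float(x @ y)
    vx = sx * (n - sx)
    vy = sy * (n - sy)
    if vx == 0 or vy == 0:
        return float("nan")
    return (n * sxy - sx * sy) / np.sqrt(vx * vy)


def phi_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation of two binary vectors (the phi coefficient).

    A constant vector makes r undefined; the result is flagged with
    ``r = NaN`` and must be skipped by callers, never treated as r = 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    r = binary_pearson(x, y)
    return CorrelationResult(r=r, n=x.size, p_analytic=_t_pvalue(r, x.size))


def binary_pearson_vec(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """r between one binary vector ``x`` and each column of binary ``Y``.

    Columns with zero variance (or constant ``x``) give NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = x.size
    sx = x.sum()
    sy = Y.sum(axis=0)
    sxy = x @ Y
    vx = sx * (n - sx)
    vy = sy * (n - sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    if vx == 0:
        r[:] = np.nan
    return r


def pairwise_binary_pearson(M: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between the columns of a binary cells x k block.

    Returns a k x k symmetric matrix with NaN rows/columns for constant
    features.
    """
    M = np.asarray(M, dtype=np.float64)
    n, k = M.shape
    s = M.sum(axis=0)
    C = M.T @ M
    num = n * C - np.outer(s, s)
    v = s * (n - s)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = num / np.sqrt(np.outer(v, v))
    R[v == 0, :] = np.nan
    R[:, v == 0] = np.nan
    return R


def analytic_pvalues(r: np.ndarray, n: int, df_offset: int = 2) -> np.ndarray:
    """Vectorised two-sided t-transform p-values for correlations."""
    return np.asarray(_t_pvalue(np.asarray(r, dtype=float), n, df_offset))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator,
    ties: str = "random",
) -> float:
    """Two-sided empirical p-value for corr(x, y) by shuffling ``x``.

    ``x`` is the gene-expression vector (the side that is permuted); ``y``
    stays fixed.  Extremeness is judged on ``|r|``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    p = permutation_pvalues_matrix(x, np.asarray(y)[:, None], n_perm, seed, ties=ties)
    return float(p[0])


def permutation_pvalues_matrix(
    x: np.ndarray,
    Y: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator,
    ties: str = "random",
) -> np.ndarray:
    """Empirical p-values for corr(x, Y[:, j]) for every column j, sharing
    one set of ``n_perm`` shuffles of ``x``.

    Because all vectors are binary with fixed margins, only the
    co-occurrence count varies under permutation; the permuted correlations
    are computed from a single (n_perm x cells) @ (cells x k) product.

    Binary statistics tie heavily (the co-occurrence count lives on a small
    integer grid), so the tie convention matters:

    * ``ties="random"`` (default): the observed statistic's rank within its
      tie group is drawn uniformly, giving ``p = (1 + #{|r| > |r_obs|} +
      B) / (n_perm + 1)`` with ``B ~ Uniform{0..#ties}``.  Under the null
      this p is *exactly* uniform on its grid; without ties it reduces to
      the plain add-one estimator.
    * ``ties="over"``: ties count as exceedances
      (``p = (1 + #{|r| >= |r_obs|}) / (n_perm + 1)``), the conventional
      conservative estimator.

    Both are deterministic for a fixed seed.
    """
    if ties not in {"random", "over"}:
        raise ValueError("ties must be 'random' or 'over'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = x.size
    sx = x.sum()
    sy = Y.sum(axis=0)
    vx = sx * (n - sx)
    vy = sy * (n - sy)
    if vx == 0:
        return np.full(Y.shape[1], np.nan)
    # |r| comparisons reduce to exact integer comparisons of the centred
    # co-occurrence numerator n*sxy - sx*sy (margins are permutation-fixed)
    num_obs = np.abs(n * (x @ Y) - sx * sy)
    P = np.empty((n_perm, n), dtype=np.float64)
    for i in range(n_perm):
        P[i] = x[rng.permutation(n)]
    num_perm = np.abs(n * (P @ Y) - sx * sy)  # n_perm x k
    greater = np.sum(num_perm > num_obs[None, :], axis=0)
    if ties == "over":
        exceed = greater + np.sum(num_perm == num_obs[None, :], axis=0)
    else:
        n_ties = np.sum(num_perm == num_obs[None, :], axis=0)
        exceed = greater + rng.integers(0, n_ties + 1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[vy == 0] = np.nan
    return p


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; all p must lie in (0, 1].  NaN entries
    (undefined tests) propagate as NaN and do not count towards the family
    size.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] <= 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if ok.sum():
        out[ok] = sps.false_discovery_control(p[ok], method="bh")
    return out


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> PartialCorrelationResult:
    """First-order partial correlation of x and y given z.

    Uses ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``
    with a two-sided p on ``n - 3`` degrees of freedom.  If x or y is
    perfectly correlated with z (or any marginal correlation is undefined)
    the result is flagged undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    n = x.size
    if not (y.size == n == z.size) or n < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    r_p = partial_from_marginals(r_xy, r_xz, r_yz)
    return PartialCorrelationResult(
        r_partial=float(r_p), p=_t_pvalue(float(r_p), n, df_offset=3), n=n
    )


def partial_from_marginals(r_xy, r_xz, r_yz):
    """Vectorised first-order partial correlation from the three marginal
    correlations; NaN where the conditioning is degenerate."""
    r_xy = np.asarray(r_xy, dtype=np.float64)
    r_xz = np.asarray(r_xz, dtype=np.float64)
    r_yz = np.asarray(r_yz, dtype=np.float64)
    denom = np.sqrt((1.0 - np.square(r_xz)) * (1.0 - np.square(r_yz)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r_xy - r_xz * r_yz) / denom
    return np.where(denom > 0, out, np.nan)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0 or vy == 0:
        return float("nan")
    return float(xc @ yc) / np.sqrt(vx * vy)


# ---------------------------------------------------------------------------
# Library-backed helpers used throughout the reporting stages
# ---------------------------------------------------------------------------


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-transform p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_odds(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio ``ad / bc`` and two-sided Fisher exact p for the
    2x2 table [[a, b], [c, d]].  ``bc == 0`` with ``ad > 0`` reports an
    infinite odds ratio."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
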