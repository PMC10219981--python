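"""Stage 3: Hi-C contact support for enhancer pairs.

Looks up normalized contact counts between the fixed-resolution bins
containing the two enhancer midpoints, log2-transforms them (missing
entries read as 0), removes the distance trend with an ordinary
least-squares fit of log-contact on log10 distance, and builds
distance-matched mirrored control pairs (the second anchor reflected
through the first), giving two complementary notions of "more contact than
expected by distance": a positive residual and an excess over the mirrored
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assoc_stats as ast

logger = logging.getLogger("coact")


@dataclass
class ContactMap:
    """Per-chromosome normalized contact lookup at fixed resolution.

    ``contacts`` maps ``(bin_i, bin_j)`` with ``bin_i <= bin_j`` to the
    normalized count; lookups are symmetric and missing entries read as 0.
    """

    chrom: str
    resolution: int = 5000
    contacts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path, chrom: str, resolution: int = 5000) -> "ContactMap":
        """Read a 3-column (start1, start2, normalized count) dump."""
        df = pd.read_csv(path, sep="\t", header=None, names=["start1", "start2", "value"])
        cm = cls(chrom=chrom, resolution=resolution)
        for b1, b2, v in zip(df["start1"], df["start2"], df["value"]):
            cm.contacts[(min(b1, b2), max(b1, b2))] = float(v)
        return cm

    def lookup(self, bin1: int, bin2: int) -> float:
        return self.contacts.get((min(bin1, bin2), max(bin1, bin2)), 0.0)


def bin_of(position: int, resolution: int) -> int:
    """Start of the fixed-resolution bin containing a position."""
    if position < 0:
        raise ValueError("position must be >= 0")
    return (position // resolution) * resolution


def pair_contact(cmap: ContactMap, mid1: int, mid2: int, chrom: str | None = None) -> float:
    """log2(c + 1) of the normalized contact between the bins holding the
    two midpoints.  Absent bin pairs count as c = 0, hence log-contact 0."""
    if chrom is not None and chrom != cmap.chrom:
        raise ValueError(
            f"cross-chromosome contact requested ({chrom} vs {cmap.chrom}); "
            "trans contacts are out of scope"
        )
    c = cmap.lookup(bin_of(mid1, cmap.resolution), bin_of(mid2, cmap.resolution))
    return float(np.log2(c + 1.0))


def control_pair(mid1: int, mid2: int) -> int:
    """Mirrored control: the second anchor reflected through the first.

    Conserves the pair distance exactly while moving to the opposite side;
    a negative coordinate means the control falls off the chromosome and
    the pair must be skipped.
    """
    return 2 * mid1 - mid2


def contact_records(
    pairs: pd.DataFrame,
    maps: dict[str, ContactMap],
) -> pd.DataFrame:
    """Contact + mirrored-control lookup for every enhancer pair record.

    ``pairs`` needs ``enhancer_a``/``enhancer_b`` ids in ``chrom:start-end``
    form.  Pairs whose mirrored control would fall below coordinate 0 get a
    NaN control (counted in ``attrs['n_control_skipped']``).
    """
    from .genomic_io import parse_interval_name

    rows = []
    n_skipped = 0
    for a, b in zip(pairs["enhancer_a"], pairs["enhancer_b"]):
        ia, ib = parse_interval_name(a), parse_interval_name(b)
        if ia.chrom != ib.chrom:
            raise ValueError(f"cross-chromosome pair {a} / {b}")
        cmap = maps.get(ia.chrom)
        m1, m2 = ia.midpoint, ib.midpoint
        dist = abs(m2 - m1)
        if cmap is None:
            lc = 0.0
            ctrl = np.nan
        else:
            lc = pair_contact(cmap, m1, m2)
            cm = control_pair(m1, m2)
            if cm < 0:
                ctrl = np.nan
                n_skipped += 1
            else:
                ctrl = pair_contact(cmap, m1, cm)
        rows.append((f"{a}|{b}", dist, lc, ctrl))
    out = pd.DataFrame(
        rows, columns=["pair_id", "distance_bp", "log_contact", "control_log_contact"]
    )
    out.attrs["n_control_skipped"] = n_skipped
    return out


def residualize_on_distance(records: pd.DataFrame, log_distance: bool = True) -> pd.DataFrame:
    """Add a ``residual`` column: log-contact minus the OLS distance trend.

    The covariate is log10(distance) by default (``log_distance=False``
    uses raw bp).  Pairs at distance 0 (same bin midpoint) are excluded
    from the fit and get NaN residuals.
    """
    out = records.copy()
    d = out["distance_bp"].to_numpy(dtype=float)
    y = out["log_contact"].to_numpy(dtype=float)
    ok = d > 0 if log_distance else np.isfinite(d)
    if ok.sum() < 3 or np.unique(d[ok]).size < 2:
        raise ValueError("need >= 3 records with at least 2 distinct distances")
    x = np.log10(d[ok]) if log_distance else d[ok]
    fit = sps.linregress(x, y[ok])
    resid = np.full(len(out), np.nan)
    resid[ok] = y[ok] - (fit.intercept + fit.slope * x)
    out["residual"] = resid
    out.attrs["distance_fit"] = {"intercept": float(fit.intercept), "slope": float(fit.slope)}
    return out


def support_summary(pairs: pd.DataFrame, records: pd.DataFrame) -> dict:
    """Headline Hi-C support statistics.

    Reports the Spearman correlation between pair correlation and
    log-contact, the fraction of pairs with positive distance residual,
    and a paired two-sided Wilcoxon signed-rank test of contact vs the
    mirrored control.
    """
    merged = pairs.reset_index(drop=True).join(records.reset_index(drop=True), rsuffix="_hic")
    r_spear, p_spear = ast.spearman(
        merged["r"].to_numpy(), merged["log_contact"].to_numpy()
    )
    resid = merged["residual"].to_numpy(dtype=float)
    frac_pos = float(np.mean(resid[np.isfinite(resid)] > 0)) if np.isfinite(resid).any() else float("nan")
    frac_pos_sig = float("nan")
    if "significant" in merged.columns:
        sig_resid = resid[merged["significant"].to_numpy(dtype=bool) & np.isfinite(resid)]
        if sig_resid.size:
            frac_pos_sig = float(np.mean(sig_resid > 0))
    has_ctrl = np.isfinite(merged["control_log_contact"].to_numpy(dtype=float))
    obs = merged.loc[has_ctrl, "log_contact"].to_numpy(dtype=float)
    ctrl = merged.loc[has_ctrl, "control_log_contact"].to_numpy(dtype=float)
    if has_ctrl.sum() >= 10 and np.any(obs != ctrl):
        w = sps.wilcoxon(obs, ctrl)
        w_p = float(w.pvalue)
    else:
        w_p = float("nan")
    return {
        "spearman_r_contact_vs_correlation": r_spear,
        "spearman_p": p_spear,
        "fraction_residual_positive": frac_pos,
        "fraction_residual_positive_significant": frac_pos_sig,
        "mean_log_contact": float(np.nanmean(merged["log_contact"])),
        "mean_control_log_contact": float(np.nanmean(ctrl)) if has_ctrl.any() else float("nan"),
        "wilcoxon_p_vs_control": w_p,
        "n_pairs": int(len(merged)),
    }
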