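"""Stage 4: transcription-factor binding sharing between enhancer pairs.

Each enhancer is assigned the set of distinct TFs with at least one binding
site fully contained in it (bedtools ``-F1`` semantics; multiple sites of
one TF collapse to one membership).  Pair-level sharing is the size of the
set intersection and its Jaccard index; pairs whose enhancers carry no
annotated site count as sharing 0 TFs rather than being excluded.

Because significant pairs sit at systematically shorter distances than
non-significant ones, the significant/non-significant comparison is also
run on distance-matched sets: each non-significant pair is matched to one
subsampled significant pair whose distance differs by at most 5%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import genomic_io as gio

logger = logging.getLogger("coact")


def assign_tfs(tfbs: pd.DataFrame, enhancers: pd.DataFrame) -> dict[str, set[str]]:
    """Per-enhancer sets of distinct TFs with fully contained sites.

    ``tfbs`` is a BED-like frame with the TF identifier in ``name``.
    Enhancers without any contained site get an empty set.
    """
    if "name" not in tfbs.columns:
        raise ValueError("TFBS intervals must carry the TF name in column 4")
    enh = enhancers.reset_index(drop=True)
    names = gio.interval_names(enh)
    out: dict[str, set[str]] = {n: set() for n in names}
    hits = gio.contained_overlap(tfbs, enh)
    for q_idx, t_idx in zip(hits["query_index"], hits["target_index"]):
        out[names.iloc[t_idx]].add(str(tfbs["name"].iloc[q_idx]))
    return out


def sharing(pairs: pd.DataFrame, assignments: dict[str, set[str]]) -> pd.DataFrame:
    """Add ``n_shared`` and ``jaccard`` columns to pair records.

    Enhancers absent from ``assignments`` are treated as having no bound
    TFs; an empty union gives Jaccard 0 by convention.
    """
    n_shared = []
    jaccard = []
    for a, b in zip(pairs["enhancer_a"], pairs["enhancer_b"]):
        sa = assignments.get(a, set())
        sb = assignments.get(b, set())
        inter = len(sa & sb)
        union = len(sa | sb)
        n_shared.append(inter)
        jaccard.append(inter / union if union else 0.0)
    out = pairs.copy()
    out["n_shared"] = n_shared
    out["jaccard"] = jaccard
    return out


def distance_match(
    sig_records: pd.DataFrame,
    nonsig_records: pd.DataFrame,
    tolerance: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match each non-significant pair to one significant pair of nearly
    equal distance (within ``tolerance`` relative difference), sampling
    without replacement.

    Non-significant records are visited in seeded random order; for each,
    one significant record with distance in ``[d*(1-tol), d*(1+tol)]`` is
    drawn uniformly from those not yet used.  Unmatchable records are
    dropped (count in ``attrs['n_unmatched']``).  Returns the matched
    (non-significant, significant) frames, row-aligned and of equal length.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rng = np.random.default_rng(seed)
    sig = sig_records.reset_index(drop=True)
    nonsig = nonsig_records.reset_index(drop=True)
    sig_d = sig["pair_distance_bp"].to_numpy(dtype=float)
    order = np.argsort(sig_d, kind="stable")
    sorted_d = sig_d[order]
    used = np.zeros(len(sig), dtype=bool)

    matched_ns: list[int] = []
    matched_sig: list[int] = []
    n_unmatched = 0
    for i in rng.permutation(len(nonsig)):
        d = float(nonsig["pair_distance_bp"].iloc[i])
        lo = np.searchsorted(sorted_d, d * (1 - tolerance), side="left")
        hi = np.searchsorted(sorted_d, d * (1 + tolerance), side="right")
        candidates = order[lo:hi]
        candidates = candidates[~used[candidates]]
        if candidates.size == 0:
            n_unmatched += 1
            continue
        pick = int(rng.choice(candidates))
        used[pick] = True
        matched_ns.append(int(i))
        matched_sig.append(pick)
    if n_unmatched:
        logger.info("distance_match: %d non-significant pairs unmatched", n_unmatched)
    out_ns = nonsig.iloc[matched_ns].reset_index(drop=True)
    out_sig = sig.iloc[matched_sig].reset_index(drop=True)
    out_ns.attrs["n_unmatched"] = n_unmatched
    out_sig.attrs["n_unmatched"] = n_unmatched
    return out_ns, out_sig


def sharing_summary(
    shared_pairs: pd.DataFrame,
    tolerance: float = 0.05,
    seed: int = 0,
) -> dict:
    """Group comparison of TF sharing between significant and
    non-significant pairs, raw and distance-matched.

    Uses a two-sided Wilcoxon rank-sum test on ``n_shared`` (library call);
    also reports the Spearman correlation of pair correlation with
    ``n_shared`` and with Jaccard.
    """
    from . import assoc_stats as ast

    sig = shared_pairs[shared_pairs["significant"].astype(bool)]
    nonsig = shared_pairs[~shared_pairs["significant"].astype(bool)]
    out: dict = {
        "n_significant": int(len(sig)),
        "n_nonsignificant": int(len(nonsig)),
        "mean_shared_significant": float(sig["n_shared"].mean()) if len(sig) else float("nan"),
        "mean_shared_nonsignificant": float(nonsig["n_shared"].mean()) if len(nonsig) else float("nan"),
    }
    if len(sig) and len(nonsig):
        w = sps.ranksums(sig["n_shared"], nonsig["n_shared"])
        out["wilcoxon_p"] = float(w.pvalue)
    else:
        out["wilcoxon_p"] = float("nan")
    if len(shared_pairs) >= 3:
        r_n, p_n = ast.spearman(shared_pairs["r"].to_numpy(), shared_pairs["n_shared"].to_numpy())
        r_j, p_j = ast.spearman(shared_pairs["r"].to_numpy(), shared_pairs["jaccard"].to_numpy())
        out["spearman_r_vs_n_shared"] = r_n
        out["spearman_r_vs_jaccard"] = r_j
    if len(sig) and len(nonsig):
        m_ns, m_sig = distance_match(sig, nonsig, tolerance=tolerance, seed=seed)
        out["n_matched"] = int(len(m_ns))
        if len(m_ns):
            out["mean_shared_significant_matched"] = float(m_sig["n_shared"].mean())
            out["mean_shared_nonsignificant_matched"] = float(m_ns["n_shared"].mean())
            w = sps.ranksums(m_sig["n_shared"], m_ns["n_shared"])
            out["wilcoxon_p_matched"] = float(w.pvalue)
    return out
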