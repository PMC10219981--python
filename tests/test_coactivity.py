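"""Pair scan, partial correlation, combination enumeration and the
enhancer-centric view."""

import numpy as np
import pandas as pd
import pytest

from coact import assoc_stats as ast, coactivity, genomic_io as gio
from coact.simulate import SimConfig, generate_multiome


def _matrix(cols, features=None):
    cols = np.asarray(cols, dtype=np.uint8)
    cells = [f"c{i}" for i in range(cols.shape[0])]
    features = features or [f"f{i}" for i in range(cols.shape[1])]
    return gio.BinaryCellMatrix(cells, features, cols)


def _assoc(records):
    df = pd.DataFrame(records, columns=["gene_id", "enhancer_id"])
    df["r"] = 0.5
    df["p_empirical"] = 0.001
    df["q"] = 0.001
    df["significant"] = True
    df["distance_bp"] = 1000
    return df


# ---------------------------------------------------------------------------
# expressing cells
# ---------------------------------------------------------------------------


def test_expressing_cells_matches_manual_scan():
    expr = _matrix([[1], [0], [1], [1]], ["g1"])
    mask = coactivity.expressing_cells(expr, "g1", min_cells=1)
    assert mask.tolist() == [True, False, True, True]


def test_expressing_cells_absent_gene_errors():
    expr = _matrix([[1], [0]], ["g1"])
    with pytest.raises(KeyError):
        coactivity.expressing_cells(expr, "nope")


def test_min_cells_boundary_inclusive():
    """A gene expressed in exactly min_cells cells is retained."""
    n = 120
    expr_cols = np.zeros((n, 1), dtype=np.uint8)
    expr_cols[:100, 0] = 1
    expr = _matrix(expr_cols, ["g1"])
    rng = np.random.default_rng(0)
    enh = _matrix((rng.random((n, 2)) < 0.5).astype(np.uint8), ["chr1:0-600", "chr1:1000-1600"])
    assoc = _assoc([("g1", "chr1:0-600"), ("g1", "chr1:1000-1600")])
    pairs = coactivity.pair_scan(expr, enh, assoc, min_cells=100)
    assert len(pairs) == 1 and pairs["n_cells"].iloc[0] == 100
    # one cell fewer -> excluded and logged
    expr_cols[99, 0] = 0
    pairs = coactivity.pair_scan(_matrix(expr_cols, ["g1"]), enh, assoc, min_cells=100)
    assert pairs.empty
    assert pairs.attrs["skipped_low_cell_genes"] == ["g1"]


# ---------------------------------------------------------------------------
# pair scan
# ---------------------------------------------------------------------------


def test_pair_counts_are_k_choose_2(sim_strong, assoc_strong, pairs_strong):
    sig = assoc_strong[assoc_strong["significant"]]
    k = sig.groupby("gene_id").size()
    skipped = set(pairs_strong.attrs["skipped_low_cell_genes"])
    expected = sum(v * (v - 1) // 2 for g, v in k.items() if v >= 2 and g not in skipped)
    assert len(pairs_strong) == expected


def test_ten_enhancers_give_45_pairs():
    rng = np.random.default_rng(2)
    n = 300
    feats = [f"chr1:{i * 1000}-{i * 1000 + 600}" for i in range(10)]
    enh = _matrix((rng.random((n, 10)) < 0.4).astype(np.uint8), feats)
    expr = _matrix(np.ones((n, 1), dtype=np.uint8), ["g1"])
    pairs = coactivity.pair_scan(expr, enh, _assoc([("g1", f) for f in feats]), min_cells=10)
    assert len(pairs) == 45
    single = coactivity.pair_scan(expr, enh, _assoc([("g1", feats[0])]), min_cells=10)
    assert single.empty


def test_pair_records_canonical_order_and_distance(pairs_strong):
    assert (pairs_strong["enhancer_a"] < pairs_strong["enhancer_b"]).all()
    a = pairs_strong.iloc[0]
    mid_a = gio.parse_interval_name(a["enhancer_a"]).midpoint
    mid_b = gio.parse_interval_name(a["enhancer_b"]).midpoint
    assert a["pair_distance_bp"] == abs(mid_a - mid_b)


def test_planted_pair_is_top_ranked():
    """One strongly co-active pair among four enhancers: it gets the
    highest r and is the significant one."""
    rng = np.random.default_rng(4)
    n = 500
    shared = (rng.random(n) < 0.5).astype(np.uint8)
    cols = np.column_stack(
        [
            shared | (rng.random(n) < 0.05),
            shared | (rng.random(n) < 0.05),
            (rng.random(n) < 0.3).astype(np.uint8),
            (rng.random(n) < 0.3).astype(np.uint8),
        ]
    ).astype(np.uint8)
    feats = [f"chr1:{i * 1000}-{i * 1000 + 600}" for i in range(4)]
    enh = _matrix(cols, feats)
    expr = _matrix(np.ones((n, 1), dtype=np.uint8), ["g1"])
    pairs = coactivity.pair_scan(expr, enh, _assoc([("g1", f) for f in feats]), min_cells=10)
    top = pairs.sort_values("r", ascending=False).iloc[0]
    assert {top["enhancer_a"], top["enhancer_b"]} == {feats[0], feats[1]}
    assert top["significant"]
    assert not pairs[pairs["r"] < 0.2]["significant"].any()


def test_pair_r_matches_direct_phi_on_expressing_cells(sim_strong, assoc_strong, pairs_strong):
    row = pairs_strong.iloc[0]
    mask = coactivity.expressing_cells(sim_strong.expr, row["gene_id"])
    x = sim_strong.enh.column(row["enhancer_a"])[mask]
    y = sim_strong.enh.column(row["enhancer_b"])[mask]
    assert row["r"] == pytest.approx(ast.phi_correlation(x, y).r, abs=1e-12)


def test_significant_pairs_positive_under_positive_coupling(pairs_strong, truth_pairs_strong):
    """Strictly positive coupling makes true co-activity positive; the only
    negative significant pairs are the expected few false discoveries."""
    sig = pairs_strong[pairs_strong["significant"]]
    assert len(sig) > 0
    planted = [
        (g, a, b) in truth_pairs_strong
        for g, a, b in zip(sig["gene_id"], sig["enhancer_a"], sig["enhancer_b"])
    ]
    assert (sig.loc[planted, "r"] > 0).all()
    assert (sig["r"] > 0).mean() > 0.95


# ---------------------------------------------------------------------------
# baseline scan
# ---------------------------------------------------------------------------


def test_baseline_flags_and_superset():
    sim = generate_multiome(SimConfig(seed=6, n_genes=30, n_cells=800))
    from coact import gene_enhancer

    assoc = gene_enhancer.scan_gene_enhancer(
        sim.expr, sim.enh, sim.genes, sim.enhancers, n_perm=99, seed=6
    )
    pairs = coactivity.pair_scan(sim.expr, sim.enh, assoc)
    base = coactivity.baseline_pair_scan(
        sim.expr, sim.enh, sim.genes, sim.enhancers, assoc
    )
    assert set(base["n_associated"]) <= {0, 1, 2}
    keys = lambda df: set(zip(df["gene_id"], df["enhancer_a"], df["enhancer_b"]))
    assert keys(pairs) <= keys(base)
    both = base[base["n_associated"] == 2]
    assert keys(pairs) == keys(both)


def test_baseline_cap_guard(sim_strong, assoc_strong):
    with pytest.raises(ValueError, match="cap"):
        coactivity.baseline_pair_scan(
            sim_strong.expr,
            sim_strong.enh,
            sim_strong.genes,
            sim_strong.enhancers,
            assoc_strong,
            max_tests=10,
        )


# ---------------------------------------------------------------------------
# partial correlation stage
# ---------------------------------------------------------------------------


def test_partial_scan_fields_and_oracle(sim_strong, pairs_strong):
    out = coactivity.partial_scan(sim_strong.expr, sim_strong.enh, pairs_strong.head(40))
    row = out.iloc[0]
    x = sim_strong.enh.column(row["enhancer_a"]).astype(float)
    y = sim_strong.enh.column(row["enhancer_b"]).astype(float)
    z = sim_strong.expr.column(row["gene_id"]).astype(float)
    expected = ast.partial_correlation(x, y, z)
    assert row["r_partial"] == pytest.approx(expected.r_partial, abs=1e-10)
    assert row["p_partial"] == pytest.approx(expected.p, rel=1e-9)


def test_partial_scan_mediated_pairs_collapse():
    """With no module coupling and no dropout, pair co-activity is fully
    mediated by observed expression: conditioning removes it."""
    sim = generate_multiome(
        SimConfig(seed=12, n_genes=40, n_cells=1200, coactivity_coupling=0.0, dropout_rate=0.0)
    )
    links = sim.truth.links.groupby("gene_id").filter(lambda d: len(d) >= 2)
    rows = []
    for gene_id, grp in links.groupby("gene_id"):
        ids = sorted(grp["enhancer_id"])[:2]
        rows.append((gene_id, ids[0], ids[1], 0, 0.0, 0.5, False, 0.5, 0))
    pairs = pd.DataFrame(
        rows,
        columns=["gene_id", "enhancer_a", "enhancer_b", "n_cells", "r", "p", "significant", "q", "pair_distance_bp"],
    )
    out = coactivity.partial_scan(sim.expr, sim.enh, pairs)
    # per pair the conditioned correlation is pure sampling noise
    # (~1/sqrt(n_cells)); allow for the max order statistic over ~40 pairs
    assert np.abs(out["r_partial"]).max() < 0.12
    # on average the conditioned correlation is far smaller
    r_alls = [
        ast.phi_correlation(sim.enh.column(a), sim.enh.column(b)).r
        for a, b in zip(out["enhancer_a"], out["enhancer_b"])
    ]
    assert np.nanmean(np.abs(out["r_partial"])) < 0.35 * np.nanmean(np.abs(r_alls))


def test_partial_scan_constant_gene_flagged():
    n = 50
    rng = np.random.default_rng(1)
    expr = _matrix(np.zeros((n, 1), dtype=np.uint8), ["g1"])
    enh = _matrix((rng.random((n, 2)) < 0.5).astype(np.uint8), ["chr1:0-600", "chr1:1000-1600"])
    pairs = pd.DataFrame(
        [("g1", "chr1:0-600", "chr1:1000-1600", n, 0.1, 0.5, False, 0.5, 1000)],
        columns=["gene_id", "enhancer_a", "enhancer_b", "n_cells", "r", "p", "significant", "q", "pair_distance_bp"],
    )
    out = coactivity.partial_scan(expr, enh, pairs)
    assert out["partial_undefined"].iloc[0]
    assert np.isnan(out["r_partial"].iloc[0])


def test_partial_larger_for_significant_pairs(sim_strong, pairs_strong):
    """Module-driven co-activity survives conditioning: partial r of
    significant pairs is stochastically larger than of non-significant."""
    from scipy import stats as sps

    out = coactivity.partial_scan(sim_strong.expr, sim_strong.enh, pairs_strong)
    sig = out[out["significant"]]["r_partial"].dropna()
    non = out[~out["significant"]]["r_partial"].dropna()
    stat = sps.ranksums(sig, non, alternative="greater")
    assert stat.pvalue < 1e-10
    assert sig.median() > non.median()


# ---------------------------------------------------------------------------
# combination enumeration
# ---------------------------------------------------------------------------


def _combo_inputs(patterns, k):
    feats = [f"chr1:{i * 1000}-{i * 1000 + 600}" for i in range(k)]
    cols = np.array(patterns, dtype=np.uint8)
    enh = _matrix(cols, feats)
    expr = _matrix(np.ones((cols.shape[0], 1), dtype=np.uint8), ["g1"])
    assoc = _assoc([("g1", f) for f in feats])
    return expr, enh, assoc


def test_all_seven_patterns_for_three_enhancers():
    patterns = [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]]
    expr, enh, assoc = _combo_inputs(patterns, 3)
    out = coactivity.combination_summary(expr, enh, assoc, min_cells=1)
    row = out.iloc[0]
    assert (row["n_possible"], row["n_observed"], row["pct_observed"]) == (7, 7, 100.0)


def test_ten_enhancers_1023_possible():
    patterns = [[1] * 10, [0] * 10]
    expr, enh, assoc = _combo_inputs(patterns, 10)
    out = coactivity.combination_summary(expr, enh, assoc, min_cells=1)
    row = out.iloc[0]
    assert row["n_possible"] == 1023
    assert row["n_possible_pairs"] == 45
    assert row["n_observed"] == 1  # only the all-on pattern is non-empty


def test_all_zero_patterns_count_nothing():
    patterns = [[0, 0, 0]] * 5
    expr, enh, assoc = _combo_inputs(patterns, 3)
    out = coactivity.combination_summary(expr, enh, assoc, min_cells=1)
    assert out["n_observed"].iloc[0] == 0


def test_combination_counts_only_expressing_cells():
    feats = ["chr1:0-600", "chr1:1000-1600"]
    enh = _matrix([[1, 1], [1, 0], [0, 1]], feats)
    expr = _matrix([[1], [1], [0]], ["g1"])  # third cell not expressing
    out = coactivity.combination_summary(expr, enh, _assoc([("g1", f) for f in feats]), min_cells=1)
    assert out["n_observed"].iloc[0] == 2  # (1,1) and (1,0); (0,1) invisible


def test_bitset_width_guard():
    k = 63
    feats = [f"chr1:{i * 1000}-{i * 1000 + 600}" for i in range(k)]
    enh = _matrix(np.zeros((2, k), dtype=np.uint8), feats)
    expr = _matrix(np.ones((2, 1), dtype=np.uint8), ["g1"])
    with pytest.raises(ValueError, match="62"):
        coactivity.combination_summary(expr, enh, _assoc([("g1", f) for f in feats]), min_cells=1)


def test_pct_observed_declines_with_k(sim_strong, assoc_strong, pairs_strong):
    out = coactivity.combination_summary(
        sim_strong.expr, sim_strong.enh, assoc_strong, pairs_strong
    )
    multi = out[out["k"] >= 2]
    r, _ = ast.spearman(multi["k"].to_numpy(float), multi["pct_observed"].to_numpy())
    assert r < 0


# ---------------------------------------------------------------------------
# enhancer-centric view
# ---------------------------------------------------------------------------


def test_enhancer_centric_groupby_oracle(pairs_strong):
    out = coactivity.enhancer_centric_summary(pairs_strong)
    # brute-force group-by on the raw records
    expected = {}
    for _, row in pairs_strong.iterrows():
        key = (row["enhancer_a"], row["enhancer_b"])
        g, s = expected.get(key, (set(), 0))
        g.add(row["gene_id"])
        expected[key] = (g, s + bool(row["significant"]))
    assert len(out) == len(expected)
    for _, row in out.head(50).iterrows():
        g, s = expected[(row["enhancer_a"], row["enhancer_b"])]
        assert row["n_genes_tested"] == len(g)
        assert row["n_genes_significant"] == s


def test_enhancer_centric_single_pair():
    pairs = pd.DataFrame(
        [("g1", "e1", "e2", 100, 0.3, 0.001, 0.005, True, 1000)],
        columns=["gene_id", "enhancer_a", "enhancer_b", "n_cells", "r", "p", "q", "significant", "pair_distance_bp"],
    )
    out = coactivity.enhancer_centric_summary(pairs)
    assert out.iloc[0][["n_genes_tested", "n_genes_significant"]].tolist() == [1, 1]
    assert out.iloc[0]["fraction_significant"] == 1.0
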