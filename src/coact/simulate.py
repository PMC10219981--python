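"""Synthetic multiome generator with known ground truth.

Emulates the statistical structure the pipeline assumes in real
SHARE-seq-style data: binarised gene-expression and enhancer-accessibility
matrices over a shared cell set, genes with strand-aware TSSs, enhancers
placed within the cis window of their gene, latent co-activity coupling
between a gene and a planted subset ("module") of its enhancers,
dropout-style sparsity, distance-decaying Hi-C contacts with multiplicative
boosts on planted pairs, and TF pools shared within planted modules.

Generative model (per cell c, gene g)
-------------------------------------
* latent gene state      ``G ~ Bernoulli(gene_expression_rate)``
* observed expression    ``E = G * Bernoulli(1 - dropout_rate)``
* module latent state    ``A = G * Bernoulli(module_on_rate)``
* linked enhancer        ``P(on) = background + coupling * G
  [+ coactivity_coupling * A if the enhancer is in g's module]``
* unlinked enhancer      ``P(on) = background``

Conditioning on expression removes the G-mediated component of
enhancer-enhancer correlation; the module term creates co-activity that
survives partial correlation, mirroring the behaviour reported for real
associated enhancer pairs.

One global seed drives independent per-component substreams
(matrices / Hi-C / TFBS / scores), so regenerating one artifact never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import BinaryCellMatrix, interval_names
import scipy.sparse as sp

_SUBSTREAMS = {"layout": 0, "multiome": 1, "hic": 2, "tfbs": 3, "scores": 4}


@dataclass
class SimConfig:
    """Generator settings; defaults define the standard study conditions.

    The default scale (2,000 cells x 200 genes, ~4 enhancers per gene plus
    one unlinked cis enhancer each) keeps every gene expressed in well over
    100 cells at the default expression rate while generating in seconds.
    """

    n_cells: int = 2000
    n_genes: int = 200
    #: mean of the (1 + Poisson) count of linked enhancers per gene
    enhancers_per_gene_mean: float = 4.0
    max_enhancers_per_gene: int = 12
    #: unlinked (pure-background) cis enhancers per gene
    unlinked_per_gene: int = 1
    window_bp: int = 1_000_000
    gene_spacing_bp: int = 300_000
    gene_length_bp: int = 20_000
    enhancer_length_bp: int = 600
    n_chromosomes: int = 22
    gene_expression_rate: float = 0.15
    enhancer_background_rate: float = 0.05
    coupling: float = 0.35
    coactivity_coupling: float = 0.5
    module_on_rate: float = 0.5
    dropout_rate: float = 0.2
    hic_resolution: int = 5000
    hic_decay_exponent: float = 1.0
    hic_base_level: float = 50.0
    hic_boost: float = 3.0
    hic_depth: float = 10.0
    tf_alphabet_size: int = 155
    tf_pool_size: int = 30
    shared_tf_bias: float = 0.8
    tf_background_mean: float = 5.0
    score_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gene_expression_rate",
            "enhancer_background_rate",
            "coupling",
            "coactivity_coupling",
            "module_on_rate",
            "dropout_rate",
            "shared_tf_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.window_bp <= 0 or self.hic_resolution <= 0:
            raise ValueError("window_bp and hic_resolution must be positive")

    def rng(self, component: str) -> np.random.Generator:
        """Independent substream for one artifact component."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[component],))
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    #: gene_id, enhancer_id, in_module for every linked enhancer
    links: pd.DataFrame
    #: gene_id, enhancer_a, enhancer_b for every within-module pair (a < b)
    coactive_pairs: pd.DataFrame
    #: gene_id -> module size (0 for genes without a module)
    module_size: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


@dataclass
class SimulatedMultiome:
    expr: BinaryCellMatrix
    enh: BinaryCellMatrix
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


def _generate_layout(cfg: SimConfig, rng: np.random.Generator):
    """Place genes along chromosomes and enhancers inside their cis window."""
    genes = []
    offset = cfg.window_bp + cfg.gene_length_bp  # keep everything >= 0
    for i in range(cfg.n_genes):
        chrom = f"chr{(i % cfg.n_chromosomes) + 1}"
        t0 = offset + (i // cfg.n_chromosomes) * cfg.gene_spacing_bp
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = t0, t0 + cfg.gene_length_bp
        else:
            start, end = t0 - cfg.gene_length_bp + 1, t0 + 1
        genes.append((f"G{i:04d}", chrom, start, end, strand, "protein_coding"))
    genes = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )

    max_offset = int(cfg.window_bp * 0.9)
    rows = []
    link_rows = []
    used: dict[str, set[int]] = {}
    for i, g in genes.iterrows():
        t0 = g["start"] if g["strand"] == "+" else g["end"] - 1
        k_linked = 1 + int(rng.poisson(cfg.enhancers_per_gene_mean - 1))
        k_linked = min(k_linked, cfg.max_enhancers_per_gene)
        n_slots = k_linked + cfg.unlinked_per_gene
        span = 2 * max_offset // max(cfg.enhancer_length_bp * 4, 1)
        if n_slots > span:
            raise ValueError("cis window too small for the requested enhancer count")
        taken = used.setdefault(g["chrom"], set())
        placed = 0
        while placed < n_slots:
            off = int(rng.integers(-max_offset, max_offset + 1))
            if abs(off) < cfg.gene_length_bp + cfg.enhancer_length_bp:
                continue  # keep enhancers clear of the gene body
            start = t0 + off - cfg.enhancer_length_bp // 2
            slot = start // cfg.enhancer_length_bp
            if start < 0 or slot in taken:
                continue
            taken.add(slot)
            start = slot * cfg.enhancer_length_bp  # snap: avoids overlaps
            end = start + cfg.enhancer_length_bp
            linked = placed < k_linked
            rows.append((g["chrom"], start, end, g["gene_id"], linked))
            if linked:
                link_rows.append((g["gene_id"], g["chrom"], start, end))
            placed += 1
    enhancers = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "source_gene", "linked"]
    )
    enhancers = enhancers.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(
        drop=True
    )
    enhancers["name"] = interval_names(enhancers)
    links = pd.DataFrame(link_rows, columns=["gene_id", "chrom", "start", "end"])
    links["enhancer_id"] = (
        links["chrom"] + ":" + links["start"].astype(str) + "-" + links["end"].astype(str)
    )
    return genes, enhancers, links


# ---------------------------------------------------------------------------
# Multiome
# ---------------------------------------------------------------------------


def generate_multiome(cfg: SimConfig) -> SimulatedMultiome:
    """Generate expression and enhancer-activity matrices plus ground truth.

    Deterministic for a fixed ``cfg.seed`` (bit-identical matrices and
    annotations across runs).
    """
    layout_rng = cfg.rng("layout")
    genes, enhancers, links = _generate_layout(cfg, layout_rng)
    rng = cfg.rng("multiome")

    n_c = cfg.n_cells
    # planted modules: a random subset (>= 2) of each multi-enhancer gene's links
    module_flags = []
    module_size = {}
    for gene_id, grp in links.groupby("gene_id", sort=False):
        k = len(grp)
        if k >= 2:
            m = int(rng.integers(2, k + 1))
            chosen = rng.choice(k, size=m, replace=False)
            flags = np.zeros(k, dtype=bool)
            flags[chosen] = True
        else:
            flags = np.zeros(k, dtype=bool)
            m = 0
        module_flags.append(pd.Series(flags, index=grp.index))
        module_size[gene_id] = m
    links = links.copy()
    links["in_module"] = pd.concat(module_flags) if module_flags else False

    expr_cols = np.zeros((n_c, cfg.n_genes), dtype=np.uint8)
    enh_prob_extra = {}  # enhancer name -> accumulated activation prob per cell
    enh_names = enhancers["name"].to_numpy()
    enh_index = {n: i for i, n in enumerate(enh_names)}
    E = np.zeros((n_c, len(enh_names)), dtype=np.uint8)
    # background activity for every enhancer
    E |= (rng.random((n_c, len(enh_names))) < cfg.enhancer_background_rate).astype(
        np.uint8
    )

    links_by_gene = dict(tuple(links.groupby("gene_id", sort=False)))
    for j, gene_id in enumerate(genes["gene_id"]):
        G = (rng.random(n_c) < cfg.gene_expression_rate).astype(np.uint8)
        expr_cols[:, j] = G * (rng.random(n_c) >= cfg.dropout_rate)
        grp = links_by_gene.get(gene_id)
        if grp is None:
            continue
        A = G * (rng.random(n_c) < cfg.module_on_rate)
        for _, row in grp.iterrows():
            p_extra = cfg.coupling * G.astype(float)
            if row["in_module"]:
                p_extra = p_extra + cfg.coactivity_coupling * A.astype(float)
            on = rng.random(n_c) < p_extra  # in addition to background
            E[:, enh_index[row["enhancer_id"]]] |= on.astype(np.uint8)

    cell_ids = np.array([f"CELL{i:05d}" for i in range(n_c)], dtype=object)
    expr = BinaryCellMatrix(cell_ids, genes["gene_id"].to_numpy(object), sp.csc_matrix(expr_cols))
    enh = BinaryCellMatrix(cell_ids, enh_names.astype(object), sp.csc_matrix(E))

    pair_rows = []
    for gene_id, grp in links.groupby("gene_id", sort=False):
        mod = sorted(grp.loc[grp["in_module"], "enhancer_id"])
        for a in range(len(mod)):
            for b in range(a + 1, len(mod)):
                pair_rows.append((gene_id, mod[a], mod[b]))
    truth = GroundTruth(
        links=links[["gene_id", "enhancer_id", "in_module"]].reset_index(drop=True),
        coactive_pairs=pd.DataFrame(
            pair_rows, columns=["gene_id", "enhancer_a", "enhancer_b"]
        ),
        module_size=pd.Series(module_size, name="module_size"),
    )
    return SimulatedMultiome(expr, enh, genes, enhancers, truth, cfg)


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------


def generate_hic(
    cfg: SimConfig, enhancers: pd.DataFrame, truth: GroundTruth
) -> dict[str, pd.DataFrame]:
    """Per-chromosome normalized contact lists for every enhancer-bin pair.

    Expected contact follows a power-law distance decay
    ``base * ((d + res) / res) ** -decay`` with a multiplicative
    ``hic_boost`` on planted co-active pairs; observed values are Poisson
    sampled at ``hic_depth`` and rescaled, mimicking normalized counts.
    Bins mirrored through each pair's first anchor are generated too, so
    distance-matched control lookups do not hit systematically missing data.
    """
    rng = cfg.rng("hic")
    res = cfg.hic_resolution
    mids = ((enhancers["start"] + enhancers["end"]) // 2).to_numpy()
    bins = (mids // res) * res
    enh_bin = dict(zip(enhancers["name"], zip(enhancers["chrom"], bins)))

    boosted = set()
    for _, row in truth.coactive_pairs.iterrows():
        ca, ba = enh_bin[row["enhancer_a"]]
        cb, bb = enh_bin[row["enhancer_b"]]
        if ca == cb:
            boosted.add((ca, min(ba, bb), max(ba, bb)))

    wanted: set[tuple[str, int, int]] = set()
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in enhancers.groupby("chrom", observed=True):
        b = np.unique((midpoints_of(grp) // res) * res)
        by_chrom[chrom] = b
        for i in range(len(b)):
            for j in range(i, len(b)):
                if b[j] - b[i] <= 2 * cfg.window_bp:
                    wanted.add((chrom, int(b[i]), int(b[j])))
                    mirror = 2 * b[i] - b[j]  # control bin for (i, j)
                    if mirror >= 0:
                        wanted.add((chrom, int(min(b[i], mirror)), int(max(b[i], mirror))))

    out: dict[str, list] = {}
    for chrom, b1, b2 in sorted(wanted):
        d = b2 - b1
        lam = cfg.hic_base_level * ((d + res) / res) ** (-cfg.hic_decay_exponent)
        if (chrom, b1, b2) in boosted:
            lam *= cfg.hic_boost
        value = rng.poisson(lam * cfg.hic_depth) / cfg.hic_depth
        if value > 0:
            out.setdefault(chrom, []).append((b1, b2, value))
    return {
        chrom: pd.DataFrame(rows, columns=["start1", "start2", "value"])
        for chrom, rows in out.items()
    }


def midpoints_of(intervals: pd.DataFrame) -> np.ndarray:
    return (intervals["start"].to_numpy() + intervals["end"].to_numpy()) // 2


# ---------------------------------------------------------------------------
# TFBS
# ---------------------------------------------------------------------------


def generate_tfbs(
    cfg: SimConfig, enhancers: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """TF binding sites (BED-like frame) fully contained in enhancers.

    Each gene's planted module draws a TF pool of ``tf_pool_size`` factors;
    module enhancers carry each pool TF with probability
    ``shared_tf_bias``.  Every enhancer additionally receives a Poisson
    number of random factors, so sharing is never exactly zero outside
    modules.
    """
    rng = cfg.rng("tfbs")
    alphabet = np.array([f"TF{i:03d}" for i in range(cfg.tf_alphabet_size)])
    assigned: dict[str, set[str]] = {n: set() for n in enhancers["name"]}

    module_members = truth.links[truth.links["in_module"]]
    for _, grp in module_members.groupby("gene_id", sort=False):
        pool = rng.choice(alphabet, size=min(cfg.tf_pool_size, len(alphabet)), replace=False)
        for enh_id in grp["enhancer_id"]:
            take = rng.random(len(pool)) < cfg.shared_tf_bias
            assigned[enh_id].update(pool[take])
    for name in enhancers["name"]:
        n_extra = int(rng.poisson(cfg.tf_background_mean))
        if n_extra:
            assigned[name].update(rng.choice(alphabet, size=n_extra, replace=True))

    rows = []
    enh_lookup = enhancers.set_index("name")
    site_len = 12
    for name, tfs in assigned.items():
        row = enh_lookup.loc[name]
        width = int(row["end"] - row["start"]) - site_len
        for tf in sorted(tfs):
            s = int(row["start"]) + int(rng.integers(0, max(width, 1)))
            rows.append((row["chrom"], s, s + site_len, tf))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Constraint / enhancer-domain scores
# ---------------------------------------------------------------------------


def generate_scores(cfg: SimConfig, truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fake LOEUF and enhancer-domain score tables tied to planted module
    size: LOEUF decreases with module size (larger co-active modules =>
    more 'essential' gene), EDS increases."""
    rng = cfg.rng("scores")
    genes = truth.module_size.index.to_numpy()
    m = truth.module_size.to_numpy(dtype=float)
    loeuf = np.clip(1.5 - 0.12 * m + rng.normal(0, cfg.score_noise_sd, m.size), 0.03, 2.0)
    eds = 0.1 * m + rng.normal(0, cfg.score_noise_sd, m.size)
    return (
        pd.DataFrame({"gene_id": genes, "loeuf": loeuf}),
        pd.DataFrame({"gene_id": genes, "eds": eds}),
    )


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------


def write_fixture(sim: SimulatedMultiome, outdir: str | Path) -> None:
    """Write a complete text fixture (MTX + TSV + BED + contact TSVs)."""
    from . import genomic_io as gio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_binary_matrix(
        sim.expr, out / "expr.mtx", out / "expr_features.tsv", out / "barcodes.tsv"
    )
    gio.write_binary_matrix(
        sim.enh, out / "enh.mtx", out / "enh_features.tsv", out / "barcodes.tsv"
    )
    sim.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    gio.write_bed(sim.enhancers, out / "enhancers.bed")
    sim.truth.links.to_csv(out / "truth_links.tsv", sep="\t", index=False)
    sim.truth.coactive_pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    hic = generate_hic(sim.config, sim.enhancers, sim.truth)
    for chrom, df in hic.items():
        df.to_csv(out / f"hic_{chrom}.tsv", sep="\t", index=False, header=False)
    generate_tfbs(sim.config, sim.enhancers, sim.truth).to_csv(
        out / "tfbs.bed", sep="\t", index=False, header=False
    )
    loeuf, eds = generate_scores(sim.config, sim.truth)
    loeuf.to_csv(out / "loeuf.tsv", sep="\t", index=False)
    eds.to_csv(out / "eds.tsv", sep="\t", index=False)
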