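"""End-to-end orchestration: run every stage in dependency order on one
dataset and emit the stage tables plus a run report.

Stages: cis pairing -> gene-enhancer scan (permutation null) -> pair scan
over expressing cells -> partial correlation over all cells -> combination
enumeration -> enhancer-centric summary -> Hi-C support -> TF sharing ->
essentiality correlations.  All outputs are TSV; the report echoes every
parameter used alongside the headline fractions, so a run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    coactivity,
    essentiality,
    gene_enhancer,
    genomic_io as gio,
    hic_support,
    tf_sharing,
)
from .simulate import (
    SimConfig,
    SimulatedMultiome,
    generate_hic,
    generate_multiome,
    generate_scores,
    generate_tfbs,
)

logger = logging.getLogger("coact")


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the pipeline's standard settings
    (cis window 1 Mb, 5 kb Hi-C bins, 1000 shuffles, FDR 5%, |r| > 0.05,
    >= 100 expressing cells)."""

    window_bp: int = 1_000_000
    hic_resolution: int = 5000
    n_perm: int = 1000
    q_max: float = 0.05
    r_min: float = 0.05
    min_cells: int = 100
    tf_match_tolerance: float = 0.05
    seed: int = 0


@dataclass
class PipelineResult:
    associations: pd.DataFrame
    pairs: pd.DataFrame
    combinations: pd.DataFrame
    enhancer_centric: pd.DataFrame
    hic_records: pd.DataFrame
    hic_summary: dict
    tf_summary: dict
    gene_summaries: pd.DataFrame
    essentiality: pd.DataFrame
    report: dict


def run_all(
    sim: SimulatedMultiome,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on a (simulated or loaded) multiome.

    When ``outdir`` is given, every stage table is written as TSV along
    with a JSON run report.
    """
    cfg = config or PipelineConfig()
    expr, enh = sim.expr, sim.enh
    genes, enhancers = sim.genes, sim.enhancers

    assoc = gene_enhancer.scan_gene_enhancer(
        expr,
        enh,
        genes,
        enhancers,
        window=cfg.window_bp,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        q_max=cfg.q_max,
        r_min=cfg.r_min,
    )
    pairs = coactivity.pair_scan(
        expr, enh, assoc, min_cells=cfg.min_cells, q_max=cfg.q_max, r_min=cfg.r_min
    )
    pairs = coactivity.partial_scan(expr, enh, pairs)
    combos = coactivity.combination_summary(expr, enh, assoc, pairs, min_cells=cfg.min_cells)
    enh_centric = coactivity.enhancer_centric_summary(pairs)

    hic_tables = generate_hic(sim.config, enhancers, sim.truth)
    maps = {
        chrom: _map_from_frame(df, chrom, cfg.hic_resolution)
        for chrom, df in hic_tables.items()
    }
    if pairs.empty:
        hic_records = pd.DataFrame(
            columns=["pair_id", "distance_bp", "log_contact", "control_log_contact", "residual"]
        )
        hic_summary = {"n_pairs": 0}
    else:
        hic_records = hic_support.contact_records(pairs, maps)
        hic_records = hic_support.residualize_on_distance(hic_records)
        hic_summary = hic_support.support_summary(pairs, hic_records)

    tfbs = generate_tfbs(sim.config, enhancers, sim.truth)
    assignments = tf_sharing.assign_tfs(tfbs, enhancers)
    if pairs.empty:
        shared = pairs
        tf_summary = {"n_significant": 0, "n_nonsignificant": 0}
    else:
        shared = tf_sharing.sharing(pairs, assignments)
        tf_summary = tf_sharing.sharing_summary(
            shared, tolerance=cfg.tf_match_tolerance, seed=cfg.seed
        )

    loeuf, eds = generate_scores(sim.config, sim.truth)
    cis = gio.cis_window_pairs(genes, enhancers, cfg.window_bp)
    summaries = essentiality.build_gene_summaries(combos, pairs, cis, loeuf, eds)
    ess = essentiality.essentiality_correlations(summaries)

    n_tests = int(len(pairs))
    n_sig = int(pairs["significant"].sum()) if n_tests else 0
    report = {
        "config": asdict(cfg),
        "sim_config": asdict(sim.config),
        "n_genes": int(len(genes)),
        "n_enhancers": int(len(enhancers)),
        "n_cells": int(expr.n_cells),
        "n_association_tests": int(len(assoc)),
        "n_significant_associations": int(assoc["significant"].sum()) if len(assoc) else 0,
        "n_pair_tests": n_tests,
        "n_significant_pairs": n_sig,
        "pct_significant_pairs": 100.0 * n_sig / n_tests if n_tests else float("nan"),
        "mean_pct_combinations_observed": (
            float(combos["pct_observed"].mean()) if len(combos) else float("nan")
        ),
        "hic": hic_summary,
        "tf": tf_summary,
        "skipped_low_cell_genes": pairs.attrs.get("skipped_low_cell_genes", []),
    }
    result = PipelineResult(
        associations=assoc,
        pairs=shared if not pairs.empty else pairs,
        combinations=combos,
        enhancer_centric=enh_centric,
        hic_records=hic_records,
        hic_summary=hic_summary,
        tf_summary=tf_summary,
        gene_summaries=summaries,
        essentiality=ess,
        report=report,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _map_from_frame(df: pd.DataFrame, chrom: str, resolution: int) -> hic_support.ContactMap:
    cm = hic_support.ContactMap(chrom=chrom, resolution=resolution)
    for b1, b2, v in zip(df["start1"], df["start2"], df["value"]):
        cm.contacts[(min(b1, b2), max(b1, b2))] = float(v)
    return cm


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    result.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    result.combinations.to_csv(out / "combinations.tsv", sep="\t", index=False)
    result.enhancer_centric.to_csv(out / "enhancer_centric.tsv", sep="\t", index=False)
    result.hic_records.to_csv(out / "hic_records.tsv", sep="\t", index=False)
    result.gene_summaries.to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
    result.essentiality.to_csv(out / "essentiality.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def simulate_and_run(
    sim_config: SimConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[SimulatedMultiome, PipelineResult]:
    """Convenience wrapper: generate a synthetic multiome and run the
    pipeline on it."""
    scfg = sim_config or SimConfig()
    sim = generate_multiome(scfg)
    return sim, run_all(sim, pipeline_config, outdir)
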