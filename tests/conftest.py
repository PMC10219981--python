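"""Shared fixtures: one synthetic multiome with planted structure, scanned
once per session, plus small hand-built interval sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coact import coactivity, gene_enhancer
from coact.simulate import SimConfig, generate_multiome

#: default-scale study conditions used by most integration tests
STRONG_SEED = 101


@pytest.fixture(scope="session")
def sim_strong():
    return generate_multiome(SimConfig(seed=STRONG_SEED))


@pytest.fixture(scope="session")
def assoc_strong(sim_strong):
    return gene_enhancer.scan_gene_enhancer(
        sim_strong.expr,
        sim_strong.enh,
        sim_strong.genes,
        sim_strong.enhancers,
        n_perm=199,
        seed=STRONG_SEED,
    )


@pytest.fixture(scope="session")
def pairs_strong(sim_strong, assoc_strong):
    return coactivity.pair_scan(sim_strong.expr, sim_strong.enh, assoc_strong)


@pytest.fixture(scope="session")
def truth_pairs_strong(sim_strong):
    return set(
        map(
            tuple,
            sim_strong.truth.coactive_pairs[
                ["gene_id", "enhancer_a", "enhancer_b"]
            ].itertuples(index=False),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_intervals(rows):
    """rows of (chrom, start, end[, name])"""
    cols = ["chrom", "start", "end", "name"][: len(rows[0])]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def toy_gtf(tmp_path):
    """Five genes: one lincRNA, one on chrX, one inside the MHC region."""
    lines = [
        'chr1\tX\tgene\t1001\t5000\t.\t+\t.\tgene_id "G1"; gene_type "protein_coding";',
        'chr1\tX\tgene\t9001\t12000\t.\t-\t.\tgene_id "G2"; gene_type "protein_coding";',
        'chr2\tX\tgene\t501\t2000\t.\t+\t.\tgene_id "G3"; gene_type "lincRNA";',
        'chrX\tX\tgene\t101\t900\t.\t+\t.\tgene_id "G4"; gene_type "protein_coding";',
        'chr6\tX\tgene\t29999001\t30001000\t.\t+\t.\tgene_id "G5"; gene_type "protein_coding";',
        'chr3\tX\tgene\t2001\t7000\t.\t-\t.\tgene_id "G6"; gene_type "protein_coding";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
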