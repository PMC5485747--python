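"""Shared fixtures: small synthetic datasets and one full-size reference run.

The ``reference_run`` fixture executes the complete analysis once per test
session on the generator's default configuration (six studies, 2000 genes,
10% DE at ~1 log2 unit, batch noise twice the measurement noise, 20%
replicates, 5% dropout, seed 7) so recovery-style tests share the work.
"""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from emtint.cluster_eval import evaluate_grouping
from emtint.de import concordance, consensus_rank, differential_expression, select_candidates
from emtint.io import intersect_and_merge
from emtint.normalization import METHODS, normalize
from emtint.simulate import SyntheticConfig, generate_multistudy


def planted_blocks(rng: np.random.Generator, sizes, intra_corr: float, n_samples: int):
    """Genes x samples matrix of factor-model blocks with given intra-block correlation."""
    rows = []
    for size in sizes:
        factor = rng.normal(size=n_samples)
        rows.append(
            np.sqrt(intra_corr) * factor
            + np.sqrt(1.0 - intra_corr) * rng.normal(size=(size, n_samples))
        )
    return np.vstack(rows)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SyntheticConfig(
        n_genes=300, n_studies=3, samples_per_group_per_study=3,
        gene_dropout_frac=0.1, seed=11,
    )
    studies, metadata, truth = generate_multistudy(cfg)
    return SimpleNamespace(config=cfg, studies=studies, metadata=metadata, truth=truth)


@pytest.fixture(scope="session")
def reference_run():
    cfg = SyntheticConfig()  # the default study conditions, seed 7
    studies, metadata, truth = generate_multistudy(cfg)
    integrated = intersect_and_merge(studies, metadata)
    phenotype = integrated.phenotype
    normalized = {}
    for method in METHODS:
        if method == "MCtr":
            nm = normalize(studies, method, metadata=metadata)
            nm.values = nm.values[integrated.samples]
        else:
            nm = normalize(integrated, method, random_state=7)
        normalized[method] = nm
    de_tables = {
        m: differential_expression(nm.values, phenotype) for m, nm in normalized.items()
    }
    four = ["QN", "SVA", "QN_SVA", "MCtr"]
    rho, _ = concordance({m: de_tables[m]["t_statistic"].to_numpy() for m in four})
    consensus = consensus_rank({m: de_tables[m]["rank"] for m in four})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates = select_candidates(consensus, de_tables)
    bh = evaluate_grouping({m: nm.values for m, nm in normalized.items()}, phenotype)
    return SimpleNamespace(
        config=cfg, studies=studies, metadata=metadata, truth=truth,
        integrated=integrated, phenotype=phenotype, normalized=normalized,
        de_tables=de_tables, rho=rho, consensus=consensus, candidates=candidates,
        bh=bh,
    )
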