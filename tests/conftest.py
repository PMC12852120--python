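import numpy as np
import pandas as pd
import pytest

import tcms
from tcms.synthetic import GeneratorConfig, default_profiles, synthetic_registry


@pytest.fixture(scope="session")
def registry():
    return synthetic_registry(genes_per_signature=8)


@pytest.fixture(scope="session")
def small_cohort(registry):
    """A 200-sample cohort with default planted effects, shared read-only."""
    cfg = GeneratorConfig(n_samples=200, n_genes=1000, genes_per_signature=8, seed=42)
    return tcms.generate_bulk_cohort(cfg, registry)


@pytest.fixture(scope="session")
def small_scores(small_cohort, registry):
    return tcms.zscale_features(tcms.score_matrix(small_cohort.expression, registry))


@pytest.fixture(scope="session")
def small_run(small_scores):
    return tcms.consensus_cluster(small_scores, k_range=(2, 6), reps=80, seed=7)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


def ssgsea_oracle(values: dict, gene_set, alpha: float) -> float:
    """Brute-force running-sum reference for the single-sample enrichment
    score: literal walk down the ranked gene list, independent of the
    package's vectorized implementation."""
    from scipy.stats import rankdata

    genes = list(values)
    vals = [values[g] for g in genes]
    ranks = rankdata(vals)  # 1..N, average ties
    order = sorted(range(len(genes)), key=lambda i: (-ranks[i], genes[i]))
    in_set = [genes[i] in set(gene_set) for i in order]
    weights = [abs(ranks[i]) ** alpha for i in order]
    sum_w = sum(w for w, f in zip(weights, in_set) if f)
    n_out = sum(1 for f in in_set if not f)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for w, f in zip(weights, in_set):
        if f:
            cum_in += w / sum_w
        elif n_out:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score
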