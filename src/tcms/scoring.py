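"""Single-sample gene-set enrichment (ssGSEA) scoring.

The score for one sample and one gene set follows the weighted running-sum
form: genes are ranked by expression (average ranks for ties, highest
expression -> rank N), the ranked list is walked from top to bottom, and the
score is the sum over all positions of the difference between the weighted
in-set empirical CDF (weights |rank|^alpha) and the unweighted out-of-set
ECDF.  High expression of set genes therefore yields a positive score.

Scores are rank-based: they are invariant to any strictly monotone transform
of a sample's expression column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import SignatureRegistry


@dataclass
class ScoreMatrix:
    """Samples x features enrichment scores with a normalization tag."""

    scores: pd.DataFrame  # index: samples, columns: features
    normalization: str = "raw"  # raw | range-normalized | z-scored

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)

    @property
    def features(self) -> list[str]:
        return list(self.scores.columns)


def _as_sets(collection: SignatureRegistry | Mapping[str, Iterable[str]]) -> dict[str, list[str]]:
    if isinstance(collection, SignatureRegistry):
        return collection.as_dict()
    return {k: list(v) for k, v in collection.items()}


def ssgsea_sample(
    values: pd.Series | Mapping[str, float],
    gene_set: Sequence[str],
    alpha: float = 0.25,
) -> float:
    """ssGSEA score of one gene set in one sample.

    ``values`` maps gene -> expression (log2 scale; only ranks matter).
    Returns NaN with a warning when the set shares no genes with the profile.
    """
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise ValueError("missing values in expression column")
    in_set = np.asarray(s.index.isin(set(gene_set)), dtype=float)
    if in_set.sum() == 0:
        warnings.warn("gene set has no overlap with expression rows", stacklevel=2)
        return float("nan")
    ranks = s.rank(method="average").to_numpy()  # 1..N, ties averaged
    # walk genes from highest to lowest expression; tie-break by gene name
    # for determinism (ties carry equal averaged ranks, so in-set weights are
    # unaffected; only the interleaving of tied in/out genes is pinned down).
    order = np.lexsort((np.array(s.index), -ranks))
    return _running_sum(ranks[order], in_set[order], alpha)


def _running_sum(ordered_ranks: np.ndarray, ordered_in: np.ndarray, alpha: float) -> float:
    w = np.abs(ordered_ranks) ** alpha
    in_w = w * ordered_in
    denom_in = in_w.sum()
    n_out = float(len(ordered_in) - ordered_in.sum())
    p_in = np.cumsum(in_w) / denom_in
    if n_out == 0:
        p_out = np.zeros_like(p_in)
    else:
        p_out = np.cumsum(1.0 - ordered_in) / n_out
    return float(np.sum(p_in - p_out))


def score_matrix(
    expr: pd.DataFrame,
    gene_sets: SignatureRegistry | Mapping[str, Iterable[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> ScoreMatrix:
    """Score every sample of a genes x samples matrix against every gene set.

    Set members absent from the matrix rows are ignored (intersection is
    logged via warning when empty).  With ``normalize``, all scores are
    divided by the global (max - min) across the score matrix.
    """
    sets = _as_sets(gene_sets)
    if not sets:
        raise ValueError("empty gene-set collection")
    if expr.empty:
        raise ValueError("empty expression matrix")
    if expr.isna().to_numpy().any():
        raise ValueError("missing values in expression matrix")
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers")

    genes = np.array(expr.index)
    vals = expr.to_numpy(float)
    n_genes, n_samples = vals.shape
    ranks = pd.DataFrame(vals, index=expr.index).rank(axis=0, method="average").to_numpy()
    membership = {}
    for name, members in sets.items():
        mask = np.isin(genes, np.asarray(list(members), dtype=genes.dtype))
        if not mask.any():
            warnings.warn(f"gene set {name!r} has no overlap with expression rows", stacklevel=2)
        membership[name] = mask.astype(float)

    out = np.full((n_samples, len(sets)), np.nan)
    gene_order_key = np.argsort(genes, kind="stable")
    rank_of_name = np.empty(n_genes)
    rank_of_name[gene_order_key] = np.arange(n_genes)  # lexicographic tie-break key
    for j in range(n_samples):
        order = np.lexsort((rank_of_name, -ranks[:, j]))
        r = ranks[order, j]
        w = np.abs(r) ** alpha
        for i, (name, mask) in enumerate(membership.items()):
            m = mask[order]
            if m.sum() == 0:
                continue
            in_w = w * m
            p_in = np.cumsum(in_w) / in_w.sum()
            n_out = n_genes - m.sum()
            p_out = np.cumsum(1.0 - m) / n_out if n_out else np.zeros(n_genes)
            out[j, i] = np.sum(p_in - p_out)
    df = pd.DataFrame(out, index=expr.columns, columns=list(sets))
    tag = "raw"
    if normalize:
        rng = np.nanmax(out) - np.nanmin(out)
        if rng > 0:
            df = df / rng
        tag = "range-normalized"
    return ScoreMatrix(scores=df, normalization=tag)


def zscale_features(scores: ScoreMatrix) -> ScoreMatrix:
    """Standardize each feature column to mean 0, SD 1 (population SD).

    Constant columns become all zeros with a warning.  Idempotent on
    already-standardized input.
    """
    df = scores.scores
    if df.shape[0] < 2:
        raise ValueError("z-scaling needs >= 2 samples")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"constant feature column(s) set to zero: {list(df.columns[const])}", stacklevel=2)
    sd = sd.replace(0, 1.0)
    z = (df - mean) / sd
    z.loc[:, const] = 0.0
    return ScoreMatrix(scores=z, normalization="z-scored")
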