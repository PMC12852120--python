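"""Resampled consensus clustering of TCMS scores and subtype labeling.

Samples are clustered by PAM (k-medoids) on z-scored feature profiles under
repeated subsampling (default: 80% of samples per repetition, all features).
The consensus matrix entry for a pair is the fraction of co-sampled
repetitions in which the pair co-clustered.  k is selected over a range by
the delta-area rule on the consensus CDF, with an explicit override because
the number of subtypes is ultimately a judgment call.  At k = 4 the clusters
are mapped to the biological subtype labels:

* HPI — highest mean aggression z (solid/micropapillary, metastasis,
  tumor proliferation, matrix remodeling);
* LPI — highest GGO/lepidic z among the remaining clusters;
* IME / IMD — of the final two, the higher / lower mean immunity z
  (CD8 T, NK, B cells).

External cohorts scored on the same registry are assigned by nearest
centroid (Spearman correlation by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .scoring import ScoreMatrix
from .signatures import SignatureRegistry

SUBTYPES = ("LPI", "IMD", "IME", "HPI")

AGGRESSION_FEATURES = ("solid_micropapillary", "metastasis", "tumor_proliferation", "matrix_remodeling")
INDOLENCE_FEATURES = ("GGO_lepidic",)
IMMUNITY_FEATURES = ("CD8_T", "NK", "B_cell")


# ---------------------------------------------------------------------------
# PAM (k-medoids) on a precomputed distance matrix
# ---------------------------------------------------------------------------

def _kmedoidspp_init(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids++ seeding: subsequent medoids drawn with probability
    proportional to squared distance to the nearest chosen medoid."""
    n = dist.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(dist[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total == 0:  # fewer distinct points than k: fall back to uniform
            candidates = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(candidates)))
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    return np.array(medoids)


def pam_labels(dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """k-medoids clustering of a symmetric distance matrix.

    Alternating (Voronoi) updates: assign each point to its nearest medoid,
    then re-pick each cluster's medoid as the member minimizing total
    within-cluster distance; iterate to a fixed point.
    """
    n = dist.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of samples ({n})")
    medoids = _kmedoidspp_init(dist, k, rng)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster at the worst-served point
                worst = int(np.argmax(np.min(dist[:, new_medoids], axis=1)))
                new_medoids[c] = worst
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusRun:
    consensus: dict[int, pd.DataFrame]  # per-k samples x samples in [0,1]
    cosample_counts: pd.DataFrame
    labels: dict[int, pd.Series]  # per-k final labels (cluster indices)
    params: dict = field(default_factory=dict)


@dataclass
class KSelection:
    areas: dict[int, float]
    delta_areas: dict[int, float]
    pac: dict[int, float]
    chosen_k: int
    override: bool = False


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample -> subtype name
    cluster_map: dict[int, str]
    cluster_means: pd.DataFrame  # clusters x features mean z


@dataclass
class SubtypeCentroids:
    centroids: pd.DataFrame  # 4 x features mean z-scores, indexed by subtype


def consensus_cluster(
    scores: ScoreMatrix,
    k_range: range | tuple[int, int] = (2, 10),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
) -> ConsensusRun:
    """Resampled PAM consensus clustering of a (z-scored) score matrix.

    For each repetition, floor(p_item * n) samples (and floor(p_feature * p)
    features) are subsampled and PAM is run for every k; consensus(i, j) =
    co-cluster count / co-sample count.  Final per-k labels come from PAM on
    (1 - consensus) as a distance.  Deterministic given the seed.
    """
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    df = scores.scores
    n, p = df.shape
    if max(ks) >= n:
        raise ValueError(f"max k ({max(ks)}) must be < n samples ({n})")
    if n < 2 * max(ks):
        raise ValueError("need at least 2*max(k) samples")
    x = df.to_numpy(float)
    rng = np.random.default_rng(seed)
    n_sub = int(np.floor(p_item * n))
    p_sub = max(1, int(np.floor(p_feature * p)))

    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False)) if n_sub < n else np.arange(n)
        feats = np.sort(rng.choice(p, size=p_sub, replace=False)) if p_sub < p else np.arange(p)
        sub = x[np.ix_(idx, feats)]
        dist = cdist(sub, sub)
        co_sample[np.ix_(idx, idx)] += 1
        for k in ks:
            labels = pam_labels(dist, k, rng)
            for c in range(k):
                members = idx[labels == c]
                co_cluster[k][np.ix_(members, members)] += 1

    if (co_sample == 0).any():
        warnings.warn("some sample pairs were never co-sampled; their consensus is undefined (0)", stacklevel=2)
    denom = np.where(co_sample > 0, co_sample, 1.0)
    consensus = {}
    final_labels = {}
    for k in ks:
        cmat = co_cluster[k] / denom
        np.fill_diagonal(cmat, 1.0)
        cmat = (cmat + cmat.T) / 2
        consensus[k] = pd.DataFrame(cmat, index=df.index, columns=df.index)
        final = pam_labels(1.0 - cmat, k, rng)
        final_labels[k] = pd.Series(final, index=df.index, name=f"k{k}")
    return ConsensusRun(
        consensus=consensus,
        cosample_counts=pd.DataFrame(co_sample, index=df.index, columns=df.index),
        labels=final_labels,
        params={"k_range": ks, "reps": reps, "p_item": p_item, "p_feature": p_feature, "seed": seed},
    )


def _cdf_area(cmat: pd.DataFrame) -> float:
    """Area under the empirical CDF of the upper-triangle consensus entries.

    For a variable supported on [0, 1], the integral of the CDF equals
    1 - mean, which is used exactly instead of a binned approximation.
    """
    vals = cmat.to_numpy()
    iu = np.triu_indices_from(vals, k=1)
    return float(1.0 - vals[iu].mean())


def _pac(cmat: pd.DataFrame, lo: float = 0.1, hi: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus in (lo, hi)."""
    vals = cmat.to_numpy()
    iu = np.triu_indices_from(vals, k=1)
    x = vals[iu]
    return float(((x > lo) & (x < hi)).mean())


def select_k(
    run: ConsensusRun,
    threshold: float = 0.1,
    pac_crisp: float = 0.05,
    override: int | None = None,
) -> KSelection:
    """Delta-area elbow rule on the consensus CDF, with a crispness refinement.

    delta(k=2) = A_2; delta(k>=3) = (A_k - A_{k-1}) / A_{k-1}.  The baseline
    choice is the largest k with delta >= ``threshold``.  When some
    delta-eligible k yields an essentially unambiguous consensus matrix
    (PAC, the fraction of off-diagonal entries in (0.1, 0.9), at most
    ``pac_crisp``), the largest such k is preferred instead: the raw CDF
    area grows whenever clusters fragment — stably or not — so on sharply
    separated data the delta alone over-counts forced splits of true
    clusters, while the PAC pinpoints the partition the resampling actually
    agrees on.  ``override`` pins k.
    """
    ks = sorted(run.consensus)
    if len(ks) < 2:
        raise ValueError("need at least two k values")
    areas = {k: _cdf_area(run.consensus[k]) for k in ks}
    pac = {k: _pac(run.consensus[k]) for k in ks}
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    if override is not None:
        return KSelection(areas=areas, delta_areas=deltas, pac=pac, chosen_k=int(override), override=True)
    delta_ok = [k for k in ks if deltas[k] >= threshold]
    crisp = [k for k in delta_ok if pac[k] <= pac_crisp]
    if crisp:
        chosen = max(crisp)
    elif delta_ok:
        chosen = max(delta_ok)
    else:
        chosen = ks[0]
    return KSelection(areas=areas, delta_areas=deltas, pac=pac, chosen_k=chosen)


def label_subtypes(
    run: ConsensusRun,
    scores: ScoreMatrix,
    registry: SignatureRegistry | None = None,
    k: int = 4,
) -> SubtypeAssignment:
    """Map the k=4 clusters to LPI / IMD / IME / HPI by feature-group means.

    Aggression = mean z over solid/micropapillary, metastasis, proliferation
    and matrix remodeling; indolence = GGO/lepidic z; immunity = mean z over
    CD8 T, NK and B cells.  HPI = argmax aggression; LPI = argmax indolence
    among the rest; of the final two, IME has the higher immunity.  Exact
    ties raise rather than being silently broken.
    """
    if k != 4:
        raise ValueError("biological labeling is defined for k=4")
    if k not in run.labels:
        raise ValueError(f"run has no k={k} clustering")
    cl = run.labels[k]
    df = scores.scores.loc[cl.index]
    means = df.groupby(cl).mean()
    for feats in (AGGRESSION_FEATURES, INDOLENCE_FEATURES, IMMUNITY_FEATURES):
        missing = [f for f in feats if f not in df.columns]
        if missing:
            raise ValueError(f"score matrix lacks labeling features: {missing}")

    def _argmax(series: pd.Series, what: str) -> int:
        top = series.max()
        winners = series.index[series == top]
        if len(winners) > 1:
            raise ValueError(f"exact tie in {what} between clusters {list(winners)}; manual mapping required")
        return int(winners[0])

    aggression = means[list(AGGRESSION_FEATURES)].mean(axis=1)
    hpi = _argmax(aggression, "aggression")
    rest = means.drop(index=hpi)
    indolence = rest[list(INDOLENCE_FEATURES)].mean(axis=1)
    lpi = _argmax(indolence, "indolence")
    last_two = rest.drop(index=lpi)
    immunity = last_two[list(IMMUNITY_FEATURES)].mean(axis=1)
    ime = _argmax(immunity, "immunity")
    imd = int(last_two.drop(index=ime).index[0])
    cluster_map = {hpi: "HPI", lpi: "LPI", ime: "IME", imd: "IMD"}
    labels = cl.map(cluster_map)
    labels.name = "subtype"
    return SubtypeAssignment(labels=labels, cluster_map=cluster_map, cluster_means=means)


def fit_centroids(assignment: SubtypeAssignment, scores: ScoreMatrix) -> SubtypeCentroids:
    """Per-subtype mean z-score profile over the 20 features."""
    df = scores.scores.loc[assignment.labels.index]
    cent = df.groupby(assignment.labels).mean()
    cent = cent.reindex([s for s in SUBTYPES if s in cent.index])
    return SubtypeCentroids(centroids=cent)


def classify_external(
    new_scores: ScoreMatrix,
    centroids: SubtypeCentroids,
    metric: str = "spearman",
) -> tuple[pd.Series, pd.Series]:
    """Nearest-centroid subtype assignment for an externally scored cohort.

    Features are matched by name; the similarity is Spearman correlation
    (default) or negative Euclidean distance.  Returns (labels, margins)
    where margin = best minus second-best similarity.  Ties resolve in the
    fixed order LPI < IMD < IME < HPI with a warning.
    """
    cent = centroids.centroids
    missing = [f for f in cent.columns if f not in new_scores.scores.columns]
    if missing:
        raise ValueError(f"new cohort is missing features: {missing}")
    x = new_scores.scores[cent.columns].to_numpy(float)
    c = cent.to_numpy(float)
    if metric == "spearman":
        xr = np.apply_along_axis(rankdata, 1, x)
        cr = np.apply_along_axis(rankdata, 1, c)
        xs = (xr - xr.mean(axis=1, keepdims=True)) / xr.std(axis=1, keepdims=True)
        cs = (cr - cr.mean(axis=1, keepdims=True)) / cr.std(axis=1, keepdims=True)
        sim = xs @ cs.T / x.shape[1]
    elif metric == "euclidean":
        sim = -cdist(x, c)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = {name: i for i, name in enumerate(SUBTYPES)}
    pref = np.array([order.get(name, len(SUBTYPES)) for name in cent.index])
    labels, margins = [], []
    tie_seen = False
    for row in sim:
        top = row.max()
        winners = np.flatnonzero(row == top)
        if len(winners) > 1:
            tie_seen = True
            winners = winners[np.argsort(pref[winners])]
        best = winners[0]
        second = np.sort(row)[-2] if len(row) > 1 else top
        labels.append(cent.index[best])
        margins.append(top - second)
    if tie_seen:
        warnings.warn("similarity tie(s) resolved in fixed subtype order", stacklevel=2)
    idx = new_scores.scores.index
    return pd.Series(labels, index=idx, name="subtype"), pd.Series(margins, index=idx, name="margin")
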