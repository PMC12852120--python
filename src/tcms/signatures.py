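"""Construction of the 20-feature TCMS signature registry.

The registry couples three clinico-pathological gene signatures derived by
differential expression (GGO/lepidic, solid/micropapillary, metastasis) with
17 tumor-microenvironment signatures assembled by consensus voting across
marker-gene sources (deconvolution method marker lists, single-cell datasets,
and published signatures).  The voting tiers are:

* nine cell types selected when a gene appears in at least 4 of 9 sources
  (7 deconvolution methods + 2 single-cell datasets);
* three cell types with thin literature, selected at >= 2 publications;
* four single-source features (myeloid, tumor proliferation rate, matrix
  remodeling, angiogenesis);
* EMT, selected when a gene appears in at least 1/5 of the surveyed papers.

Single-cell marker nomination is supported by the QC filter and per-cluster
differential-expression rule (log2FC >= 1, p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import read_gmt, write_gmt

# Canonical feature names, grouped by how their gene lists are assembled.
CLINICAL_FEATURES = ("GGO_lepidic", "solid_micropapillary", "metastasis")
TME_VOTED_4_OF_9 = (
    "CD8_T",
    "CD4_T",
    "B_cell",
    "Treg",
    "NK",
    "macrophage",
    "CAF",
    "endothelial",
    "neutrophil",
)
TME_VOTED_2_PUBS = ("T_helper", "M1_macrophage", "dendritic_cell")
TME_SINGLE_SOURCE = ("myeloid", "tumor_proliferation", "matrix_remodeling", "angiogenesis")
TME_FRACTION_VOTED = ("EMT",)
TME_FEATURES = TME_VOTED_4_OF_9 + TME_VOTED_2_PUBS + TME_SINGLE_SOURCE + TME_FRACTION_VOTED
ALL_FEATURES = CLINICAL_FEATURES + TME_FEATURES

_PROCESS_FEATURES = {"tumor_proliferation", "matrix_remodeling", "angiogenesis", "EMT"}


def feature_category(name: str) -> str:
    if name in CLINICAL_FEATURES:
        return "clinical"
    if name in _PROCESS_FEATURES:
        return "tme_process"
    return "tme_cell"


@dataclass
class GeneSignature:
    """A named, ordered gene list with per-gene provenance votes."""

    name: str
    genes: list[str]
    category: str = "tme_cell"
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.category not in ("clinical", "tme_cell", "tme_process"):
            raise ValueError(f"unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureRegistry:
    """The ordered collection of gene signatures used for TCMS scoring."""

    signatures: list[GeneSignature]
    version: str = "synthetic-0"

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(names) != len(set(names)):
            raise ValueError("duplicate signature names in registry")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.signatures:
            for g in s.genes:
                seen.setdefault(g, None)
        return list(seen)

    def as_dict(self) -> dict[str, list[str]]:
        return {s.name: list(s.genes) for s in self.signatures}

    def to_gmt(self, path) -> None:
        write_gmt(self.as_dict(), path, descriptions={s.name: s.category for s in self.signatures})

    @classmethod
    def from_gmt(cls, path, version: str = "gmt") -> "SignatureRegistry":
        sets = read_gmt(path)
        sigs = [
            GeneSignature(name=n, genes=g, category=feature_category(n) if n in ALL_FEATURES else "tme_cell")
            for n, g in sets.items()
        ]
        return cls(signatures=sigs, version=version)


@dataclass
class MarkerSourceSet:
    """One marker-gene source: a deconvolution method, a single-cell dataset,
    or a publication, mapping cell type / feature name -> gene set."""

    source_id: str
    kind: str  # "deconvolution-method" | "single-cell-dataset" | "publication"
    markers: dict[str, set[str]]


@dataclass
class VotingRule:
    """Inclusion rule for one feature: an absolute or fractional vote count
    over a named pool of sources.  Exactly one of min_sources / min_fraction
    is set; both boundaries are inclusive."""

    feature: str
    min_sources: int | None = None
    min_fraction: float | None = None
    pool: list[str] | None = None  # source ids; None = all provided sources

    def __post_init__(self) -> None:
        if (self.min_sources is None) == (self.min_fraction is None):
            raise ValueError("exactly one of min_sources / min_fraction must be set")


@dataclass
class DifferentialResult:
    """Per-gene two-group comparison on log2 expression."""

    table: pd.DataFrame  # index: gene; columns: log2fc, p_value, p_adjusted, mean_a, mean_b
    group_a: list[str]
    group_b: list[str]


@dataclass
class ScQcThresholds:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.05
    max_genes_per_cell: int = 2500  # cells with detected genes >= this are removed

    def __post_init__(self) -> None:
        if min(self.min_cells_per_gene, self.min_genes_per_cell, self.max_genes_per_cell) <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.max_mito_fraction <= 0:
            raise ValueError("QC thresholds must be positive")


def vote_markers(
    celltype: str,
    sources: Sequence[MarkerSourceSet],
    rule: VotingRule,
) -> GeneSignature:
    """Select marker genes for ``celltype`` by consensus voting over sources.

    A gene is included iff its vote count meets the rule's boundary
    (inclusive): ``count >= min_sources`` or ``count / pool_size >=
    min_fraction``.  Provenance records every source that voted for each
    included gene.
    """
    if not sources:
        raise ValueError("empty source list")
    if rule.pool is not None:
        ids = {s.source_id for s in sources}
        missing = [p for p in rule.pool if p not in ids]
        if missing:
            raise ValueError(f"rule pool references unknown sources: {missing}")
        pool = [s for s in sources if s.source_id in set(rule.pool)]
    else:
        pool = list(sources)
    if not pool:
        raise ValueError("empty source pool after filtering")

    votes: dict[str, list[str]] = {}
    for src in pool:
        for gene in src.markers.get(celltype, ()):  # sources lacking the type abstain
            votes.setdefault(gene, []).append(src.source_id)

    n_pool = len(pool)
    selected = []
    for gene in sorted(votes):
        count = len(votes[gene])
        if rule.min_sources is not None:
            ok = count >= rule.min_sources
        else:
            ok = count / n_pool >= rule.min_fraction
        if ok:
            selected.append(gene)
    return GeneSignature(
        name=rule.feature,
        genes=selected,
        category=feature_category(rule.feature) if rule.feature in ALL_FEATURES else "tme_cell",
        provenance={g: sorted(votes[g]) for g in selected},
    )


def differential_expression(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> DifferentialResult:
    """Per-gene Welch t-test of group A vs group B on a log2-scale matrix.

    log2 fold change = mean(A) - mean(B) (already a log-ratio on log2 data).
    p-values are two-sided; BH adjustment is applied over all tested genes.
    Zero-variance genes with equal group means get p = 1 (p = 0 if the means
    differ, since the difference is then noise-free).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = expr[group_a].to_numpy(float)
    b = expr[group_b].to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values in expression matrix")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(pvals, float)
    degenerate = np.isnan(pvals)
    if degenerate.any():
        equal = np.isclose(mean_a, mean_b)
        pvals[degenerate & equal] = 1.0
        pvals[degenerate & ~equal] = 0.0
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": mean_a - mean_b,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=expr.index,
    )
    return DifferentialResult(table=table, group_a=group_a, group_b=group_b)


def derive_de_signature(
    result: DifferentialResult,
    name: str = "de_signature",
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    use_adjusted: bool = False,
    exclusion_list: Iterable[str] = (),
    category: str = "clinical",
) -> GeneSignature:
    """Turn a differential result into an up-regulated gene signature.

    Keeps genes with log2FC >= lfc_min and (adjusted or raw) p < p_max,
    removes ``exclusion_list`` members, and orders by descending log2FC with
    lexicographic tie-breaking.  An empty outcome is allowed but warned about.
    """
    tab = result.table
    pcol = "p_adjusted" if use_adjusted else "p_value"
    mask = (tab["log2fc"] >= lfc_min) & (tab[pcol] < p_max)
    excl = set(exclusion_list)
    passing = tab.loc[mask & ~tab.index.isin(excl)]
    order = sorted(passing.index, key=lambda g: (-passing.at[g, "log2fc"], g))
    if not order:
        warnings.warn(f"derived signature {name!r} is empty", stacklevel=2)
    return GeneSignature(name=name, genes=order, category=category)


def qc_filter_cells(
    counts: pd.DataFrame,
    mito_genes: Iterable[str],
    thresholds: ScQcThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the single-cell QC cascade to a cells x genes count matrix.

    Order: (1) keep genes expressed in >= min_cells_per_gene cells; (2) keep
    cells expressing >= min_genes_per_cell genes; (3) keep cells with
    mitochondrial count fraction <= max_mito_fraction; (4) keep cells whose
    detected-gene count is strictly below max_genes_per_cell.  Returns the
    filtered matrix and the number of genes/cells removed at each step.
    """
    thresholds = thresholds or ScQcThresholds()
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be nonnegative")
    report: dict[str, int] = {"genes_low_cells": 0, "cells_low_genes": 0, "cells_high_mito": 0, "cells_high_genes": 0}
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        return counts.copy(), report

    expressed = (counts > 0).sum(axis=0)
    keep_genes = expressed[expressed >= thresholds.min_cells_per_gene].index
    report["genes_low_cells"] = counts.shape[1] - len(keep_genes)
    counts = counts[keep_genes]

    detected = (counts > 0).sum(axis=1)
    keep = detected >= thresholds.min_genes_per_cell
    report["cells_low_genes"] = int((~keep).sum())
    counts = counts.loc[keep]

    mito = [g for g in mito_genes if g in counts.columns]
    total = counts.sum(axis=1)
    mito_frac = counts[mito].sum(axis=1) / total.replace(0, np.nan) if mito else pd.Series(0.0, index=counts.index)
    mito_frac = mito_frac.fillna(0.0)
    keep = mito_frac <= thresholds.max_mito_fraction
    report["cells_high_mito"] = int((~keep).sum())
    counts = counts.loc[keep]

    detected = (counts > 0).sum(axis=1)
    keep = detected < thresholds.max_genes_per_cell
    report["cells_high_genes"] = int((~keep).sum())
    counts = counts.loc[keep]

    return counts, report


def build_default_registry(
    clinical_sigs: Sequence[GeneSignature],
    source_sets: Sequence[MarkerSourceSet],
    rules: Mapping[str, VotingRule],
    version: str = "voted-0",
) -> SignatureRegistry:
    """Assemble the full 20-feature registry: 3 clinical + 17 voted TME slots.

    ``rules`` must provide a VotingRule for each TME feature name; any slot
    that cannot be filled (missing rule, or no genes survive the vote) raises
    an error naming the slot.
    """
    by_name = {s.name: s for s in clinical_sigs}
    missing = [n for n in CLINICAL_FEATURES if n not in by_name]
    if missing:
        raise ValueError(f"missing clinical signature slot(s): {missing}")
    sigs: list[GeneSignature] = []
    for n in CLINICAL_FEATURES:
        s = by_name[n]
        sigs.append(GeneSignature(name=n, genes=list(s.genes), category="clinical", provenance=dict(s.provenance)))
    for feat in TME_FEATURES:
        if feat not in rules:
            raise ValueError(f"missing voting rule for slot: {feat}")
        try:
            sig = vote_markers(feat, source_sets, rules[feat])
        except ValueError as exc:
            raise ValueError(f"cannot fill slot {feat}: {exc}") from exc
        if not sig.genes:
            raise ValueError(f"cannot fill slot {feat}: no genes survive the vote")
        sigs.append(sig)
    registry = SignatureRegistry(signatures=sigs, version=version)
    assert len(registry) == 20
    return registry


def default_voting_rules() -> dict[str, VotingRule]:
    """The canonical voting tiers, over all provided sources per feature.

    Pools default to "all sources that define the feature's kind of
    evidence"; callers narrow with explicit pools when mixing source kinds.
    """
    rules: dict[str, VotingRule] = {}
    for f in TME_VOTED_4_OF_9:
        rules[f] = VotingRule(feature=f, min_sources=4)
    for f in TME_VOTED_2_PUBS:
        rules[f] = VotingRule(feature=f, min_sources=2)
    for f in TME_SINGLE_SOURCE:
        rules[f] = VotingRule(feature=f, min_sources=1)
    rules["EMT"] = VotingRule(feature="EMT", min_fraction=0.2)
    return rules
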