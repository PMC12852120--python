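"""Genomic alteration analysis.

Four groups of machinery:

* an actionable-hotspot rule engine over MAF-like mutation and fusion
  tables, with the NCCN (v5.2022) lung adenocarcinoma list as the default
  rule set (EGFR G719 / exon-19 deletion / exon-20 insertion / S768I /
  L858R / L861Q, KRAS G12C, BRAF V600E, ERBB2 exon-20 insertion, and
  ALK / ROS1 / MET / RET fusions);
* pairwise co-occurrence / mutual-exclusivity testing of binary event
  matrices by the exact two-sided Fisher test, and group-wise event
  frequency comparison;
* the 32-category structural-variant taxonomy — {DEL, DUP, INV} x five
  size bins (1-10 Kb, 10-100 Kb, 100 Kb-1 Mb, 1-10 Mb, >10 Mb) plus
  unbinned TRA, each split clustered / non-clustered — and per-sample
  catalogs over it;
* NMF signature extraction from catalogs (KL multiplicative updates,
  replicate-stability rank selection) and NNLS refitting of known
  signature catalogs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .subtyping import pam_labels

# ---------------------------------------------------------------------------
# Hotspot rule engine
# ---------------------------------------------------------------------------

_MISSENSE_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class CodonRule:
    """Match a missense mutation at gene/codon (any alt unless specified)."""

    gene: str
    position: int
    ref_aa: str
    alt_aa: str | None = None
    exon: int | None = None

    def describe(self) -> str:
        alt = self.alt_aa or ""
        return f"{self.gene} p.{self.ref_aa}{self.position}{alt or '*'}"


@dataclass(frozen=True)
class ExonClassRule:
    """Match any mutation of a given class within a gene exon."""

    gene: str
    exon: int
    variant_class: str

    def describe(self) -> str:
        return f"{self.gene} exon {self.exon} {self.variant_class}"


@dataclass(frozen=True)
class FusionRule:
    """Match a fusion involving the gene as either partner."""

    gene: str

    def describe(self) -> str:
        return f"{self.gene} fusion"


HotspotRule = CodonRule | ExonClassRule | FusionRule


@dataclass
class HotspotRuleSet:
    rules: list[HotspotRule]

    @property
    def mutation_rules(self) -> list[HotspotRule]:
        return [r for r in self.rules if not isinstance(r, FusionRule)]

    @property
    def fusion_rules(self) -> list[FusionRule]:
        return [r for r in self.rules if isinstance(r, FusionRule)]


def default_nccn_ruleset() -> HotspotRuleSet:
    """The NCCN v5.2022 actionable-alteration list for LUAD."""
    return HotspotRuleSet(
        rules=[
            CodonRule("EGFR", 719, "G", None, exon=18),
            ExonClassRule("EGFR", 19, "inframe_del"),
            ExonClassRule("EGFR", 20, "inframe_ins"),
            CodonRule("EGFR", 768, "S", "I", exon=20),
            CodonRule("EGFR", 858, "L", "R", exon=21),
            CodonRule("EGFR", 861, "L", "Q"),
            CodonRule("KRAS", 12, "G", "C"),
            CodonRule("BRAF", 600, "V", "E"),
            ExonClassRule("ERBB2", 20, "inframe_ins"),
            FusionRule("ALK"),
            FusionRule("ROS1"),
            FusionRule("MET"),
            FusionRule("RET"),
        ]
    )


def parse_protein_change(change: str) -> tuple[str, int, str] | None:
    """Parse a single-letter HGVS short form 'p.<ref><pos><alt>'; None if not."""
    if not isinstance(change, str):
        return None
    m = _MISSENSE_RE.match(change.strip())
    if m is None:
        return None
    return m.group(1), int(m.group(2)), m.group(3)


def _match_mutation(row: pd.Series, rule: HotspotRule) -> bool:
    if isinstance(rule, FusionRule):
        return False
    if row["gene"] != rule.gene:
        return False
    if isinstance(rule, ExonClassRule):
        return row["exon"] == rule.exon and row["variant_class"] == rule.variant_class
    # CodonRule: requires a parseable missense protein change
    if row["variant_class"] != "missense":
        return False
    parsed = parse_protein_change(row["protein_change"])
    if parsed is None:
        warnings.warn(
            f"unparseable protein change {row['protein_change']!r} for {row['gene']}; record skipped",
            stacklevel=3,
        )
        return False
    ref, pos, alt = parsed
    if pos != rule.position or ref != rule.ref_aa:
        return False
    if rule.exon is not None and not pd.isna(row["exon"]) and int(row["exon"]) != rule.exon:
        return False
    return rule.alt_aa is None or alt == rule.alt_aa


def call_hotspot_status(
    mutations: pd.DataFrame,
    fusions: pd.DataFrame,
    rules: HotspotRuleSet | None = None,
) -> tuple[str, list[str]]:
    """Classify one sample's alterations as hotspot positive/negative.

    ``mutations`` / ``fusions`` hold only the sample's records.  Returns the
    status and the descriptions of every matched rule (provenance).
    """
    rules = rules or default_nccn_ruleset()
    matched: list[str] = []
    for _, row in mutations.iterrows():
        for rule in rules.mutation_rules:
            if _match_mutation(row, rule):
                matched.append(rule.describe())
    fusion_genes = {r.gene for r in rules.fusion_rules}
    for _, row in fusions.iterrows():
        for g in (row["gene_a"], row["gene_b"]):
            if g in fusion_genes:
                matched.append(f"{g} fusion")
    status = "positive" if matched else "negative"
    return status, matched


def hotspot_status_table(
    mutations: pd.DataFrame,
    fusions: pd.DataFrame,
    samples: Sequence[str],
    rules: HotspotRuleSet | None = None,
) -> pd.Series:
    """Per-sample hotspot status over a cohort."""
    rules = rules or default_nccn_ruleset()
    mut_by = dict(tuple(mutations.groupby("sample"))) if len(mutations) else {}
    fus_by = dict(tuple(fusions.groupby("sample"))) if len(fusions) else {}
    empty_mut = mutations.iloc[0:0]
    empty_fus = fusions.iloc[0:0]
    out = {}
    for s in samples:
        status, _ = call_hotspot_status(mut_by.get(s, empty_mut), fus_by.get(s, empty_fus), rules)
        out[s] = status
    return pd.Series(out, name="hotspot_status")


# ---------------------------------------------------------------------------
# Fisher exact association testing
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of the table [[a, b], [c, d]].

    The p-value sums, over the hypergeometric support with fixed margins,
    the probabilities of all tables at most as probable as the observed one
    (with a 1 + 1e-7 relative slack on the comparison, the standard guard
    against floating-point ties).  Returns (odds_ratio, p); the odds ratio
    is the exact sample ratio a*d / (b*c), with inf / 0 representable.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    n = a + b + c + d
    if n == 0:
        return 1.0, 1.0
    row1, col1 = a + b, a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if (b > 0 or c > 0) else np.nan)
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


@dataclass
class PairwiseAssociation:
    table: pd.DataFrame  # one row per event pair


def pairwise_association(event_matrix: pd.DataFrame) -> PairwiseAssociation:
    """Fisher co-occurrence / mutual-exclusivity over all event pairs.

    ``event_matrix`` is binary events x samples.  Direction is called from
    the odds ratio (co-occurrent > 1, exclusive < 1); constant events give
    an undefined association reported as 'none' with a note.  BH adjustment
    runs across all testable pairs.
    """
    m = event_matrix.astype(bool)
    if m.shape[1] < 1:
        raise ValueError("need at least one sample")
    events = list(m.index)
    rows = []
    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            ei, ej = m.loc[events[i]].to_numpy(), m.loc[events[j]].to_numpy()
            a = int((ei & ej).sum())
            b = int((ei & ~ej).sum())
            c = int((~ei & ej).sum())
            d = int((~ei & ~ej).sum())
            note = ""
            if ei.all() or (~ei).all() or ej.all() or (~ej).all():
                rows.append((events[i], events[j], a, b, c, d, np.nan, np.nan, "none", "constant event"))
                continue
            odds, p = fisher_exact_2x2(a, b, c, d)
            if p < 0.05:
                direction = "co-occurrent" if odds > 1 else ("exclusive" if odds < 1 else "none")
            else:
                direction = "none"
            rows.append((events[i], events[j], a, b, c, d, odds, p, direction, note))
    tab = pd.DataFrame(
        rows,
        columns=["event_a", "event_b", "both", "a_only", "b_only", "neither", "odds_ratio", "p_value", "direction", "note"],
    )
    tab["p_adjusted"] = np.nan
    tested = tab["p_value"].notna()
    if tested.any():
        tab.loc[tested, "p_adjusted"] = multipletests(tab.loc[tested, "p_value"], method="fdr_bh")[1]
    return PairwiseAssociation(table=tab)


def compare_event_frequencies(
    group_a: Sequence[str],
    group_b: Sequence[str],
    event_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Per-event Fisher test of mutation frequency between two sample groups."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    m = event_matrix.astype(bool)
    rows = []
    for event in m.index:
        va = m.loc[event, group_a].to_numpy()
        vb = m.loc[event, group_b].to_numpy()
        a, b = int(va.sum()), int(len(va) - va.sum())
        c, d = int(vb.sum()), int(len(vb) - vb.sum())
        note = ""
        if a + c == 0:
            odds, p = 1.0, 1.0
            note = "event absent in both groups"
        else:
            odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append((event, a, len(va), c, len(vb), odds, p, note))
    tab = pd.DataFrame(
        rows,
        columns=["event", "count_a", "n_a", "count_b", "n_b", "odds_ratio", "p_value", "note"],
    )
    tab["p_adjusted"] = multipletests(tab["p_value"], method="fdr_bh")[1]
    return tab


# ---------------------------------------------------------------------------
# Structural-variant taxonomy
# ---------------------------------------------------------------------------

SV_INTRA_TYPES = ("DEL", "DUP", "INV")
SV_SIZE_BINS = ((0, 10_000), (10_000, 100_000), (100_000, 1_000_000), (1_000_000, 10_000_000), (10_000_000, np.inf))
SV_SIZE_BIN_LABELS = ("1-10Kb", "10-100Kb", "100Kb-1Mb", "1Mb-10Mb", ">10Mb")
SV_CLUSTER_FACTOR = 10.0  # clustered iff nearest other-event breakpoint < mean gap / factor


def sv_category_names() -> list[str]:
    """The canonical 32-category order: per clustered status (non-clustered
    first), DEL x 5 bins, DUP x 5 bins, INV x 5 bins, then TRA."""
    names = []
    for status in ("non-clustered", "clustered"):
        for t in SV_INTRA_TYPES:
            for lbl in SV_SIZE_BIN_LABELS:
                names.append(f"{status}_{t}_{lbl}")
        names.append(f"{status}_TRA")
    return names


SV_CATEGORIES = sv_category_names()
assert len(SV_CATEGORIES) == 32


@dataclass
class SvRecord:
    sample: str
    svtype: str  # DEL | DUP | INV | TRA
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    def __post_init__(self) -> None:
        if self.svtype not in (*SV_INTRA_TYPES, "TRA"):
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.svtype == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("TRA must join two chromosomes")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.svtype} must be intra-chromosomal")
            if self.size <= 0:
                raise ValueError("intra-chromosomal SV must have size > 0")

    @property
    def size(self) -> int:
        return abs(self.pos2 - self.pos1)


def _size_bin(size: float) -> int:
    for i, (lo, hi) in enumerate(SV_SIZE_BINS):
        if lo <= size < hi:
            return i
    raise ValueError(f"size {size} outside all bins")


def sv_category_index(svtype: str, size: float | None, clustered: bool) -> int:
    base = 16 if clustered else 0
    if svtype == "TRA":
        return base + 15
    if svtype not in SV_INTRA_TYPES:
        raise ValueError(f"unknown SV type {svtype!r}")
    return base + SV_INTRA_TYPES.index(svtype) * 5 + _size_bin(size)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [
            {"sample": r.sample, "svtype": r.svtype, "chrom1": r.chrom1, "pos1": r.pos1, "chrom2": r.chrom2, "pos2": r.pos2}
            for r in records
        ]
    )


def _clustered_flags(sample_records: pd.DataFrame, factor: float = SV_CLUSTER_FACTOR) -> np.ndarray:
    """Clustered/non-clustered call for every record of one sample.

    The clustering threshold tau is the sample's mean same-chromosome
    inter-breakpoint distance divided by ``factor``; a record is clustered
    iff any of its breakpoints lies within tau of a breakpoint belonging to
    a *different* record on the same chromosome.  Isolated records are
    non-clustered by construction.
    """
    n = len(sample_records)
    bp_chrom: list[str] = []
    bp_pos: list[int] = []
    bp_rec: list[int] = []
    for i, row in enumerate(sample_records.itertuples(index=False)):
        bp_chrom.extend([row.chrom1, row.chrom2])
        bp_pos.extend([row.pos1, row.pos2])
        bp_rec.extend([i, i])
    bp = pd.DataFrame({"chrom": bp_chrom, "pos": bp_pos, "rec": bp_rec})
    gaps: list[np.ndarray] = []
    for _, grp in bp.groupby("chrom"):
        if len(grp) >= 2:
            pos = np.sort(grp["pos"].to_numpy())
            gaps.append(np.diff(pos))
    if not gaps:
        return np.zeros(n, dtype=bool)
    mean_gap = float(np.concatenate(gaps).mean())
    tau = mean_gap / factor
    flags = np.zeros(n, dtype=bool)
    for _, grp in bp.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        rec = grp["rec"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, rec = pos[order], rec[order]
        for i in range(len(pos)):
            # nearest breakpoint of a different record, scanning outward
            for j in range(i + 1, len(pos)):
                if pos[j] - pos[i] >= tau:
                    break
                if rec[j] != rec[i]:
                    flags[rec[i]] = flags[rec[j]] = True
    return flags


def classify_sv(record: SvRecord, context: Iterable[SvRecord] | pd.DataFrame, factor: float = SV_CLUSTER_FACTOR) -> int:
    """Category index (0..31) of one SV given all records of its sample."""
    ctx = _records_frame(context)
    if not len(ctx):
        raise ValueError("context must contain at least the record itself")
    flags = _clustered_flags(ctx, factor=factor)
    match = (
        (ctx["svtype"] == record.svtype)
        & (ctx["chrom1"] == record.chrom1)
        & (ctx["pos1"] == record.pos1)
        & (ctx["chrom2"] == record.chrom2)
        & (ctx["pos2"] == record.pos2)
    )
    if not match.any():
        raise ValueError("record not found in its sample context")
    clustered = bool(flags[match.to_numpy()].any())
    size = None if record.svtype == "TRA" else record.size
    return sv_category_index(record.svtype, size, clustered)


def build_sv_catalog(records, factor: float = SV_CLUSTER_FACTOR) -> pd.DataFrame:
    """Per-sample 32-category SV count catalog.

    ``records`` is a table (or SvRecord list) with columns sample, svtype,
    chrom1, pos1, chrom2, pos2.  Column sums equal per-sample record counts.
    """
    df = _records_frame(records)
    if df.empty:
        return pd.DataFrame(index=SV_CATEGORIES, dtype=int)
    out = {}
    for sample, grp in df.groupby("sample", sort=True):
        grp = grp.reset_index(drop=True)
        flags = _clustered_flags(grp, factor=factor)
        counts = np.zeros(32, dtype=int)
        for i, row in enumerate(grp.itertuples(index=False)):
            size = None if row.svtype == "TRA" else abs(row.pos2 - row.pos1)
            counts[sv_category_index(row.svtype, size, bool(flags[i]))] += 1
        out[sample] = counts
    return pd.DataFrame(out, index=SV_CATEGORIES)


# ---------------------------------------------------------------------------
# NMF signature extraction and NNLS refitting
# ---------------------------------------------------------------------------

def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    mask = v > 0
    return float((v[mask] * np.log(v[mask] / wh[mask])).sum() - v.sum() + wh.sum())


def nmf_kl(
    v: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    n_iter: int = 400,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """KL-objective NMF by multiplicative updates; returns (W, H, objective
    trace).  The generalized KL divergence is checked to be non-increasing
    across iterations (up to numerical slack)."""
    eps = 1e-12
    m, n = v.shape
    w = rng.uniform(0.1, 1.0, size=(m, rank))
    h = rng.uniform(0.1, 1.0, size=(rank, n))
    trace = []
    prev = np.inf
    for _ in range(n_iter):
        wh = w @ h + eps
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], eps)
        wh = w @ h + eps
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(v, w @ h + eps)
        trace.append(obj)
        if obj > prev + 1e-8 * max(1.0, abs(prev)):
            raise RuntimeError("NMF objective increased — multiplicative update invariant violated")
        if prev - obj < tol * max(1.0, abs(prev)):
            break
        prev = obj
    return w, h, trace


def _mean_sample_cosine_distance(v: np.ndarray, wh: np.ndarray) -> float:
    num = (v * wh).sum(axis=0)
    den = np.linalg.norm(v, axis=0) * np.linalg.norm(wh, axis=0)
    ok = den > 0
    cos = np.ones(v.shape[1])
    cos[ok] = num[ok] / den[ok]
    return float(np.mean(1.0 - cos))


def extract_signatures_nmf(
    catalogs: pd.DataFrame,
    rank_range: tuple[int, int] = (1, 30),
    replicates: int = 20,
    stability_min: float = 0.8,
    improvement_min: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Extract SV signatures from a categories x samples count matrix.

    For each candidate rank, ``replicates`` NMF runs from random starts are
    pooled; the replicate signature vectors are clustered (k-medoids, cosine
    distance) and the average silhouette is the rank's stability, while
    reconstruction quality is the mean per-sample cosine distance of the
    best run.  The chosen rank is the largest rank that is both stable
    (stability >= ``stability_min``) and worth its extra signature: adding
    it must reduce the mean sample cosine distance by at least
    ``improvement_min`` of the rank-1 distance.  (Stability alone
    over-selects: a consistent split of a true signature stays stable but
    buys almost no reconstruction.)  Returns (signatures with unit-sum
    columns, exposures, per-rank diagnostics).
    """
    v = catalogs.to_numpy(float)
    if (v < 0).any():
        raise ValueError("catalog matrix must be nonnegative")
    if v.sum() == 0:
        raise ValueError("catalog matrix is all zero")
    if v.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = rank_range
    hi = min(hi, v.shape[1] - 1, v.shape[0])
    ranks = list(range(lo, hi + 1))
    rng = np.random.default_rng(seed)

    diagnostics = []
    best_factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for rank in ranks:
        runs = []
        for _ in range(replicates):
            w, h, _ = nmf_kl(v, rank, rng)
            runs.append((w, h, _kl_divergence(v, w @ h + 1e-12)))
        w_best, h_best, _ = min(runs, key=lambda t: t[2])
        best_factors[rank] = (w_best, h_best)
        recon = _mean_sample_cosine_distance(v, w_best @ h_best)
        if rank == 1:
            stability = 1.0
        else:
            cols = np.concatenate([w for w, _, _ in runs], axis=1).T  # (reps*rank) x m
            norms = np.linalg.norm(cols, axis=1, keepdims=True)
            unit = cols / np.maximum(norms, 1e-12)
            dist = 1.0 - unit @ unit.T
            np.fill_diagonal(dist, 0.0)
            dist = np.clip(dist, 0.0, 2.0)
            labels = pam_labels(dist, rank, rng)
            if len(set(labels)) < 2:
                stability = 0.0
            else:
                stability = float(silhouette_score(dist, labels, metric="precomputed"))
        diagnostics.append({"rank": rank, "stability": stability, "mean_cosine_distance": recon})

    diag = pd.DataFrame(diagnostics).set_index("rank")
    d = diag["mean_cosine_distance"]
    base = max(float(d.iloc[0]), 1e-12)
    improvement = -d.diff().fillna(0.0) / base  # gain of rank r over rank r-1
    diag["improvement"] = improvement
    stable = diag["stability"] >= stability_min
    eligible = [r for r in diag.index if stable.loc[r] and (r == diag.index[0] or improvement.loc[r] >= improvement_min)]
    chosen = int(max(eligible)) if eligible else int(diag["stability"].idxmax())
    diag["chosen"] = diag.index == chosen

    w, h = best_factors[chosen]
    colsum = np.maximum(w.sum(axis=0), 1e-12)
    w_norm = w / colsum
    h_scaled = h * colsum[:, None]
    sig_names = [f"SV32{chr(ord('A') + i)}" for i in range(chosen)]
    signatures = pd.DataFrame(w_norm, index=catalogs.index, columns=sig_names)
    exposures = pd.DataFrame(h_scaled, index=sig_names, columns=catalogs.columns)
    return signatures, exposures, diag


def refit_exposures(catalog: pd.Series | np.ndarray, reference: pd.DataFrame) -> tuple[pd.Series, float]:
    """Nonnegative least-squares refit of a catalog onto known signatures.

    ``reference`` is categories x K with unit-sum columns.  Returns the
    exposure vector and the residual norm.
    """
    v = np.asarray(catalog, float).ravel()
    if (v < 0).any():
        raise ValueError("catalog entries must be nonnegative")
    if len(v) != reference.shape[0]:
        raise ValueError("catalog / reference dimension mismatch")
    x, resid = nnls(reference.to_numpy(float), v)
    return pd.Series(x, index=reference.columns, name="exposure"), float(resid)


def cnv_gene_events(cnv: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Binary amplification/deletion event matrix from thresholded CNV calls.

    Amplification iff value == 2, deep deletion iff value == -2 (GISTIC-style
    thresholded input).  Rows are named '<gene>_amp' / '<gene>_del'.
    """
    vals = cnv.to_numpy()
    if ((vals < -2) | (vals > 2)).any():
        raise ValueError("CNV values must lie in -2..2")
    use = list(genes) if genes is not None else list(cnv.index)
    missing = [g for g in use if g not in cnv.index]
    if missing:
        raise ValueError(f"genes absent from CNV matrix: {missing}")
    rows = {}
    for g in use:
        rows[f"{g}_amp"] = (cnv.loc[g] == 2).astype(int)
        rows[f"{g}_del"] = (cnv.loc[g] == -2).astype(int)
    return pd.DataFrame(rows).T
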