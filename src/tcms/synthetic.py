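"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants four subtype score-profiles over the 20 TCMS features
directly on the log2 expression scale (Gaussian noise around
subtype-shifted means), exponential survival with subtype-dependent hazard
multipliers and independent exponential censoring, Bernoulli alteration
tables with optional planted pairwise co-occurrence (odds-multiplier on the
2x2 joint law with fixed marginals), SV event lists realized from planted
32-category signatures, and negative-binomial single-cell counts with
planted marker over-expression and QC-failure fractions.

Every generator is a pure function of (config, seed); per-table substreams
are derived from one master seed with fixed spawn keys so adding a table
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alterations import (
    CodonRule,
    ExonClassRule,
    FusionRule,
    HotspotRuleSet,
    default_nccn_ruleset,
)
from .signatures import ALL_FEATURES, GeneSignature, SignatureRegistry, feature_category

SUBTYPES = ("LPI", "IMD", "IME", "HPI")

_AA = "ARNDCQEGHILKMFPSTWYV"

_FUSION_PARTNERS = {"ALK": "EML4", "ROS1": "CD74", "RET": "KIF5B", "MET": "CAPZA2"}

# Approximate autosome lengths (Mb), longest first.
_CHROM_LENGTHS_MB = [248, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135, 133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51]


def default_genome_model() -> pd.DataFrame:
    """Chromosome-length table used to place synthetic SV breakpoints."""
    return pd.DataFrame(
        {
            "chrom": [f"chr{i}" for i in range(1, 23)],
            "length": [mb * 1_000_000 for mb in _CHROM_LENGTHS_MB],
        }
    )


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SubtypeProfile:
    """Planted per-feature mean z-shifts and hazard multipliers."""

    name: str
    feature_means: dict[str, float]
    hazard_os: float = 1.0
    hazard_rfs: float = 1.0

    def __post_init__(self) -> None:
        if self.hazard_os <= 0 or self.hazard_rfs <= 0:
            raise ValueError("hazard multipliers must be > 0")
        unknown = set(self.feature_means) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"profile references unknown features: {sorted(unknown)}")


def default_profiles() -> dict[str, SubtypeProfile]:
    """The planted phenotype pattern of the four subtypes.

    LPI is indolent (high GGO/lepidic, low proliferation, mildly active
    immunity); IMD is an immune desert at intermediate aggressiveness; IME
    is immune-enriched (CD8 T / NK / B cells high); HPI is aggressive (high
    solid/micropapillary, metastasis, proliferation, matrix remodeling).
    Hazards rise from LPI to HPI.
    """
    immune_all = ("CD8_T", "CD4_T", "B_cell", "Treg", "NK", "T_helper", "M1_macrophage", "dendritic_cell")
    lpi = {"GGO_lepidic": 1.0, "solid_micropapillary": -0.6, "metastasis": -0.6,
           "tumor_proliferation": -1.0, "matrix_remodeling": -0.6, "EMT": -0.4,
           "CD8_T": 0.3, "NK": 0.3, "B_cell": 0.3}
    imd = {f: -0.8 for f in immune_all}
    imd.update({"macrophage": -0.4, "neutrophil": -0.4, "GGO_lepidic": -0.2})
    ime = {"CD8_T": 1.0, "NK": 1.0, "B_cell": 1.0, "CD4_T": 0.8, "T_helper": 0.8,
           "M1_macrophage": 0.8, "dendritic_cell": 0.8, "Treg": 0.5, "macrophage": 0.4,
           "GGO_lepidic": -0.2}
    hpi = {"solid_micropapillary": 1.0, "metastasis": 1.0, "tumor_proliferation": 1.0,
           "matrix_remodeling": 1.0, "EMT": 0.8, "CAF": 0.6, "angiogenesis": 0.6,
           "myeloid": 0.3, "GGO_lepidic": -1.0, "CD8_T": -0.3, "NK": -0.3, "B_cell": -0.3}
    return {
        "LPI": SubtypeProfile("LPI", lpi, hazard_os=0.4, hazard_rfs=0.3),
        "IMD": SubtypeProfile("IMD", imd, hazard_os=0.8, hazard_rfs=0.8),
        "IME": SubtypeProfile("IME", ime, hazard_os=1.2, hazard_rfs=1.2),
        "HPI": SubtypeProfile("HPI", hpi, hazard_os=2.5, hazard_rfs=3.0),
    }


@dataclass(frozen=True)
class AlterationEventSpec:
    """One background somatic event with a baseline Bernoulli rate."""

    name: str  # e.g. "TP53_mut", "VOPP1_amp"
    kind: str  # mutation | amplification | deletion
    gene: str
    rate: float


def default_alteration_events() -> list[AlterationEventSpec]:
    # Baseline frequencies in the 5-20% range typical of recurrent LUAD events.
    return [
        AlterationEventSpec("TP53_mut", "mutation", "TP53", 0.20),
        AlterationEventSpec("RBM10_mut", "mutation", "RBM10", 0.10),
        AlterationEventSpec("DYNC2H1_mut", "mutation", "DYNC2H1", 0.10),
        AlterationEventSpec("MAP2K1_mut", "mutation", "MAP2K1", 0.05),
        AlterationEventSpec("VOPP1_amp", "amplification", "VOPP1", 0.15),
        AlterationEventSpec("RRM2B_amp", "amplification", "RRM2B", 0.15),
        AlterationEventSpec("EGFR_amp", "amplification", "EGFR", 0.10),
        AlterationEventSpec("CDKN2A_del", "deletion", "CDKN2A", 0.08),
    ]


@dataclass
class GeneratorConfig:
    n_samples: int = 400
    n_genes: int = 2000
    genes_per_signature: int = 10
    effect_size: float = 1.5  # z-shift magnitude applied to feature_means
    noise_sd: float = 1.0
    baseline_expression: float = 5.0  # log2 units
    subtype_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    censor_rate: float = 0.3
    base_rate_os: float = 0.02  # events per month at hazard multiplier 1
    base_rate_rfs: float = 0.03
    hotspot_positive_rate: float = 0.7
    alteration_events: list[AlterationEventSpec] = field(default_factory=default_alteration_events)
    cooccurrence_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    sv_signatures: np.ndarray | None = None  # 32 x r
    sv_exposures: np.ndarray | None = None  # r x n_samples
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.genes_per_signature) <= 0:
            raise ValueError("counts must be positive")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        for a, b, mult in self.cooccurrence_pairs:
            if mult <= 0:
                raise ValueError(f"odds multiplier for ({a}, {b}) must be > 0")
        for m in (self.sv_signatures, self.sv_exposures):
            if m is not None and (np.asarray(m) < 0).any():
                raise ValueError("SV signature/exposure matrices must be nonnegative")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, log2 scale
    truth_labels: pd.Series  # sample -> subtype
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    fusions: pd.DataFrame
    cnv: pd.DataFrame
    svs: pd.DataFrame
    sc_counts: pd.DataFrame | None = None
    sc_labels: pd.Series | None = None


def synthetic_registry(genes_per_signature: int = 10, version: str = "synthetic-0") -> SignatureRegistry:
    """A placeholder 20-feature registry with synthetic gene symbols."""
    sigs = [
        GeneSignature(
            name=f,
            genes=[f"{f}_G{i:03d}" for i in range(1, genes_per_signature + 1)],
            category=feature_category(f),
        )
        for f in ALL_FEATURES
    ]
    return SignatureRegistry(signatures=sigs, version=version)


def synthetic_voting_inputs(seed: int = 0, pool_size: int = 12, n_emt_papers: int = 84):
    """Synthetic marker-source sets and voting rules for registry assembly.

    Emulates the evidence structure behind the 17 TME slots: 7 deconvolution
    methods + 2 single-cell datasets for the nine 4-of-9 cell types, small
    publication pools for the >=2-publication and single-source tiers, and
    ``n_emt_papers`` EMT papers for the fractional vote.  Returns
    (clinical_sigs, sources, rules) ready for ``build_default_registry``.
    """
    from .signatures import (
        MarkerSourceSet,
        TME_FRACTION_VOTED,
        TME_SINGLE_SOURCE,
        TME_VOTED_2_PUBS,
        TME_VOTED_4_OF_9,
        VotingRule,
    )

    rng = _rng(seed, 8)
    pools = {f: [f"{f}_M{i:02d}" for i in range(1, pool_size + 1)] for f in TME_VOTED_4_OF_9 + TME_VOTED_2_PUBS + TME_SINGLE_SOURCE + TME_FRACTION_VOTED}

    deconv_ids = [f"method_{m}" for m in ("cibersort", "mcp", "epic", "quantiseq", "xcell", "fges", "kassandra")]
    sc_ids = ["sc_dataset_1", "sc_dataset_2"]
    nine_ids = deconv_ids + sc_ids
    sources = []
    for i, sid in enumerate(nine_ids):
        kind = "deconvolution-method" if sid.startswith("method") else "single-cell-dataset"
        markers = {}
        for f in TME_VOTED_4_OF_9:
            genes = pools[f]
            keep = rng.random(len(genes)) < 0.7  # each source reports ~70% of the pool
            markers[f] = {g for g, k in zip(genes, keep) if k}
        sources.append(MarkerSourceSet(source_id=sid, kind=kind, markers=markers))

    pub_ids = ["pub_1", "pub_2", "pub_3"]
    for sid in pub_ids:
        markers = {}
        for f in TME_VOTED_2_PUBS:
            genes = pools[f]
            keep = rng.random(len(genes)) < 0.8
            markers[f] = {g for g, k in zip(genes, keep) if k}
        sources.append(MarkerSourceSet(source_id=sid, kind="publication", markers=markers))

    single_id = "single_paper"
    sources.append(
        MarkerSourceSet(
            source_id=single_id,
            kind="publication",
            markers={f: set(pools[f]) for f in TME_SINGLE_SOURCE},
        )
    )

    emt_ids = [f"emt_paper_{i:02d}" for i in range(1, n_emt_papers + 1)]
    for sid in emt_ids:
        genes = pools["EMT"]
        keep = rng.random(len(genes)) < 0.35  # well above the 1/5 threshold on average
        sources.append(MarkerSourceSet(source_id=sid, kind="publication", markers={"EMT": {g for g, k in zip(genes, keep) if k}}))

    rules = {}
    for f in TME_VOTED_4_OF_9:
        rules[f] = VotingRule(feature=f, min_sources=4, pool=nine_ids)
    for f in TME_VOTED_2_PUBS:
        rules[f] = VotingRule(feature=f, min_sources=2, pool=pub_ids)
    for f in TME_SINGLE_SOURCE:
        rules[f] = VotingRule(feature=f, min_sources=1, pool=[single_id])
    rules["EMT"] = VotingRule(feature="EMT", min_fraction=0.2, pool=emt_ids)

    clinical_sigs = [
        GeneSignature(name=f, genes=[f"{f}_G{i:03d}" for i in range(1, 11)], category="clinical")
        for f in ("GGO_lepidic", "solid_micropapillary", "metastasis")
    ]
    return clinical_sigs, sources, rules


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def assign_subtypes(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.Series:
    rng = rng if rng is not None else _rng(config.seed, 0)
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    labels = rng.choice(SUBTYPES, size=config.n_samples, p=list(config.subtype_proportions))
    return pd.Series(labels, index=samples, name="subtype")


def generate_expression(
    config: GeneratorConfig,
    registry: SignatureRegistry,
    labels: pd.Series,
    profiles: Mapping[str, SubtypeProfile] | None = None,
) -> pd.DataFrame:
    """Log2-scale genes x samples matrix with planted subtype shifts.

    Signature-member genes of feature f have mean baseline + effect_size *
    profile.feature_means[f] for each sample's subtype; background genes sit
    at baseline.  Gaussian noise with SD noise_sd everywhere.
    """
    profiles = profiles or default_profiles()
    sig_genes = registry.all_genes()
    if config.n_genes < len(sig_genes):
        raise ValueError(
            f"n_genes ({config.n_genes}) < total signature genes ({len(sig_genes)})"
        )
    rng = _rng(config.seed, 1)
    n_bg = config.n_genes - len(sig_genes)
    genes = sig_genes + [f"BG{i:05d}" for i in range(1, n_bg + 1)]
    shift = np.zeros((config.n_genes, config.n_samples))
    subtype_arr = labels.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for sig in registry.signatures:
        rows = [gene_pos[g] for g in sig.genes]
        for st, prof in profiles.items():
            delta = config.effect_size * prof.feature_means.get(sig.name, 0.0)
            if delta == 0.0:
                continue
            cols = np.flatnonzero(subtype_arr == st)
            shift[np.ix_(rows, cols)] += delta
    noise = rng.normal(0.0, config.noise_sd, size=shift.shape)
    expr = config.baseline_expression + shift + noise
    return pd.DataFrame(expr, index=genes, columns=labels.index)


def generate_bulk_cohort(
    config: GeneratorConfig,
    registry: SignatureRegistry,
    profiles: Mapping[str, SubtypeProfile] | None = None,
    hotspot_rules: HotspotRuleSet | None = None,
) -> SyntheticCohort:
    """Full bulk cohort: expression, truth labels, clinical, alterations, SVs.

    Composes the individual generators on fixed substreams of the master
    seed, so each table is reproducible independently of the others.
    """
    profiles = profiles or default_profiles()
    labels = assign_subtypes(config)
    expression = generate_expression(config, registry, labels, profiles)
    os_data = generate_survival(labels, profiles, config.base_rate_os, config.censor_rate, seed=config.seed, endpoint="os")
    rfs_data = generate_survival(labels, profiles, config.base_rate_rfs, config.censor_rate, seed=config.seed, endpoint="rfs")
    clinical = _clinical_table(labels, os_data, rfs_data, _rng(config.seed, 4))
    mutations, fusions, cnv = generate_alterations(config, labels, hotspot_rules or default_nccn_ruleset(), seed=config.seed)
    if config.sv_signatures is not None and config.sv_exposures is not None:
        svs = generate_sv_events(config.sv_signatures, config.sv_exposures, seed=config.seed, sample_ids=list(labels.index))
    else:
        svs = pd.DataFrame(columns=["sample", "svtype", "chrom1", "pos1", "chrom2", "pos2"])
    return SyntheticCohort(
        expression=expression,
        truth_labels=labels,
        clinical=clinical,
        mutations=mutations,
        fusions=fusions,
        cnv=cnv,
        svs=svs,
    )


def _clinical_table(labels: pd.Series, os_data: pd.DataFrame, rfs_data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    stage_probs = {
        "LPI": (["AIS", "MIA", "IA", "IB"], [0.2, 0.2, 0.4, 0.2]),
        "IMD": (["IA", "IB", "II", "III"], [0.35, 0.3, 0.2, 0.15]),
        "IME": (["IA", "IB", "II", "III"], [0.3, 0.3, 0.2, 0.2]),
        "HPI": (["IB", "II", "III", "IV"], [0.15, 0.3, 0.35, 0.2]),
    }
    stages = [rng.choice(stage_probs[s][0], p=stage_probs[s][1]) for s in labels]
    adjuvant = rng.binomial(1, 0.4, size=len(labels))
    therapy = rng.choice(["TKI", "chemo", "none"], size=len(labels), p=[0.35, 0.35, 0.3])
    return pd.DataFrame(
        {
            "subtype": labels,
            "os_time": os_data["time"].to_numpy(),
            "os_event": os_data["event"].to_numpy(),
            "rfs_time": rfs_data["time"].to_numpy(),
            "rfs_event": rfs_data["event"].to_numpy(),
            "stage": stages,
            "relapse": rfs_data["event"].to_numpy(),
            "adjuvant": adjuvant,
            "therapy": therapy,
        },
        index=labels.index,
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival(
    labels: pd.Series,
    profiles: Mapping[str, SubtypeProfile] | Mapping[str, float],
    base_rate: float,
    censor_rate: float,
    seed: int = 0,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Exponential event times with label-dependent hazards and independent
    exponential censoring.

    Event time T ~ Exp(base_rate * multiplier(label)); censoring time C is
    exponential with a single global rate chosen so the expected censored
    fraction matches ``censor_rate``.  Returns a table with columns time,
    event, group.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be > 0")
    mults = {}
    for lab in pd.unique(labels):
        if lab not in profiles:
            raise ValueError(f"no profile for label {lab!r}")
        prof = profiles[lab]
        if isinstance(prof, SubtypeProfile):
            mults[lab] = prof.hazard_rfs if endpoint == "rfs" else prof.hazard_os
        else:
            mults[lab] = float(prof)
    key = 2 if endpoint == "os" else 3
    rng = _rng(seed, key)
    lam = np.array([base_rate * mults[lab] for lab in labels])
    t_event = rng.exponential(1.0 / lam)
    if censor_rate >= 1.0:
        return pd.DataFrame({"time": t_event, "event": 0, "group": labels.to_numpy()}, index=labels.index)
    if censor_rate <= 0.0:
        return pd.DataFrame({"time": t_event, "event": 1, "group": labels.to_numpy()}, index=labels.index)
    # with T ~ Exp(l) and C ~ Exp(c), P(censored) = c / (l + c); matching the
    # target at the mean hazard gives c = censor_rate/(1-censor_rate) * mean(l)
    c_rate = censor_rate / (1.0 - censor_rate) * lam.mean()
    t_cens = rng.exponential(1.0 / c_rate, size=len(lam))
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"time": time, "event": event, "group": labels.to_numpy()}, index=labels.index)


# ---------------------------------------------------------------------------
# Alterations
# ---------------------------------------------------------------------------

def _joint_prob_with_odds(pa: float, pb: float, theta: float) -> float:
    """P(A and B) for given marginals and odds ratio theta (Plackett form)."""
    if theta == 1.0:
        return pa * pb
    a = theta - 1.0
    b = -(theta * (pa + pb) + 1.0 - pa - pb)
    c = theta * pa * pb
    disc = b * b - 4 * a * c
    root = (-b - np.sqrt(disc)) / (2 * a)
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    if not (lo - 1e-12 <= root <= hi + 1e-12):
        root = (-b + np.sqrt(disc)) / (2 * a)
    return float(np.clip(root, lo, hi))


def _random_missense(rng: np.random.Generator) -> tuple[str, int]:
    ref, alt = rng.choice(list(_AA), size=2, replace=True)
    while alt == ref:
        alt = rng.choice(list(_AA))
    pos = int(rng.integers(30, 900))
    return f"p.{ref}{pos}{alt}", pos


def _realize_hotspot(rule, rng: np.random.Generator):
    """A well-formed mutation/fusion record matching the given rule."""
    if isinstance(rule, FusionRule):
        return {"gene_a": rule.gene, "gene_b": _FUSION_PARTNERS.get(rule.gene, "PARTNER1")}
    if isinstance(rule, CodonRule):
        alt = rule.alt_aa
        if alt is None:
            alt = rng.choice([a for a in _AA if a != rule.ref_aa])
        return {
            "gene": rule.gene,
            "protein_change": f"p.{rule.ref_aa}{rule.position}{alt}",
            "exon": rule.exon,
            "variant_class": "missense",
        }
    if isinstance(rule, ExonClassRule):
        change = {
            ("EGFR", 19): "p.E746_A750del",
            ("EGFR", 20): "p.A767_V769dup",
            ("ERBB2", 20): "p.Y772_A775dup",
        }.get((rule.gene, rule.exon), f"p.X{100 * rule.exon}_X{100 * rule.exon + 3}del")
        return {
            "gene": rule.gene,
            "protein_change": change,
            "exon": rule.exon,
            "variant_class": rule.variant_class,
        }
    raise TypeError(f"unknown rule type {type(rule)!r}")


def generate_alterations(
    config: GeneratorConfig,
    labels: pd.Series,
    hotspot_rules: HotspotRuleSet | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mutation, fusion and gene-level CNV tables with planted structure.

    Background events are Bernoulli at their baseline rates; each pair in
    ``config.cooccurrence_pairs`` has its 2x2 joint law inflated to the
    stated odds multiplier with marginals held fixed.  Hotspot-positive
    samples (rate ``hotspot_positive_rate``) carry one variant drawn
    uniformly from the rule list.
    """
    rules = hotspot_rules or default_nccn_ruleset()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 5)
    specs = {s.name: s for s in config.alteration_events}
    for a, b, _ in config.cooccurrence_pairs:
        for name in (a, b):
            if name not in specs:
                raise ValueError(f"co-occurrence pair references undefined event {name!r}")
    samples = list(labels.index)
    n = len(samples)

    presence = pd.DataFrame(False, index=list(specs), columns=samples)
    paired = set()
    for a, b, theta in config.cooccurrence_pairs:
        pa, pb = specs[a].rate, specs[b].rate
        p11 = _joint_prob_with_odds(pa, pb, theta)
        p10, p01 = pa - p11, pb - p11
        u = rng.random(n)
        both = u < p11
        a_only = (u >= p11) & (u < p11 + p10)
        b_only = (u >= p11 + p10) & (u < p11 + p10 + p01)
        presence.loc[a] = both | a_only
        presence.loc[b] = both | b_only
        paired.update((a, b))
    for name, spec in specs.items():
        if name in paired:
            continue
        presence.loc[name] = rng.random(n) < spec.rate

    mut_rows, fus_rows = [], []
    for name, spec in specs.items():
        if spec.kind != "mutation":
            continue
        for s in presence.columns[presence.loc[name]]:
            change, _ = _random_missense(rng)
            mut_rows.append({"sample": s, "gene": spec.gene, "protein_change": change, "exon": int(rng.integers(2, 25)), "variant_class": "missense"})

    hot = rng.random(n) < config.hotspot_positive_rate
    rule_list = rules.rules
    for s, is_hot in zip(samples, hot):
        if not is_hot or not rule_list:
            continue
        rule = rule_list[int(rng.integers(len(rule_list)))]
        rec = _realize_hotspot(rule, rng)
        if isinstance(rule, FusionRule):
            fus_rows.append({"sample": s, **rec})
        else:
            mut_rows.append({"sample": s, **rec})

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "protein_change", "exon", "variant_class"])
    fusions = pd.DataFrame(fus_rows, columns=["sample", "gene_a", "gene_b"])

    cnv_genes = sorted({s.gene for s in specs.values() if s.kind in ("amplification", "deletion")} | {"EGFR", "VOPP1", "RRM2B", "CDKN2A"})
    cnv = pd.DataFrame(0, index=cnv_genes, columns=samples)
    noise = rng.choice([-1, 0, 1], size=cnv.shape, p=[0.025, 0.95, 0.025])
    cnv.iloc[:, :] = noise
    for name, spec in specs.items():
        if spec.kind == "amplification":
            cnv.loc[spec.gene, presence.loc[name].to_numpy()] = 2
        elif spec.kind == "deletion":
            cnv.loc[spec.gene, presence.loc[name].to_numpy()] = -2
    return mutations, fusions, cnv


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

_SIZE_RANGES = [(1_000, 10_000), (10_000, 100_000), (100_000, 1_000_000), (1_000_000, 10_000_000), (10_000_000, 30_000_000)]


def _draw_size(bin_idx: int, rng: np.random.Generator) -> int:
    lo, hi = _SIZE_RANGES[bin_idx]
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_sv_events(
    sv_signatures: np.ndarray | pd.DataFrame,
    sv_exposures: np.ndarray | pd.DataFrame,
    genome_model: pd.DataFrame | None = None,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Realize SV records from planted 32-category signatures.

    Per-sample category counts are Poisson(signatures @ exposures).  Event
    sizes are drawn log-uniformly inside the category's size bin, and
    breakpoint positions are laid out so the classifier's own adaptive rule
    (nearest other-event breakpoint < mean same-chromosome gap / 10)
    reproduces the planted clustered / non-clustered status: non-clustered
    breakpoints go on an even per-chromosome grid, clustered events into
    tight multi-event clusters (two clusters per chromosome, separated by a
    wide gap).
    """
    from .alterations import SV_CATEGORIES  # canonical order

    w = np.asarray(sv_signatures, float)
    h = np.asarray(sv_exposures, float)
    if w.shape[0] != 32:
        raise ValueError("sv_signatures must have 32 rows in the canonical category order")
    if (w < 0).any() or (h < 0).any():
        raise ValueError("signature and exposure matrices must be nonnegative")
    genome = genome_model if genome_model is not None else default_genome_model()
    chroms = list(genome["chrom"])
    lengths = dict(zip(genome["chrom"], genome["length"]))
    rng = _rng(seed, 6)
    mu = w @ h
    n_samples = mu.shape[1]
    ids = list(sample_ids) if sample_ids is not None else [f"S{i:04d}" for i in range(1, n_samples + 1)]
    if len(ids) != n_samples:
        raise ValueError("sample_ids length must match exposure columns")

    records = []
    for j, sample in enumerate(ids):
        counts = rng.poisson(mu[:, j])
        # expand into event descriptors (category -> type, size bin, clustered)
        grid_units = []  # (event dict, size or None) for non-clustered
        cluster_units = []
        for cat_idx in np.flatnonzero(counts):
            clustered = cat_idx >= 16
            local = cat_idx % 16
            if local == 15:
                svtype, bin_idx = "TRA", None
            else:
                svtype = ("DEL", "DUP", "INV")[local // 5]
                bin_idx = local % 5
            for _ in range(counts[cat_idx]):
                size = None if bin_idx is None else _draw_size(bin_idx, rng)
                (cluster_units if clustered else grid_units).append((svtype, size))
        records.extend(_place_sample_events(sample, grid_units, cluster_units, chroms, lengths, rng))
    return pd.DataFrame(records, columns=["sample", "svtype", "chrom1", "pos1", "chrom2", "pos2"])


def _place_sample_events(sample, grid_units, cluster_units, chroms, lengths, rng):
    """Breakpoint placement honoring the adaptive clustering rule.

    Non-clustered breakpoints (intra-chromosomal events and both ends of
    translocations) go on an even per-chromosome grid with mild jitter, so
    every neighbor gap sits near the chromosome's mean gap and far above
    the tau = mean/10 threshold.  Clustered events are packed into tight
    multi-event clusters, two clusters per chromosome separated by a wide
    gap, keeping large gaps in the sample so tau stays well above the
    intra-cluster spacing.
    """
    records = []
    # expand non-clustered events into placeable units; TRA contributes two
    # linked point units that must land on different chromosomes
    units = []  # ('intra', svtype, size) | ('tra_end', tra_id, end)
    n_tra = 0
    for svtype, size in grid_units:
        if svtype == "TRA":
            units.append(("tra_end", n_tra, 0))
            units.append(("tra_end", n_tra, 1))
            n_tra += 1
        else:
            units.append(("intra", svtype, size))
    grid_chroms = chroms[: max(2, len(chroms) // 2)] if cluster_units else chroms
    per_chrom: dict[str, list] = {c: [] for c in grid_chroms}
    for i, u in enumerate(units):
        per_chrom[grid_chroms[i % len(grid_chroms)]].append(u)
    tra_ends: dict[int, list[tuple[str, int]]] = {}
    for chrom, chrom_units in per_chrom.items():
        if not chrom_units:
            continue
        length = lengths[chrom]
        slot = length / len(chrom_units)
        for i, u in enumerate(chrom_units):
            jitter = rng.uniform(-0.05, 0.05) * slot
            pos1 = int(i * slot + 0.3 * slot + jitter)
            pos1 = max(1, min(pos1, length - 2))
            if u[0] == "tra_end":
                tra_ends.setdefault(u[1], []).append((chrom, pos1))
            else:
                _, svtype, size = u
                pos2 = min(pos1 + size, length - 1)
                records.append({"sample": sample, "svtype": svtype, "chrom1": chrom, "pos1": pos1, "chrom2": chrom, "pos2": pos2})
    for tra_id, ends in tra_ends.items():
        (c1, p1), (c2, p2) = ends if len(ends) == 2 else (ends[0], ends[0])
        if c1 == c2:  # can happen only with a single grid chromosome
            alt = next((c for c in chroms if c != c1), None)
            if alt is None:
                continue  # degenerate one-chromosome genome: drop the TRA
            c2, p2 = alt, max(1, int(lengths[alt] * 0.5))
        records.append({"sample": sample, "svtype": "TRA", "chrom1": c1, "pos1": p1, "chrom2": c2, "pos2": p2})

    if cluster_units:
        chunks = [cluster_units[i : i + 4] for i in range(0, len(cluster_units), 4)]
        if len(chunks) >= 2 and len(chunks[-1]) == 1:
            chunks[-2].extend(chunks.pop())  # avoid a singleton cluster
        if len(chunks) == 1 and len(chunks[0]) >= 2:
            half = len(chunks[0]) // 2
            chunks = [chunks[0][:half], chunks[0][half:]]  # keep a wide gap in-sample
        back = list(reversed(chroms))
        gap_in = 1_000  # intra-cluster breakpoint spacing
        ci = 0
        tra_partner_count = 0
        for chunk_pair in range(0, len(chunks), 2):
            chrom = back[ci % len(back)]
            ci += 1
            length = lengths[chrom]
            anchors = [int(0.1 * length), int(0.6 * length)]
            for a, chunk in enumerate(chunks[chunk_pair : chunk_pair + 2]):
                cursor = anchors[a]
                for svtype, size in chunk:
                    if svtype == "TRA":
                        # partner breakpoint on another back-half chromosome,
                        # spread out so partner ends do not pile up on grid slots
                        partner = next(c for c in back if c != chrom)
                        pos2 = max(1, int(lengths[partner] * (0.30 + 0.04 * (tra_partner_count % 10))))
                        tra_partner_count += 1
                        records.append({"sample": sample, "svtype": "TRA", "chrom1": chrom, "pos1": cursor, "chrom2": partner, "pos2": pos2})
                        cursor += gap_in
                    else:
                        pos2 = min(cursor + size, length - 1)
                        records.append({"sample": sample, "svtype": svtype, "chrom1": chrom, "pos1": cursor, "chrom2": chrom, "pos2": pos2})
                        cursor = pos2 + gap_in
    return records


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------

def generate_single_cell(
    n_cells: int,
    n_genes: int,
    type_markers: Mapping[str, Sequence[str]],
    mito_genes: Sequence[str],
    seed: int = 0,
    base_mean: float = 0.5,
    marker_fold: float = 8.0,
    dispersion: float = 2.0,
    frac_low_quality: float = 0.0,
    frac_high_mito: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial single-cell counts with planted marker structure.

    Marker genes are over-expressed ``marker_fold``-fold in their own cell
    type; ``frac_low_quality`` cells have their library scaled down to fail
    the minimum-genes QC filter and ``frac_high_mito`` cells get inflated
    mitochondrial counts (fraction > 5%).  Returns (cells x genes counts,
    cell-type labels).
    """
    if not type_markers:
        raise ValueError("empty marker map")
    marker_all = [g for genes in type_markers.values() for g in genes]
    if len(marker_all) != len(set(marker_all)):
        raise ValueError("marker sets must be disjoint")
    if set(marker_all) & set(mito_genes):
        raise ValueError("marker sets must be disjoint from mitochondrial genes")
    rng = _rng(seed, 7)
    named = list(dict.fromkeys([*marker_all, *mito_genes]))
    if n_genes < len(named):
        raise ValueError(f"n_genes ({n_genes}) < named genes ({len(named)})")
    genes = named + [f"BG{i:05d}" for i in range(1, n_genes - len(named) + 1)]
    cells = [f"C{i:05d}" for i in range(1, n_cells + 1)]
    types = list(type_markers)
    labels = pd.Series(rng.choice(types, size=n_cells), index=cells, name="cell_type")

    mean = np.full((n_cells, n_genes), base_mean)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for ct, markers in type_markers.items():
        rows = np.flatnonzero(labels.to_numpy() == ct)
        cols = [gene_pos[g] for g in markers]
        mean[np.ix_(rows, cols)] *= marker_fold
    mito_cols = [gene_pos[g] for g in mito_genes]
    n_hm = int(round(frac_high_mito * n_cells))
    n_lq = int(round(frac_low_quality * n_cells))
    flagged = rng.choice(n_cells, size=min(n_cells, n_hm + n_lq), replace=False)
    high_mito, low_quality = flagged[:n_hm], flagged[n_hm : n_hm + n_lq]
    if mito_cols and n_hm:
        mean[np.ix_(high_mito, mito_cols)] *= 30.0  # pushes mito fraction well over 5%
    if n_lq:
        mean[low_quality, :] *= 0.05  # library collapse: detected genes < 200
    r = dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=cells, columns=genes), labels
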