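"""Hotspot engine, Fisher associations, SV taxonomy, NMF and NNLS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from tcms.alterations import (
    SV_CATEGORIES,
    SvRecord,
    build_sv_catalog,
    call_hotspot_status,
    classify_sv,
    cnv_gene_events,
    compare_event_frequencies,
    default_nccn_ruleset,
    extract_signatures_nmf,
    fisher_exact_2x2,
    hotspot_status_table,
    nmf_kl,
    pairwise_association,
    refit_exposures,
    sv_category_index,
)


def _mut(gene, change, exon, vclass="missense", sample="s1"):
    return pd.DataFrame(
        [{"sample": sample, "gene": gene, "protein_change": change, "exon": exon, "variant_class": vclass}]
    )


_EMPTY_MUT = pd.DataFrame(columns=["sample", "gene", "protein_change", "exon", "variant_class"])
_EMPTY_FUS = pd.DataFrame(columns=["sample", "gene_a", "gene_b"])


class TestHotspots:
    @pytest.mark.parametrize(
        "gene,change,exon,vclass,expected",
        [
            ("EGFR", "p.L858R", 21, "missense", "positive"),
            ("KRAS", "p.G12C", 2, "missense", "positive"),
            ("KRAS", "p.G12D", 2, "missense", "negative"),
            ("BRAF", "p.V600E", 15, "missense", "positive"),
            ("EGFR", "p.G719A", 18, "missense", "positive"),
            ("EGFR", "p.G719S", 18, "missense", "positive"),
            ("EGFR", "p.S768I", 20, "missense", "positive"),
            ("EGFR", "p.L861Q", 21, "missense", "positive"),
            ("EGFR", "p.E746_A750del", 19, "inframe_del", "positive"),
            ("EGFR", "p.A767_V769dup", 20, "inframe_ins", "positive"),
            ("ERBB2", "p.Y772_A775dup", 20, "inframe_ins", "positive"),
            ("ERBB2", "p.L755S", 19, "missense", "negative"),
            ("TP53", "p.R175H", 5, "missense", "negative"),
        ],
    )
    def test_worked_variants(self, gene, change, exon, vclass, expected):
        status, _ = call_hotspot_status(_mut(gene, change, exon, vclass), _EMPTY_FUS)
        assert status == expected

    def test_alk_fusion_any_partner_positive(self):
        for a, b in [("ALK", "EML4"), ("NOVEL", "ALK"), ("KIF5B", "RET")]:
            fus = pd.DataFrame([{"sample": "s1", "gene_a": a, "gene_b": b}])
            status, matched = call_hotspot_status(_EMPTY_MUT, fus)
            assert status == "positive" and matched

    def test_no_qualifying_events_negative(self):
        status, matched = call_hotspot_status(_EMPTY_MUT, _EMPTY_FUS)
        assert status == "negative" and matched == []

    def test_unparseable_protein_change_skipped_with_warning(self):
        bad = _mut("EGFR", "c.2573T>G", 21, "missense")
        with pytest.warns(UserWarning, match="unparseable"):
            status, _ = call_hotspot_status(bad, _EMPTY_FUS)
        assert status == "negative"

    def test_adding_nonmatching_record_never_flips_negative(self):
        base = _mut("KRAS", "p.G12D", 2)
        extra = pd.concat([base, _mut("TP53", "p.R273H", 8)], ignore_index=True)
        assert call_hotspot_status(base, _EMPTY_FUS)[0] == "negative"
        assert call_hotspot_status(extra, _EMPTY_FUS)[0] == "negative"

    def test_removing_records_never_creates_positive(self):
        full = pd.concat(
            [_mut("EGFR", "p.L858R", 21), _mut("TP53", "p.R175H", 5)], ignore_index=True
        )
        sub = full.iloc[1:]  # drop the only matching record
        assert call_hotspot_status(full, _EMPTY_FUS)[0] == "positive"
        assert call_hotspot_status(sub, _EMPTY_FUS)[0] == "negative"

    def test_cohort_table(self):
        muts = pd.concat(
            [_mut("EGFR", "p.L858R", 21, sample="sA"), _mut("KRAS", "p.G12D", 2, sample="sB")],
            ignore_index=True,
        )
        table = hotspot_status_table(muts, _EMPTY_FUS, ["sA", "sB", "sC"])
        assert table.to_dict() == {"sA": "positive", "sB": "negative", "sC": "negative"}


class TestFisher:
    def test_perfect_cooccurrence_closed_form(self):
        odds, p = fisher_exact_2x2(10, 0, 0, 10)
        assert odds == np.inf
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_independence(self):
        odds, p = fisher_exact_2x2(5, 5, 5, 5)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_exclusivity_mirror(self):
        odds, p = fisher_exact_2x2(0, 10, 10, 0)
        assert odds == 0.0
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_matches_scipy_enumeration_on_small_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            _, p_ref = scipy_fisher([[a, b], [c, d]])
            assert p == pytest.approx(p_ref, abs=1e-12), (a, b, c, d)

    def test_pairwise_direction_calls(self):
        n = 40
        ev = pd.DataFrame(
            {
                f"s{i}": [i < 20, i < 20, i >= 20] for i in range(n)
            },
            index=["A", "B", "C"],
        ).astype(int)
        res = pairwise_association(ev).table.set_index(["event_a", "event_b"])
        assert res.loc[("A", "B"), "direction"] == "co-occurrent"
        assert res.loc[("A", "C"), "direction"] == "exclusive"

    def test_constant_event_reported_as_none_with_note(self):
        ev = pd.DataFrame({"s1": [1, 1], "s2": [1, 0], "s3": [1, 1]}, index=["ALWAYS", "X"])
        res = pairwise_association(ev).table
        row = res.iloc[0]
        assert row["direction"] == "none" and row["note"] == "constant event"
        assert np.isnan(row["p_value"])

    def test_compare_frequencies_identical_groups_null(self):
        rng = np.random.default_rng(0)
        ev = pd.DataFrame(
            rng.binomial(1, 0.3, size=(4, 40)),
            index=["E1", "E2", "E3", "E4"],
            columns=[f"s{i}" for i in range(40)],
        )
        # same per-event counts in both groups by construction
        ev.iloc[:, 20:] = ev.iloc[:, :20].to_numpy()
        res = compare_event_frequencies([f"s{i}" for i in range(20)], [f"s{i}" for i in range(20, 40)], ev)
        assert np.allclose(res["p_value"], 1.0)

    def test_compare_frequencies_planted_difference(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(200)]
        ev = pd.DataFrame(0, index=["HIT"], columns=cols)
        ev.loc["HIT", cols[:100]] = rng.binomial(1, 0.4, 100)
        ev.loc["HIT", cols[100:]] = rng.binomial(1, 0.05, 100)
        res = compare_event_frequencies(cols[:100], cols[100:], ev)
        assert res.loc[0, "p_value"] < 1e-3

    def test_event_absent_in_both_groups(self):
        ev = pd.DataFrame(0, index=["NONE"], columns=["s1", "s2", "s3", "s4"])
        res = compare_event_frequencies(["s1", "s2"], ["s3", "s4"], ev)
        assert res.loc[0, "p_value"] == 1.0 and res.loc[0, "odds_ratio"] == 1.0
        assert res.loc[0, "note"]

    def test_empty_group_rejected(self):
        ev = pd.DataFrame({"s1": [1]}, index=["E"])
        with pytest.raises(ValueError):
            compare_event_frequencies([], ["s1"], ev)


class TestSvTaxonomy:
    def test_exactly_32_categories(self):
        assert len(SV_CATEGORIES) == 32
        assert len(set(SV_CATEGORIES)) == 32
        # enumerate the classification space: every (type, bin, status) maps
        # to a distinct index and fills 0..31
        idx = set()
        for clustered in (False, True):
            for t in ("DEL", "DUP", "INV"):
                for size in (5e3, 5e4, 5e5, 5e6, 5e7):
                    idx.add(sv_category_index(t, size, clustered))
            idx.add(sv_category_index("TRA", None, clustered))
        assert idx == set(range(32))

    @pytest.mark.parametrize(
        "size,label",
        [(500, "1-10Kb"), (5_000, "1-10Kb"), (10_000, "10-100Kb"), (999_999, "100Kb-1Mb"),
         (1_000_000, "1Mb-10Mb"), (10_000_000, ">10Mb"), (5e8, ">10Mb")],
    )
    def test_size_bins_half_open_with_sub_kb_folding(self, size, label):
        idx = sv_category_index("DEL", size, clustered=False)
        assert SV_CATEGORIES[idx] == f"non-clustered_DEL_{label}"

    def test_isolated_del_is_nonclustered(self):
        rec = SvRecord("s1", "DEL", "chr1", 1_000_000, "chr1", 1_005_000)
        idx = classify_sv(rec, [rec])
        assert SV_CATEGORIES[idx] == "non-clustered_DEL_1-10Kb"

    def test_tra_has_exactly_two_categories(self):
        assert {c for c in SV_CATEGORIES if c.endswith("TRA")} == {"non-clustered_TRA", "clustered_TRA"}
        with pytest.raises(ValueError):
            SvRecord("s1", "TRA", "chr1", 100, "chr1", 200)

    def test_tight_cluster_flagged_under_adaptive_rule(self):
        # 10 DELs with all breakpoints within 200 Kb on chr1; chr2 carries
        # two distant events so the sample's mean gap stays large
        recs = [
            SvRecord("s1", "DEL", "chr1", 10_000_000 + i * 20_000, "chr1", 10_000_000 + i * 20_000 + 5_000)
            for i in range(10)
        ]
        recs += [
            SvRecord("s1", "DUP", "chr2", 10_000_000, "chr2", 10_050_000),
            SvRecord("s1", "DUP", "chr2", 80_000_000, "chr2", 80_050_000),
        ]
        for r in recs[:10]:
            idx = classify_sv(r, recs)
            assert SV_CATEGORIES[idx].startswith("clustered_DEL")

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            SvRecord("s1", "BND", "chr1", 1, "chr2", 2)

    def test_catalog_conservation_and_empty(self):
        assert build_sv_catalog([]).shape[0] == 32
        recs = [
            SvRecord("s1", "DEL", "chr1", 1_000_000, "chr1", 1_005_000),
            SvRecord("s1", "TRA", "chr1", 50_000_000, "chr3", 1_000_000),
            SvRecord("s2", "INV", "chr2", 10_000_000, "chr2", 12_000_000),
        ]
        cat = build_sv_catalog(recs)
        assert list(cat.columns) == ["s1", "s2"]
        assert cat["s1"].sum() == 2 and cat["s2"].sum() == 1
        assert (cat.index == SV_CATEGORIES).all()


class TestNmf:
    def _planted(self, seed, rank=3, n_samples=40, noise=True):
        rng = np.random.default_rng(seed)
        w = np.zeros((32, rank))
        supports = [range(0, 5), range(5, 12), [15, 31, 16, 17], range(20, 26)][:rank]
        for k, sup in enumerate(supports):
            vals = rng.uniform(0.5, 1.0, len(list(sup)))
            w[list(sup), k] = vals / vals.sum()
        h = rng.gamma(0.7, 150, (rank, n_samples))
        h *= np.maximum(1, 250 / np.maximum(h.sum(axis=0), 1e-9))
        v = rng.poisson(w @ h).astype(float) if noise else w @ h
        return w, h, pd.DataFrame(v, index=SV_CATEGORIES)

    def test_objective_nonincreasing(self):
        _, _, v = self._planted(0)
        _, _, trace = nmf_kl(v.to_numpy(), 3, np.random.default_rng(0))
        diffs = np.diff(trace)
        assert (diffs <= 1e-6 * np.maximum(1, np.abs(trace[:-1]))).all()

    def test_exact_product_recovers_true_rank_and_signatures(self):
        w, h, v = self._planted(1, noise=False)
        sigs, exps, diag = extract_signatures_nmf(v, rank_range=(1, 5), replicates=6, seed=0)
        assert int(diag.index[diag["chosen"]][0]) == 3
        s = sigs.to_numpy()
        wn = w / w.sum(axis=0)
        cos = (s.T @ wn) / (
            np.linalg.norm(s, axis=0)[:, None] * np.linalg.norm(wn, axis=0)[None, :]
        )
        assert cos.max(axis=0).min() >= 0.99

    def test_rank_one_data_chooses_rank_one(self):
        rng = np.random.default_rng(2)
        w = np.zeros((32, 1))
        w[:6, 0] = 1 / 6
        h = rng.uniform(100, 300, (1, 30))
        v = pd.DataFrame(rng.poisson(w @ h).astype(float), index=SV_CATEGORIES)
        _, _, diag = extract_signatures_nmf(v, rank_range=(1, 4), replicates=6, seed=0)
        assert int(diag.index[diag["chosen"]][0]) == 1

    def test_reconstruction_close_to_sklearn(self):
        # independent cross-check: sklearn's KL-NMF reaches a comparable
        # objective on the same matrix and rank
        from sklearn.decomposition import NMF

        _, _, v = self._planted(3)
        x = v.to_numpy()
        w, h, trace = nmf_kl(x, 3, np.random.default_rng(0), n_iter=2000, tol=1e-10)
        model = NMF(3, solver="mu", beta_loss="kullback-leibler", init="random",
                    random_state=0, max_iter=2000, tol=1e-10)
        w_sk = model.fit_transform(x)
        from tcms.alterations import _kl_divergence

        ours = _kl_divergence(x, w @ h + 1e-12)
        theirs = _kl_divergence(x, w_sk @ model.components_ + 1e-12)
        assert ours <= theirs * 1.05 + 1e-6

    def test_all_zero_matrix_rejected(self):
        v = pd.DataFrame(np.zeros((32, 5)), index=SV_CATEGORIES)
        with pytest.raises(ValueError):
            extract_signatures_nmf(v, rank_range=(1, 2), replicates=2)

    def test_deterministic_given_seed(self):
        _, _, v = self._planted(4)
        out1 = extract_signatures_nmf(v, rank_range=(1, 3), replicates=4, seed=9)
        out2 = extract_signatures_nmf(v, rank_range=(1, 3), replicates=4, seed=9)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[2], out2[2])


class TestNnls:
    def _reference(self, seed=0, k=4):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, size=(32, k)) ** 3  # sparse-ish columns
        w /= w.sum(axis=0)
        return pd.DataFrame(w, index=SV_CATEGORIES, columns=[f"R{i}" for i in range(k)])

    def test_exact_generative_case(self):
        ref = self._reference()
        exp, resid = refit_exposures(ref["R1"].to_numpy() * 100, ref)
        assert exp["R1"] == pytest.approx(100, abs=1e-8)
        assert exp.drop("R1").abs().max() < 1e-8
        assert resid < 1e-8

    def test_zero_catalog_zero_exposures(self):
        ref = self._reference()
        exp, resid = refit_exposures(np.zeros(32), ref)
        assert (exp == 0).all() and resid == 0

    def test_random_nonnegative_combination_recovered(self):
        rng = np.random.default_rng(1)
        ref = self._reference(seed=2)
        w_true = rng.uniform(0, 50, 4)
        catalog = ref.to_numpy() @ w_true
        exp, _ = refit_exposures(catalog, ref)
        assert np.allclose(exp.to_numpy(), w_true, atol=1e-6)

    def test_kkt_residual_orthogonal_to_active_columns(self):
        rng = np.random.default_rng(3)
        ref = self._reference(seed=4)
        catalog = rng.poisson(ref.to_numpy() @ rng.uniform(10, 80, 4)).astype(float)
        exp, _ = refit_exposures(catalog, ref)
        residual = catalog - ref.to_numpy() @ exp.to_numpy()
        active = exp.to_numpy() > 1e-10
        grad = ref.to_numpy().T @ residual
        assert np.abs(grad[active]).max() < 1e-6  # stationarity on active set
        assert (grad[~active] <= 1e-6).all()  # feasibility on inactive set

    def test_negative_catalog_rejected(self):
        ref = self._reference()
        with pytest.raises(ValueError):
            refit_exposures(-np.ones(32), ref)


class TestCnvEvents:
    def test_thresholds(self):
        cnv = pd.DataFrame(
            {"s1": [2, 1, 0], "s2": [-2, -1, 2]}, index=["RRM2B", "VOPP1", "EGFR"]
        )
        ev = cnv_gene_events(cnv)
        assert ev.loc["RRM2B_amp", "s1"] == 1
        assert ev.loc["VOPP1_amp", "s1"] == 0  # value 1 is not an amplification
        assert ev.loc["RRM2B_del", "s2"] == 1
        assert ev.loc["VOPP1_del", "s2"] == 0  # value -1 is not a deep deletion
        assert ev.loc["EGFR_amp", "s2"] == 1

    def test_all_zero_matrix_gives_no_events(self):
        cnv = pd.DataFrame(0, index=["A", "B"], columns=["s1", "s2"])
        assert cnv_gene_events(cnv).to_numpy().sum() == 0

    def test_out_of_range_rejected(self):
        cnv = pd.DataFrame({"s1": [3]}, index=["A"])
        with pytest.raises(ValueError):
            cnv_gene_events(cnv)
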