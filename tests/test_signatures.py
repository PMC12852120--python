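"""Signature registry construction: voting, differential expression, QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcms.io import read_gmt
from tcms.signatures import (
    DifferentialResult,
    GeneSignature,
    MarkerSourceSet,
    ScQcThresholds,
    SignatureRegistry,
    VotingRule,
    build_default_registry,
    derive_de_signature,
    differential_expression,
    qc_filter_cells,
    vote_markers,
)
from tcms.synthetic import generate_single_cell, synthetic_voting_inputs


def _sources_with_votes(gene_votes: dict[str, int], n_sources: int = 9):
    """Sources such that gene g appears in exactly gene_votes[g] of them."""
    return [
        MarkerSourceSet(
            source_id=f"s{i}",
            kind="deconvolution-method",
            markers={"CD8_T": {g for g, v in gene_votes.items() if v > i}},
        )
        for i in range(n_sources)
    ]


class TestVoting:
    @pytest.mark.parametrize(
        "votes,included",
        [(9, True), (4, True), (3, False), (1, False)],
    )
    def test_four_of_nine_boundary(self, votes, included):
        sources = _sources_with_votes({"GENE": votes})
        sig = vote_markers("CD8_T", sources, VotingRule(feature="CD8_T", min_sources=4))
        assert ("GENE" in sig.genes) is included

    @pytest.mark.parametrize("votes,included", [(17, True), (16, False), (84, True)])
    def test_emt_fraction_boundary_over_84_papers(self, votes, included):
        sources = [
            MarkerSourceSet(f"p{i}", "publication", {"EMT": {"GENE"} if i < votes else set()})
            for i in range(84)
        ]
        sig = vote_markers("EMT", sources, VotingRule(feature="EMT", min_fraction=1 / 5))
        assert ("GENE" in sig.genes) is included

    def test_provenance_records_contributing_sources(self):
        sources = _sources_with_votes({"GENE": 5})
        sig = vote_markers("CD8_T", sources, VotingRule(feature="CD8_T", min_sources=4))
        assert sig.provenance["GENE"] == ["s0", "s1", "s2", "s3", "s4"]

    def test_empty_source_list_rejected(self):
        with pytest.raises(ValueError):
            vote_markers("CD8_T", [], VotingRule(feature="CD8_T", min_sources=4))

    def test_voting_monotone_under_added_supporting_source(self):
        sources = _sources_with_votes({"A": 4, "B": 6, "C": 3})
        rule = VotingRule(feature="CD8_T", min_sources=4)
        before = set(vote_markers("CD8_T", sources, rule).genes)
        extra = MarkerSourceSet("s_extra", "single-cell-dataset", {"CD8_T": before})
        after = set(vote_markers("CD8_T", sources + [extra], rule).genes)
        assert before <= after


class TestDifferentialExpression:
    def _matrix(self, rng, n_genes=50, n_per=20, shift_gene=None, shift=0.0, sd=1.0):
        a_cols = [f"A{i}" for i in range(n_per)]
        b_cols = [f"B{i}" for i in range(n_per)]
        genes = [f"G{i}" for i in range(n_genes)]
        x = rng.normal(5.0, sd, size=(n_genes, 2 * n_per))
        df = pd.DataFrame(x, index=genes, columns=a_cols + b_cols)
        if shift_gene is not None:
            df.loc[shift_gene, a_cols] += shift
        return df, a_cols, b_cols

    def test_planted_two_unit_shift_passes_both_filters(self):
        rng = np.random.default_rng(0)
        df, a, b = self._matrix(rng, shift_gene="G0", shift=2.0, sd=0.1)
        res = differential_expression(df, a, b)
        sig = derive_de_signature(res, lfc_min=1.0, p_max=0.05)
        assert "G0" in sig.genes
        # oracle: Welch t computed directly on the same values
        t, p = stats.ttest_ind(df.loc["G0", a], df.loc["G0", b], equal_var=False)
        assert res.table.loc["G0", "p_value"] == pytest.approx(p, abs=1e-12)

    def test_sub_unit_shift_fails_fold_change_filter(self):
        rng = np.random.default_rng(1)
        df, a, b = self._matrix(rng, shift_gene="G0", shift=0.9, sd=0.01)
        res = differential_expression(df, a, b)
        sig = derive_de_signature(res, lfc_min=1.0, p_max=0.05)
        assert "G0" not in sig.genes
        assert res.table.loc["G0", "p_value"] < 1e-6  # significant, but lfc < 1

    def test_identical_duplicated_groups_yield_zero_fold_change(self):
        rng = np.random.default_rng(2)
        base = rng.normal(5, 1, size=(30, 5))
        df = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"G{i}" for i in range(30)],
            columns=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        )
        res = differential_expression(df, [f"A{i}" for i in range(5)], [f"B{i}" for i in range(5)])
        assert np.allclose(res.table["log2fc"], 0)
        assert derive_de_signature(res).genes == []

    def test_zero_variance_equal_means_gives_p_one(self):
        df = pd.DataFrame(
            {"A0": [1.0], "A1": [1.0], "B0": [1.0], "B1": [1.0]}, index=["G0"]
        )
        res = differential_expression(df, ["A0", "A1"], ["B0", "B1"])
        assert res.table.loc["G0", "p_value"] == 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        df, a, b = self._matrix(rng, n_genes=800)
        res = differential_expression(df, a, b)
        _, ks_p = stats.kstest(res.table["p_value"], "uniform")
        assert ks_p > 0.01

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        df, a, b = self._matrix(rng, n_genes=200)
        res = differential_expression(df, a, b)
        assert (res.table["p_adjusted"] >= res.table["p_value"] - 1e-15).all()

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(5)
        df, a, b = self._matrix(rng)
        with pytest.raises(ValueError):
            differential_expression(df, a, a[:2] + b)


class TestDeriveSignature:
    def _result_with_passing(self, n_pass, n_fail=8):
        genes = [f"HIST{i}" for i in range(n_pass)] + [f"NULL{i}" for i in range(n_fail)]
        tab = pd.DataFrame(
            {
                "log2fc": [2.0] * n_pass + [0.1] * n_fail,
                "p_value": [1e-6] * n_pass + [0.9] * n_fail,
                "p_adjusted": [1e-5] * n_pass + [0.95] * n_fail,
                "mean_a": 5.0,
                "mean_b": 4.0,
            },
            index=genes,
        )
        return DifferentialResult(table=tab, group_a=["a1", "a2"], group_b=["b1", "b2"])

    def test_32_candidates_minus_11_exclusions_gives_21(self):
        res = self._result_with_passing(32)
        excl = [f"HIST{i}" for i in range(11)]
        sig = derive_de_signature(res, use_adjusted=True, exclusion_list=excl)
        assert len(sig.genes) == 21

    def test_empty_exclusion_keeps_all_passing(self):
        res = self._result_with_passing(32)
        assert len(derive_de_signature(res).genes) == 32

    def test_zero_p_threshold_empties_signature(self):
        res = self._result_with_passing(10)
        with pytest.warns(UserWarning):
            sig = derive_de_signature(res, p_max=0.0)
        assert sig.genes == []

    def test_descending_fold_change_order_with_lexicographic_ties(self):
        tab = pd.DataFrame(
            {
                "log2fc": [1.5, 2.5, 1.5],
                "p_value": [1e-4] * 3,
                "p_adjusted": [1e-3] * 3,
                "mean_a": 5.0,
                "mean_b": 4.0,
            },
            index=["ZZZ", "MID", "AAA"],
        )
        res = DifferentialResult(table=tab, group_a=["a1", "a2"], group_b=["b1", "b2"])
        assert derive_de_signature(res).genes == ["MID", "AAA", "ZZZ"]


class TestQcFilter:
    def _counts(self, n_cells=30, n_genes=1000, seed=0):
        counts, _ = generate_single_cell(
            n_cells,
            n_genes,
            type_markers={"T": ["M1", "M2"]},
            mito_genes=["MT1", "MT2"],
            seed=seed,
        )
        return counts

    def test_cell_below_min_genes_removed(self):
        counts = self._counts()
        # keep the gene panel intact but silence one cell down to 150 genes
        row = counts.iloc[0].copy()
        nz = row[row > 0].index
        row[nz[150:]] = 0
        row[nz[:150]] = np.maximum(row[nz[:150]], 1)
        counts.iloc[0] = row
        filtered, report = qc_filter_cells(counts, ["MT1", "MT2"])
        assert counts.index[0] not in filtered.index
        assert report["cells_low_genes"] >= 1

    def test_six_percent_mito_cell_removed(self):
        counts = self._counts()
        cell = counts.index[1]
        total = counts.loc[cell].sum()
        counts.loc[cell, "MT1"] = int(0.06 * total / (1 - 0.06)) + 1
        filtered, _ = qc_filter_cells(counts, ["MT1", "MT2"])
        assert cell not in filtered.index

    def test_detected_gene_upper_boundary(self):
        rng = np.random.default_rng(0)
        n_genes = 2600
        base = rng.poisson(2.0, size=(8, n_genes)) + 1  # all genes detected everywhere
        counts = pd.DataFrame(base, index=[f"C{i}" for i in range(8)], columns=[f"G{i}" for i in range(n_genes)])
        counts.iloc[0, 2500:] = 0  # exactly 2500 detected -> removed
        counts.iloc[1, 2499:] = 0  # 2499 detected -> retained
        filtered, _ = qc_filter_cells(counts, [])
        assert "C0" not in filtered.index
        assert "C1" in filtered.index

    def test_gene_filter_min_cells(self):
        counts = self._counts()
        counts["RARE"] = 0
        counts.iloc[:2, counts.columns.get_loc("RARE")] = 5  # expressed in 2 < 3 cells
        filtered, report = qc_filter_cells(counts, [])
        assert "RARE" not in filtered.columns

    def test_idempotent(self):
        counts = self._counts(n_cells=60, seed=3)
        once, _ = qc_filter_cells(counts, ["MT1", "MT2"])
        twice, _ = qc_filter_cells(once, ["MT1", "MT2"])
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_allowed(self):
        counts = pd.DataFrame(
            np.ones((4, 5), dtype=int), index=list("abcd"), columns=[f"G{i}" for i in range(5)]
        )
        filtered, _ = qc_filter_cells(counts, [])  # 5 genes << 200 per cell
        assert filtered.shape[0] == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ScQcThresholds(min_cells_per_gene=0)


class TestRegistry:
    def test_default_registry_has_twenty_features(self):
        clinical, sources, rules = synthetic_voting_inputs(seed=0)
        reg = build_default_registry(clinical, sources, rules)
        assert len(reg) == 20
        cats = [s.category for s in reg.signatures]
        assert cats.count("clinical") == 3
        assert cats.count("tme_cell") + cats.count("tme_process") == 17

    def test_missing_emt_sources_error_names_slot(self):
        clinical, sources, rules = synthetic_voting_inputs(seed=0)
        sources = [s for s in sources if not s.source_id.startswith("emt_paper")]
        with pytest.raises(ValueError, match="EMT"):
            build_default_registry(clinical, sources, rules)

    def test_source_order_does_not_change_registry(self):
        clinical, sources, rules = synthetic_voting_inputs(seed=1)
        reg1 = build_default_registry(clinical, sources, rules)
        reg2 = build_default_registry(clinical, list(reversed(sources)), rules)
        assert reg1.as_dict() == reg2.as_dict()

    def test_gmt_round_trip(self, tmp_path, registry):
        path = tmp_path / "tcms.gmt"
        registry.to_gmt(path)
        back = SignatureRegistry.from_gmt(path)
        assert back.as_dict() == registry.as_dict()
        raw = read_gmt(path)
        assert len(raw) == 20

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneSignature(name="x", genes=["A", "A"])
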