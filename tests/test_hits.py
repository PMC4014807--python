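import numpy as np
import pytest

import screensift as ss
from conftest import make_table
from oracles import brute_force_reagent_counts


class TestCutoffSpec:
    def test_mode_fields_are_exclusive(self):
        with pytest.raises(ValueError):
            ss.CutoffSpec(mode="stat", reference="samples", k=2, value=0.5)
        with pytest.raises(ValueError):
            ss.CutoffSpec(mode="value")
        with pytest.raises(ValueError):
            ss.CutoffSpec(mode="stat", reference="samples", k=-1)

    def test_stat_mode_uses_reference_mean_plus_k_sd(self):
        t = make_table(
            {1: [0.0, 0.2, 1.0, 1.2, 0.5]},
            well_types=["GFP", "GFP", "STX16", "STX16", "sample"],
        )
        spec = ss.CutoffSpec(mode="stat", reference="GFP", k=3)
        thr = ss.select_cutoff(t, "Signal", spec)
        gfp = np.array([0.0, 0.2])
        assert thr == pytest.approx(gfp.mean() + 3 * gfp.std(ddof=1))

    def test_stat_mode_on_samples_with_le_direction_subtracts(self):
        t = make_table({1: [1.0, 2.0, 3.0, 4.0]})
        spec = ss.CutoffSpec(mode="stat", reference="samples", k=2, direction="le")
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert ss.select_cutoff(t, "Signal", spec) == pytest.approx(
            v.mean() - 2 * v.std(ddof=1)
        )

    def test_value_mode_echoes(self):
        t = make_table({1: [0.5, 0.7]})
        assert ss.select_cutoff(t, "Signal", ss.CutoffSpec(mode="value", value=0.6)) == 0.6

    def test_rank_mode_indexes_ordered_plot(self):
        t = make_table({1: [5.0, 2.0, 9.0]})
        assert ss.select_cutoff(t, "Signal", ss.CutoffSpec(mode="rank", rank=1)) == 9.0
        assert ss.select_cutoff(t, "Signal", ss.CutoffSpec(mode="rank", rank=3)) == 2.0
        with pytest.raises(ValueError):
            ss.select_cutoff(t, "Signal", ss.CutoffSpec(mode="rank", rank=4))

    def test_absent_reference_control_is_error(self):
        t = make_table({1: [1.0, 2.0]})
        with pytest.raises(ValueError, match="GFP"):
            ss.select_cutoff(t, "Signal", ss.CutoffSpec(mode="stat", reference="GFP", k=1))


class TestFinalizeThreshold:
    def test_flags_values_passing_threshold(self):
        t = make_table({1: [0.5, 0.7]})
        child, hit_list = ss.finalize_threshold(t, "Signal", 0.6, "ge")
        assert child.records["Signal_hit"].tolist() == [0.0, 1.0]
        assert hit_list["score"].tolist() == [0.7]

    def test_no_hits_below_threshold(self):
        t = make_table({1: [0.1, 0.2, 0.3]})
        _, hit_list = ss.finalize_threshold(t, "Signal", 0.6, "ge")
        assert hit_list.empty

    def test_hit_count_matches_brute_force(self, rng):
        values = rng.normal(0, 1, 192).tolist()
        t = make_table({1: values[:96], 2: values[96:]})
        thr = 0.4
        _, hit_list = ss.finalize_threshold(t, "Signal", thr, "ge")
        assert len(hit_list) == sum(1 for v in values if v >= thr)

    def test_raising_threshold_never_adds_hits(self, rng):
        t = make_table({1: rng.normal(0, 1, 96).tolist()})
        counts = [
            len(ss.finalize_threshold(t, "Signal", thr, "ge")[1])
            for thr in np.linspace(-2, 2, 15)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_missing_scores_are_not_hits(self):
        t = make_table({1: [np.nan, 1.0]})
        child, hit_list = ss.finalize_threshold(t, "Signal", 0.5, "ge")
        assert child.records["Signal_hit"].tolist() == [0.0, 1.0]
        assert len(hit_list) == 1


class TestColumnArithmetic:
    def test_self_subtraction_is_zero(self):
        t = make_table({1: [1.0, 2.0, 3.0]})
        out = ss.column_arithmetic(t, "Signal", "Signal", "-")
        assert np.allclose(out.records["Signal-Signal"], 0.0)

    def test_add_then_subtract_recovers(self, rng):
        t = make_table({1: rng.normal(size=20).tolist()})
        t = t.with_column("B", rng.normal(size=20), "b column")
        t2 = ss.column_arithmetic(t, "Signal", "B", "+")
        t3 = ss.column_arithmetic(t2, "Signal+B", "B", "-")
        assert np.allclose(t3.records["Signal+B-B"], t.records["Signal"], atol=1e-12)

    def test_ratio_then_filter_yields_specific_subset(self):
        # the screen-comparison workflow: ratio of two toxin columns >= 2-fold
        pe = [1.0, 2.0, 0.4, 3.0]
        ricin = [0.5, 2.0, 0.2, 1.0]
        t = make_table({1: pe})
        t = t.with_column("Ricin", ricin, "second screen")
        ratio = ss.column_arithmetic(t, "Signal", "Ricin", "/")
        subset = ss.filter_rows(ratio, "`Signal/Ricin` >= 2")
        # 1/0.5 = 2, 2/2 = 1, 0.4/0.2 = 2, 3/1 = 3
        assert subset.records["gene_symbol"].tolist() == ["G1", "G3", "G4"]

    def test_division_by_zero_reported_as_missing(self):
        t = make_table({1: [1.0, 2.0]})
        t = t.with_column("D", [0.0, 2.0], "divisor")
        out = ss.column_arithmetic(t, "Signal", "D", "/")
        assert out.records["Signal/D"].isna().tolist() == [True, False]
        assert "1 division(s) by zero" in out.derivation_log[-1]

    def test_scalar_operand(self):
        t = make_table({1: [1.0, 2.0]})
        out = ss.column_arithmetic(t, "Signal", 2.0, "*")
        assert out.records["Signal*2"].tolist() == [2.0, 4.0]


class TestFilterRows:
    def test_identity_and_empty_filters(self):
        t = make_table({1: [1.0, 2.0, 3.0]})
        keep = ss.filter_rows(t, "Signal > -999")
        assert len(keep) == len(t)
        drop = ss.filter_rows(t, "Signal > 999")
        assert len(drop) == 0
        assert list(drop.records.columns) == list(t.records.columns)

    def test_composition_equals_conjunction(self, rng):
        t = make_table({1: rng.normal(size=50).tolist()})
        t = t.with_column("B", rng.normal(size=50), "b")
        both = ss.filter_rows(ss.filter_rows(t, "Signal > 0"), "B > 0")
        conj = ss.filter_rows(t, "Signal > 0 and B > 0")
        assert both.records["well"].tolist() == conj.records["well"].tolist()

    def test_survivor_count_matches_brute_force(self, rng):
        vals = rng.normal(size=80)
        t = make_table({1: vals.tolist()})
        out = ss.filter_rows(t, "Signal >= 0.25")
        assert len(out) == int((vals >= 0.25).sum())

    def test_malformed_predicate_is_error(self):
        t = make_table({1: [1.0]})
        with pytest.raises(ValueError):
            ss.filter_rows(t, "nonsense ~~ 3")

    def test_predicate_recorded_in_provenance(self):
        t = make_table({1: [1.0, 2.0]})
        out = ss.filter_rows(t, "Signal > 1.5")
        assert "Signal > 1.5" in out.derivation_log[-1]


def _deconv_table(scores_by_gene, column="Signal"):
    """gene -> list of per-reagent scores."""
    genes, reagents, values = [], [], []
    for gene, scores in scores_by_gene.items():
        for i, s in enumerate(scores):
            genes.append(gene)
            reagents.append(f"{gene}.r{i + 1}")
            values.append(s)
    return make_table({1: values}, genes=genes, reagents=reagents, column=column)


class TestMultiReagent:
    def test_three_of_four_reagents_pass(self):
        t = _deconv_table({"TOP1": [0.9, 0.5, 0.31, 0.1], "LOW1": [0.1, 0.2, 0.0, 0.05]})
        res = ss.multi_reagent_counts(t, "Signal", 0.30)
        counts = dict(zip(res.gene_counts["gene_symbol"], res.gene_counts["n_passing"]))
        assert counts == {"TOP1": 3, "LOW1": 0}

    def test_validated_gene_rule_two_reagents(self):
        t = _deconv_table(
            {"A": [0.9, 0.8, 0.1, 0.1], "B": [0.5, 0.1, 0.1, 0.1], "C": [0.9, 0.9, 0.9, 0.9]}
        )
        res = ss.multi_reagent_counts(t, "Signal", 0.30)
        validated = res.validated_genes(min_reagents=2)
        assert validated["gene_symbol"].tolist() == ["C", "A"]

    def test_counts_match_brute_force_on_shuffled_input(self, rng):
        scores = {f"G{i:03d}": rng.uniform(0, 1, 4).tolist() for i in range(20)}
        t = _deconv_table(scores)
        shuffled = t.records.sample(frac=1, random_state=5).reset_index(drop=True)
        t2 = ss.ScreenTable(
            records=shuffled, data_columns=["Signal"], geometry=t.geometry,
            control_types=t.control_types,
        )
        res = ss.multi_reagent_counts(t2, "Signal", 0.5)
        rows = [
            (g, r, s)
            for g, rs in scores.items()
            for r, s in enumerate(rs)
        ]
        expected = brute_force_reagent_counts(rows, 0.5)
        got = {
            g: (int(tot), int(ok))
            for g, tot, ok in zip(
                res.gene_counts["gene_symbol"], res.gene_counts["n_total"], res.gene_counts["n_passing"]
            )
        }
        assert got == expected

    def test_missing_scores_do_not_count_toward_totals(self):
        t = _deconv_table({"A": [0.9, np.nan, 0.5, 0.1]})
        res = ss.multi_reagent_counts(t, "Signal", 0.30)
        assert res.gene_counts.loc[0, "n_total"] == 3
        assert res.gene_counts.loc[0, "n_passing"] == 2

    def test_missing_reagent_id_is_integrity_error(self):
        t = make_table({1: [0.5, 0.7]})  # no reagent ids at all
        with pytest.raises(ss.IntegrityError):
            ss.multi_reagent_counts(t, "Signal", 0.3)

    def test_ties_ranked_by_gene_symbol(self):
        t = _deconv_table({"ZZZ": [1.0, 1.0], "AAA": [1.0, 1.0]})
        res = ss.multi_reagent_counts(t, "Signal", 0.5)
        assert res.gene_counts["gene_symbol"].tolist() == ["AAA", "ZZZ"]


class TestFinalizeMultireagent:
    def test_flag_and_count_columns(self):
        t = _deconv_table({"A": [0.9, 0.5, 0.1, 0.1], "B": [0.1, 0.1, 0.1, 0.1]})
        res = ss.multi_reagent_counts(t, "Signal", 0.30)
        out = ss.finalize_multireagent(t, res)
        rec = out.records
        a = rec[rec["gene_symbol"] == "A"]
        b = rec[rec["gene_symbol"] == "B"]
        assert a["Signal_validated"].sum() == 2
        assert (a["Signal_n_validated"] == 2).all()
        assert (b["Signal_validated"] == 0).all()
        assert (b["Signal_n_validated"] == 0).all()

    def test_flag_sum_equals_count_within_every_gene(self, rng):
        scores = {f"G{i}": rng.uniform(0, 1, 4).tolist() for i in range(20)}
        t = _deconv_table(scores)
        res = ss.multi_reagent_counts(t, "Signal", 0.4)
        out = ss.finalize_multireagent(t, res)
        grouped = out.records.groupby("gene_symbol")
        for _, grp in grouped:
            assert grp["Signal_validated"].sum() == grp["Signal_n_validated"].iloc[0]
            assert grp["Signal_n_validated"].nunique() == 1

    def test_total_flags_equal_total_passing(self, rng):
        scores = {f"G{i}": rng.uniform(0, 1, 3).tolist() for i in range(30)}
        t = _deconv_table(scores)
        res = ss.multi_reagent_counts(t, "Signal", 0.6)
        assert res.reagent_flags["passed"].sum() == res.gene_counts["n_passing"].sum()
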