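"""Benchmark sets, ROC machinery, Fisher tests and logistic CV."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from oracles import (
    auc_pair_enumeration,
    fisher_two_sided_enumeration,
    ranksum_min_two_sided_p,
    threshold_search_oracle,
)
from phosphoswitch import simulate
from phosphoswitch.benchmark import (
    BenchmarkEntry,
    build_negative_set,
    compare_site_properties,
    filter_by_effect,
    filter_high_identity,
    filter_kinase_interactors,
    fisher_exact_p,
    load_benchmark_table,
    logistic_cv,
    oriented_scores,
    roc_pr_curves,
    threshold_at_fpr,
)

TABLE_HEADER = (
    "set\tprotein\tsite\tsite+-7AA\tinteractor\teffect\ttemplate\tpdbres\t"
    "IE\tf_ID\tf_Cons\tS_switch\tddG\tkinase\n"
)


def _entry(which="positive", effect="enabling", s=2.0, f_id=0.9, protein="P1",
           site="S10", kinase=False):
    return BenchmarkEntry(
        set=which, protein=protein, site=site, interactor="I1", effect=effect,
        ie=s, f_id=f_id, f_cons=0.8, s_switch=s, is_kinase=kinase,
    )


class TestLoadTable:
    def test_three_row_fixture(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(
            TABLE_HEADER
            + "positive\tP1\tS10\taaasaaa\tI1\tenabling\t1abc\tA10S\t2.0\t0.9\t0.8\t1.44\t\t0\n"
            + "negative\tP1\tS22\taaasaaa\tI1\tenabling\t1abc\t\t0.1\t0.9\t0.8\t0.07\t\t0\n"
            + "positive\tP2\tY5\taaayaaa\tI2\tdisabling\t2xyz\tB5Y\t-3.0\t1.0\t0.5\t-1.5\t-0.8\t1\n"
        )
        entries = load_benchmark_table(p)
        assert len(entries) == 3
        assert entries[2].is_kinase
        assert entries[2].ddg == pytest.approx(-0.8)
        assert entries[1].set == "negative"

    def test_invalid_set_value_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(TABLE_HEADER + "maybe\tP1\tS10\t\tI1\tenabling\t\t\t1\t1\t1\t1\t\t0\n")
        with pytest.raises(ValueError):
            load_benchmark_table(p)

    def test_missing_mandatory_column_rejected(self, tmp_path):
        p = tmp_path / "cols.tsv"
        p.write_text("protein\tsite\nP1\tS10\n")
        with pytest.raises(ValueError, match="missing mandatory"):
            load_benchmark_table(p)


class TestNegativeSet:
    SEQ = "A" + "SAYATA" * 4 + "S"  # S/T/Y positions known by construction

    def _exposures(self, seq, cls="exposed"):
        return {("P1", i + 1): cls for i, aa in enumerate(seq) if aa in "STY"}

    def test_ten_negatives_all_same_exposure_class(self):
        positives = [_entry(site="S2")]
        expo = self._exposures(self.SEQ)
        negs = build_negative_set(positives, {"P1": self.SEQ}, expo, n_shuffles=10, seed=1)
        assert len(negs) == 10
        positions = [int(n.site[1:]) for n in negs]
        assert all(expo[("P1", p)] == "exposed" for p in positions)
        assert all(n.effect == "enabling" and n.interactor == "I1" for n in negs)

    def test_shortfall_capped_without_replacement(self):
        seq = "ASAYASA"  # three S/T/Y apart from the positive
        positives = [_entry(site="S2")]
        expo = {("P1", p): "exposed" for p in (2, 4, 6)}
        negs = build_negative_set(positives, {"P1": seq}, expo, n_shuffles=10, seed=1)
        assert len(negs) == 2  # positions 4 and 6 only
        assert len({n.site for n in negs}) == len(negs)

    def test_deterministic_under_seed(self):
        positives = [_entry(site="S2")]
        expo = self._exposures(self.SEQ)
        a = build_negative_set(positives, {"P1": self.SEQ}, expo, seed=7)
        b = build_negative_set(positives, {"P1": self.SEQ}, expo, seed=7)
        assert [n.site for n in a] == [n.site for n in b]

    def test_exposure_class_preserved_when_eligible(self):
        expo = {("P1", i + 1): ("buried" if (i + 1) % 2 else "exposed")
                for i, aa in enumerate(self.SEQ) if aa in "STY"}
        positives = [_entry(site="S2")]  # buried? position 2 -> buried per rule
        own = expo[("P1", 2)]
        negs = build_negative_set(positives, {"P1": self.SEQ}, expo, n_shuffles=5, seed=3)
        positions = [int(n.site[1:]) for n in negs]
        assert all(expo[("P1", p)] == own for p in positions)


class TestRoc:
    SCORES = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2, 0.1]
    LABELS = [1, 1, 1, 0, 0, 0, 0]

    def test_auc_matches_pair_enumeration(self):
        curve = roc_pr_curves(self.SCORES, self.LABELS)
        assert curve.auc == pytest.approx(11 / 12)
        assert curve.auc == pytest.approx(auc_pair_enumeration(self.SCORES, self.LABELS))

    def test_perfect_separation(self):
        assert roc_pr_curves([3, 2, 1, 0], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_pr_curves([1, 1, 1, 1], [1, 0, 1, 0]).auc == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[0], labels[1] = 0, 1
        a = roc_pr_curves(scores, labels).auc
        b = roc_pr_curves(np.exp(2.0 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_absolute_mode_ranks_by_magnitude(self):
        scores = [-5.0, 4.0, 0.1, -0.2]
        labels = [1, 1, 0, 0]
        assert roc_pr_curves(scores, labels, direction="absolute").auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([1, 2], [1, 1])


class TestThresholdAtFpr:
    def test_worked_example(self):
        curve = roc_pr_curves(TestRoc.SCORES, TestRoc.LABELS)
        summ = threshold_at_fpr(curve, 0.05)
        assert summ.threshold == pytest.approx(0.8)
        assert summ.tpr == pytest.approx(2 / 3)
        assert summ.fpr == 0.0

    def test_integer_constraint_with_four_negatives(self):
        # 1/4 > 0.05: no false positive is allowed at max_fpr=0.05
        curve = roc_pr_curves(TestRoc.SCORES, TestRoc.LABELS)
        summ = threshold_at_fpr(curve, 0.05)
        assert summ.fp == 0

    def test_max_fpr_one_accepts_everything(self):
        curve = roc_pr_curves(TestRoc.SCORES, TestRoc.LABELS)
        summ = threshold_at_fpr(curve, 1.0)
        assert summ.tpr == 1.0
        assert summ.threshold == pytest.approx(min(TestRoc.SCORES))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 2)  # ties likely
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        max_fpr = float(rng.choice([0.01, 0.05, 0.2]))
        curve = roc_pr_curves(scores, labels)
        summ = threshold_at_fpr(curve, max_fpr)
        t, tpr, fpr, tnr, acc = threshold_search_oracle(scores, labels, max_fpr)
        assert summ.threshold == pytest.approx(t)
        assert summ.tpr == pytest.approx(tpr)
        assert summ.fpr == pytest.approx(fpr)
        assert summ.accuracy == pytest.approx(acc)


class TestFisher:
    def test_enumeration_of_three_tables(self):
        assert fisher_exact_p(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_identical_row_proportions(self):
        assert fisher_exact_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_strong_diagonal(self):
        assert fisher_exact_p(10, 0, 0, 10) < 1e-4

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_full_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        while True:
            tp, fp, fn, tn = rng.integers(0, 9, size=4)
            if tp + fp + fn + tn > 0 and tp + fp + fn + tn <= 30:
                break
        assert fisher_exact_p(tp, fp, fn, tn) == pytest.approx(
            fisher_two_sided_enumeration(int(tp), int(fp), int(fn), int(tn)),
            rel=1e-9,
        )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_p(0, 0, 0, 0)


class TestLogisticCv:
    def _separable_entries(self, n=40):
        entries = []
        for i in range(n):
            entries.append(_entry("positive", s=5.0 + 0.1 * i, site=f"S{i+2}"))
        for i in range(n):
            entries.append(_entry("negative", s=-1.0 + 0.02 * i, site=f"T{i+2}"))
        return entries

    def test_separable_feature_reaches_high_auc(self):
        cv = logistic_cv(self._separable_entries(), folds=5, reps=10, seed=1)
        assert cv.summary_mean["auc"] >= 0.99

    def test_label_independent_features_give_chance_auc(self):
        rng = np.random.default_rng(2)
        entries = []
        for i in range(300):
            which = "positive" if i % 2 else "negative"
            entries.append(
                BenchmarkEntry(
                    set=which, protein="P", site=f"S{i+2}", interactor="I",
                    effect="enabling", ie=rng.normal(), f_id=rng.uniform(),
                    f_cons=rng.uniform(), s_switch=rng.normal(),
                )
            )
        cv = logistic_cv(entries, folds=5, reps=20, seed=2)
        assert 0.4 <= cv.summary_mean["auc"] <= 0.6

    def test_every_rep_balanced(self):
        entries = self._separable_entries(25) + [
            _entry("negative", s=0.0, site=f"Y{i+100}") for i in range(30)
        ]
        cv = logistic_cv(entries, folds=5, reps=15, seed=0)
        assert all(n_pos == n_neg for n_pos, n_neg in cv.rep_class_counts)

    def test_planted_monotone_feature_recovers_positive_coefficient(self):
        cv = logistic_cv(self._separable_entries(), folds=5, reps=20, seed=3)
        assert cv.final_coef["IE"] > 0
        assert cv.coef_mean["IE"] > 0

    def test_deterministic_under_seed(self):
        entries = self._separable_entries()
        a = logistic_cv(entries, folds=5, reps=5, seed=9)
        b = logistic_cv(entries, folds=5, reps=5, seed=9)
        assert a.summary_mean == b.summary_mean


class TestFilters:
    def test_kinase_filter(self):
        entries = [_entry(kinase=(i < 2), site=f"S{i+2}") for i in range(5)]
        assert len(filter_kinase_interactors(entries)) == 3

    def test_kinase_filter_identity_when_none_flagged(self):
        entries = [_entry(site=f"S{i+2}") for i in range(4)]
        assert filter_kinase_interactors(entries) == entries

    def test_high_identity_filter(self):
        entries = [_entry(f_id=0.98), _entry(f_id=0.995)]
        kept = filter_high_identity(entries, 0.99)
        assert len(kept) == 1 and kept[0].f_id == pytest.approx(0.995)

    def test_effect_stratified(self):
        entries = [_entry(effect="enabling"), _entry(effect="disabling")]
        assert len(filter_by_effect(entries, "disabling")) == 1

    def test_oriented_scores_flip_disabling(self):
        entries = [_entry(effect="enabling", s=2.0), _entry(effect="disabling", s=-3.0)]
        assert list(oriented_scores(entries)) == [2.0, 3.0]


class TestSiteProperties:
    def test_identical_distributions_not_significant(self):
        vals = list(range(30))
        _, p = compare_site_properties(vals, vals, kind="continuous")
        assert p > 0.9

    def test_chi_square_hand_value(self):
        # 2x2 counts (90,10) vs (50,50): sum (O-E)^2/E = 38.095...
        a = [1] * 90 + [0] * 10
        b = [1] * 50 + [0] * 50
        chi2, p = compare_site_properties(a, b, kind="binary")
        assert chi2 == pytest.approx(800 / 21, abs=1e-9)
        assert p < 1e-8

    def test_disjoint_ranges_reach_minimal_p(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        _, p = compare_site_properties(a, b, kind="continuous")
        assert p == pytest.approx(ranksum_min_two_sided_p(3, 3))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_site_properties([], [1.0], kind="continuous")
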