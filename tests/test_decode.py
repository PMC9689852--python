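"""Decision rule, classifier ensemble, offline simulation and group stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_epochset
from cstpbci.decode import (
    OneVsOneForest,
    P0,
    PredictionBlock,
    decision_rule,
    draw_block,
    enumerate_chance,
    fit_classifier,
    group_stats,
    partition,
    random_baseline,
    run_offline,
    single_channel_accuracy,
)
from cstpbci.simulate import CLASSES

MC, MI, NT = "MC_target", "MI_target", "nontarget"


def rule_oracle(condition, preds):
    """Independent re-statement of the block rule by direct counting.

    Returns True/False, or None when the strategy vote is tied (the
    outcome then depends on the tie-breaker).
    """
    target = f"{condition}_target"
    tgt, nt = preds[:4], preds[4:]
    hits = sum(p != NT for p in tgt)
    if hits <= 4 - hits:
        return False
    exact = sum(p == target for p in tgt)
    wrong = hits - exact
    nt_correct = sum(p == NT for p in nt)
    clause2 = (nt_correct > 4 - nt_correct) or (4 - nt_correct < hits)
    if exact < wrong:
        return False
    if exact == wrong:
        return None if clause2 else False
    return clause2


def block(condition, preds, scores=None):
    return PredictionBlock(condition=condition, target_pred=list(preds[:4]),
                           nontarget_pred=list(preds[4:]),
                           target_scores=scores)


class TestDecisionRule:
    def test_three_of_four_both_clauses(self):
        assert decision_rule(block("MI", [MI, MI, MI, NT, NT, NT, NT, MI]))

    def test_two_detected_targets_insufficient(self):
        assert not decision_rule(block("MI", [MI, MI, NT, NT, NT, NT, NT, NT]))

    def test_nontarget_clause_fails_when_errors_match_hits(self):
        # 3 detected targets, 1 non-target correct: 1 !> 3 and 3 !< 3
        assert not decision_rule(block("MI", [MI, MI, MI, NT, NT, MI, MI, MI]))

    def test_wrong_strategy_majority_rejected(self):
        assert not decision_rule(block("MI", [MC, MC, MC, MI, NT, NT, NT, NT]))

    def test_tie_broken_by_vote_fractions(self):
        preds = [MI, MI, MC, MC, NT, NT, NT, NT]
        i_mi, i_mc = CLASSES.index(MI), CLASSES.index(MC)
        up, down = np.zeros((4, 3)), np.zeros((4, 3))
        up[:, i_mi], down[:, i_mc] = 1.0, 1.0
        assert decision_rule(block("MI", preds, scores=up))
        assert not decision_rule(block("MI", preds, scores=down))

    def test_agrees_with_counting_oracle_on_all_patterns(self):
        for pattern in itertools.product(CLASSES, repeat=8):
            expected = rule_oracle("MC", list(pattern))
            if expected is None:
                continue  # tie cases exercised separately
            assert decision_rule(block("MC", list(pattern))) == expected

    def test_wrong_epoch_count_rejected(self):
        with pytest.raises(ValueError):
            PredictionBlock(condition="MI", target_pred=[MI] * 3,
                            nontarget_pred=[NT] * 4)


class TestBaselines:
    def test_exact_chance_matches_weighted_enumeration(self):
        # independent enumeration: P(correct) with tied votes worth 1/2
        total = 0.0
        for pattern in itertools.product(CLASSES, repeat=8):
            res = rule_oracle("MI", list(pattern))
            total += 0.5 if res is None else float(res)
        np.testing.assert_allclose(enumerate_chance(), total / 3 ** 8, atol=1e-12)

    def test_monte_carlo_converges_to_exact(self):
        exact = enumerate_chance()
        mc = random_baseline(n_blocks=200_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 200_000)
        assert abs(mc - exact) < 4 * se

    def test_always_nontarget_classifier_scores_zero(self):
        assert not decision_rule(block("MI", [NT] * 8))


class TestClassifier:
    def test_separable_classes_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(loc, 0.1, size=(30, 4))
                       for loc in (-5.0, 0.0, 5.0)])
        y = np.repeat(list(CLASSES), 30)
        clf = fit_classifier(X[::2], y[::2], seed=0)
        pred, scores = clf.predict(X[1::2])
        assert (pred == y[1::2]).mean() == 1.0
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_shuffled_labels_give_chance_epoch_accuracy(self, rng):
        X = rng.standard_normal((300, 8))
        y = np.array(list(CLASSES) * 100, dtype=object)
        clf = fit_classifier(X[:225], y[:225], seed=1)
        pred, _ = clf.predict(X[225:])
        assert abs((pred == y[225:]).mean() - 1 / 3) < 0.15

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((90, 5))
        y = np.array(list(CLASSES) * 30, dtype=object)
        p1, s1 = fit_classifier(X, y, seed=5).predict(X)
        p2, s2 = fit_classifier(X, y, seed=5).predict(X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            OneVsOneForest().fit(X, np.array([MI] * 10, dtype=object))


class TestPartition:
    def test_pools_and_blocks_disjoint_and_deterministic(self):
        eps = make_epochset(n_per_class=20, seed=20)
        pools = partition(eps, pool_size=15, seed=4)
        pools2 = partition(eps, pool_size=15, seed=4)
        for label in CLASSES:
            np.testing.assert_array_equal(pools.indices[label],
                                          pools2.indices[label])
            assert len(set(pools.indices[label])) == 15
        rng = np.random.default_rng(0)
        test, train = draw_block(pools, "MI", rng)
        assert len(test) == 8 and len(train) == 3 * 15 - 8
        assert set(test).isdisjoint(train)

    def test_insufficient_epochs_names_class(self):
        eps = make_epochset(n_per_class=5, seed=21)
        with pytest.raises(ValueError, match="MC_target"):
            partition(eps, pool_size=10, seed=0)


@pytest.fixture(scope="module")
def small_epochs():
    # strongly separable small dataset: class-specific temporal signatures
    t = np.linspace(0, 1, 126)
    sigs = {
        MC: 4.0 * np.outer(np.ones(8), np.sin(2 * np.pi * 2 * t)),
        MI: 4.0 * np.outer(np.ones(8), np.sin(2 * np.pi * 4 * t)),
    }
    return make_epochset(n_per_class=20, n_channels=8, n_samples=126,
                         seed=22, signal=sigs)


class TestRunOffline:

    def test_separable_data_reach_perfect_accuracy(self, small_epochs):
        rep = run_offline(small_epochs, feature_mode="raw", n_repetitions=2,
                          seed=1, pool_size=12, n_estimators=50)
        assert rep.accuracy == 1.0
        assert rep.kappa == pytest.approx(1.0)
        assert rep.n_blocks == 4

    def test_confusion_counts_conserved(self, small_epochs):
        rep = run_offline(small_epochs, feature_mode="cstp", n_repetitions=2,
                          seed=2, pool_size=12, n_estimators=25, clean=False)
        assert rep.confusion.to_numpy().sum() == 8 * rep.n_blocks
        # row sums equal the number of classified epochs per true class
        assert rep.confusion.loc[NT].sum() == 4 * rep.n_blocks

    def test_unused_epochs_do_not_leak_into_predictions(self, small_epochs):
        pools = partition(small_epochs, pool_size=12, seed=3)
        used = set(np.concatenate(list(pools.indices.values())))
        unused = sorted(set(range(small_epochs.n_epochs)) - used)
        assert unused
        corrupted = small_epochs.select(range(small_epochs.n_epochs))
        corrupted.data[unused[0]] = 1e3
        kwargs = dict(feature_mode="cstp", n_repetitions=1, seed=3,
                      pool_size=12, n_estimators=25, clean=False)
        ref = run_offline(small_epochs, **kwargs)
        alt = run_offline(corrupted, **kwargs)
        assert ref.outcomes == alt.outcomes
        pd.testing.assert_frame_equal(ref.confusion, alt.confusion)

    def test_corrupting_training_epochs_changes_predictions(self, small_epochs):
        pools = partition(small_epochs, pool_size=12, seed=3)
        corrupted = small_epochs.select(range(small_epochs.n_epochs))
        for label in CLASSES:
            corrupted.data[pools.indices[label][:6]] = np.random.default_rng(
                99
            ).standard_normal(corrupted.data[0].shape) * 50.0
        kwargs = dict(feature_mode="cstp", n_repetitions=1, seed=3,
                      pool_size=12, n_estimators=25, clean=False)
        ref = run_offline(small_epochs, **kwargs)
        alt = run_offline(corrupted, **kwargs)
        assert (not ref.outcomes == alt.outcomes
                or not ref.confusion.equals(alt.confusion))


class TestSingleChannel:
    def test_informative_channel_ranks_first(self):
        t = np.linspace(0, 1, 76)
        bump = np.sin(2 * np.pi * 3 * t)
        sig_mi = np.zeros((3, 76)); sig_mi[1] = 5.0 * bump
        sig_mc = np.zeros((3, 76)); sig_mc[1] = -5.0 * bump
        eps = make_epochset(n_per_class=20, n_channels=3, n_samples=76, seed=23,
                            signal={MI: sig_mi, MC: sig_mc})
        accs = single_channel_accuracy(eps, seed=1, n_repetitions=2,
                                       pool_size=12, n_estimators=25)
        assert len(accs) == 3
        assert accs.idxmax() == "ch1"

    def test_single_channel_input_rejected(self):
        eps = make_epochset(n_per_class=20, n_channels=1, n_samples=30, seed=24)
        with pytest.raises(ValueError):
            single_channel_accuracy(eps)


class TestGroupStats:
    def test_identical_paired_samples_null(self):
        out = group_stats([0.5] * 8, [0.5] * 8)
        assert out["wilcoxon_raw_vs_cstp"]["pvalue"] == 1.0

    def test_friedman_matches_rank_formula(self):
        # tie-free table; compare against the classical rank statistic
        table = pd.DataFrame(
            {"A": [1.0, 2.1, 3.2, 1.5, 2.2, 3.4],
             "B": [2.0, 3.1, 1.2, 2.5, 3.2, 1.4],
             "C": [3.0, 1.1, 2.2, 3.5, 1.2, 2.4]}
        )
        n, k = table.shape
        ranks = table.rank(axis=1)
        rj = ranks.sum(axis=0).to_numpy()
        expected = 12.0 / (n * k * (k + 1)) * (rj ** 2).sum() - 3 * n * (k + 1)
        out = group_stats(electrode_table=table)
        assert out["friedman"]["chi2"] == pytest.approx(expected)

    def test_dominant_electrode_survives_bonferroni(self, rng):
        n_subj, n_elec = 12, 22
        table = pd.DataFrame(
            P0 + rng.normal(0, 0.02, size=(n_subj, n_elec)),
            columns=[f"e{i}" for i in range(n_elec)],
        )
        table["e0"] = 0.6 + rng.normal(0, 0.02, size=n_subj)
        out = group_stats(electrode_table=table)
        assert bool(out["electrodes"].loc["e0", "significant"])

    def test_few_subjects_warns_but_computes(self):
        out = group_stats([0.4, 0.5, 0.6], [0.6, 0.7, 0.8])
        assert "warning" in out
        assert out["wilcoxon_raw_vs_cstp"]["pvalue"] < 1.0
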