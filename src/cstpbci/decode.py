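"""Offline BCI simulation: block-level prediction rule, accuracy and baselines.

The offline procedure emulates one BCI selection ("prediction block") from
eight stimulus presentations: 4 target epochs of a single condition (MC or
MI) and 4 non-target epochs.  A 3-class decoder labels each epoch; the
block outcome is derived from the per-epoch labels by a two-clause rule
plus a strategy vote:

* **detection** — among the 4 target presentations, classifications as a
  target (either target class) must strictly exceed misses;
* **strategy** — the block's mental strategy is the majority class among
  the target-class labels; ties are broken by the summed classifier vote
  fractions for the two target classes (a fair coin for a random
  classifier); the majority must be the condition actually tested;
* **non-targets** — correct non-target classifications must strictly
  exceed errors, or the number of non-target errors must be strictly less
  than the number of detected targets.

Under uniformly random epoch labels this rule is satisfied with
probability 1048/6561 ≈ 0.16, the empirical chance level of the paradigm
(the nominal per-epoch chance is p0 = 0.33).

Accuracy is estimated per subject from repeated blocks drawn from fixed
90/90/90 class pools; spatial/temporal filters and the classifier are
refit on the training remainder for every block, so no test epoch ever
influences feature extraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .cstp import extract_features, fit_cstp
from .preprocess import EpochSet, concatenate_raw
from .simulate import CLASSES, CONDITIONS, MC_TARGET, MI_TARGET, NONTARGET

P0 = 0.33  # assumed per-epoch chance level of the 3-class decoder

_TARGET_OF = {"MC": MC_TARGET, "MI": MI_TARGET}
_OTHER_TARGET = {"MC": MI_TARGET, "MI": MC_TARGET}


@dataclass
class PredictionBlock:
    """One offline BCI decision: 4 target + 4 non-target test epochs."""

    condition: str                       # 'MC' or 'MI'
    target_pred: list                    # 4 predicted labels
    nontarget_pred: list                 # 4 predicted labels
    target_scores: np.ndarray | None = None     # 4 x 3 vote fractions (CLASSES order)
    nontarget_scores: np.ndarray | None = None
    outcome: bool | None = None

    def __post_init__(self):
        if len(self.target_pred) != 4 or len(self.nontarget_pred) != 4:
            raise ValueError("a prediction block needs 4 target + 4 non-target epochs")


@dataclass
class AccuracyReport:
    """Offline accuracy of one subject with its chance-corrected agreement."""

    accuracy: float
    kappa: float
    n_blocks: int
    feature_mode: str
    confusion: pd.DataFrame              # 3 x 3 epoch-level counts (true x predicted)
    p0: float = P0
    outcomes: list = field(default_factory=list)


def decision_rule(block: PredictionBlock, rng: np.random.Generator | None = None) -> bool:
    """Evaluate the two-clause correctness rule on one prediction block.

    Strategy-vote ties are broken by classifier vote fractions when the
    block carries scores, by a coin flip from ``rng`` otherwise; with
    neither available a tie counts as incorrect.
    """
    target_class = _TARGET_OF[block.condition]
    other_class = _OTHER_TARGET[block.condition]
    t_hits = sum(p in (MC_TARGET, MI_TARGET) for p in block.target_pred)
    if not t_hits > 4 - t_hits:
        return False
    a = sum(p == target_class for p in block.target_pred)
    b = t_hits - a
    if a < b:
        return False
    if a == b:
        if block.target_scores is not None:
            i_t, i_o = CLASSES.index(target_class), CLASSES.index(other_class)
            s = block.target_scores.sum(axis=0)
            if not s[i_t] > s[i_o]:
                return False
        elif rng is not None:
            if rng.random() >= 0.5:
                return False
        else:
            return False
    nt_correct = sum(p == NONTARGET for p in block.nontarget_pred)
    nt_errors = 4 - nt_correct
    return (nt_correct > nt_errors) or (nt_errors < t_hits)


def enumerate_chance() -> float:
    """Exact block-success probability under uniformly random epoch labels.

    Enumerates all 3^8 prediction patterns; strategy-vote ties contribute
    probability 1/2 (the coin-flip tie-break).
    """
    total = 0.0
    for pattern in itertools.product(range(3), repeat=8):
        tgt, nt = pattern[:4], pattern[4:]
        a = sum(x == 0 for x in tgt)          # condition's target class
        b = sum(x == 1 for x in tgt)          # other target class
        t_hits = a + b
        if not t_hits > 4 - t_hits:
            continue
        p_strategy = 1.0 if a > b else (0.5 if a == b else 0.0)
        nt_correct = sum(x == 2 for x in nt)
        if (nt_correct > 4 - nt_correct) or (4 - nt_correct < t_hits):
            total += p_strategy
    return total / 3 ** 8


def random_baseline(n_blocks: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo chance level: uniform random labels pushed through the rule."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=(n_blocks, 8))
    tgt, nt = labels[:, :4], labels[:, 4:]
    a = (tgt == 0).sum(axis=1)
    b = (tgt == 1).sum(axis=1)
    t_hits = a + b
    detection = t_hits > 4 - t_hits
    coin = rng.random(n_blocks) < 0.5
    strategy = (a > b) | ((a == b) & coin)
    nt_correct = (nt == 2).sum(axis=1)
    clause2 = (nt_correct > 4 - nt_correct) | ((4 - nt_correct) < t_hits)
    return float((detection & strategy & clause2).mean())


class OneVsOneForest:
    """Three binary random forests (100 trees each) with majority voting.

    Epoch-level prediction: each binary forest votes for one of its two
    classes; the class with most votes wins, ties broken by summed class
    vote fractions.  ``scores`` are the per-class sums of binary vote
    fractions, normalized to 1 per epoch.
    """

    def __init__(self, n_estimators: int = 100, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed
        self.models_: dict = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsOneForest":
        y = np.asarray(y, dtype=object)
        present = set(np.unique(y.astype(str)))
        if len(present) < 2:
            raise ValueError("training data must contain at least two classes")
        for k, pair in enumerate(itertools.combinations(CLASSES, 2)):
            mask = np.isin(y, pair)
            if len(set(y[mask].astype(str))) < 2:
                raise ValueError(f"missing class in pair {pair}")
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.seed + k, n_jobs=1
            )
            clf.fit(X[mask], y[mask].astype(str))
            self.models_[pair] = clf
        return self

    def predict(self, X: np.ndarray):
        """Return (labels, scores); scores columns follow ``CLASSES`` order."""
        n = X.shape[0]
        votes = np.zeros((n, len(CLASSES)))
        fractions = np.zeros((n, len(CLASSES)))
        for pair, clf in self.models_.items():
            proba = clf.predict_proba(X)
            for cls, p in zip(clf.classes_, proba.T):
                j = CLASSES.index(cls)
                fractions[:, j] += p
            winners = clf.classes_[np.argmax(proba, axis=1)]
            for j, cls in enumerate(CLASSES):
                votes[:, j] += winners == cls
        # majority of binary votes; break ties by summed vote fractions
        keys = votes + 1e-6 * fractions
        labels = np.array([CLASSES[i] for i in np.argmax(keys, axis=1)], dtype=object)
        scores = fractions / fractions.sum(axis=1, keepdims=True)
        return labels, scores


def fit_classifier(X: np.ndarray, y: np.ndarray, seed: int = 0,
                   n_estimators: int = 100) -> OneVsOneForest:
    return OneVsOneForest(n_estimators=n_estimators, seed=seed).fit(X, y)


@dataclass
class Pools:
    """Fixed per-subject working pools: epoch indices per class."""

    indices: dict  # class label -> np.ndarray of epoch indices (pool_size each)


def partition(epochs: EpochSet, pool_size: int = 90, seed: int = 0) -> Pools:
    """Draw the fixed 90/90/90 class pools for one subject."""
    rng = np.random.default_rng(seed)
    indices = {}
    for label in CLASSES:
        cls = np.flatnonzero(epochs.labels == label)
        if len(cls) < pool_size:
            raise ValueError(
                f"class {label} has {len(cls)} epochs; needs >= {pool_size}"
            )
        indices[label] = rng.choice(cls, size=pool_size, replace=False)
    return Pools(indices=indices)


def draw_block(pools: Pools, condition: str, rng: np.random.Generator):
    """Split the pools into an 8-epoch test block and the training remainder."""
    target_class = _TARGET_OF[condition]
    test_t = rng.choice(pools.indices[target_class], size=4, replace=False)
    test_nt = rng.choice(pools.indices[NONTARGET], size=4, replace=False)
    test = np.concatenate([test_t, test_nt])
    train = np.concatenate(
        [np.setdiff1d(pool, test) for pool in pools.indices.values()]
    )
    return test, train


def _features(epochs: EpochSet, mode: str, model=None) -> np.ndarray:
    if mode == "cstp":
        return extract_features(epochs, model)
    if mode == "raw":
        return concatenate_raw(epochs).X
    raise ValueError(f"unknown feature mode {mode!r}")


def run_offline(epochs: EpochSet, feature_mode: str = "cstp",
                n_repetitions: int = 20, seed: int = 0, pool_size: int = 90,
                channels=None, n_estimators: int = 100,
                clean: bool = True) -> AccuracyReport:
    """Simulate repeated offline BCI predictions for one subject.

    Per repetition and per condition (MC, MI), an 8-epoch test block is
    drawn from the fixed class pools; CSTP filters (in ``cstp`` mode) and
    the one-vs-one forest are fit on the training remainder only, the test
    epochs are classified, and the block outcome follows
    :func:`decision_rule`.  Cohen's kappa uses the nominal per-epoch chance
    ``p0 = 0.33``.
    """
    if channels is not None:
        epochs = epochs.select_channels(channels)
    pools = partition(epochs, pool_size=pool_size, seed=seed)
    rng = np.random.default_rng(seed + 1)
    outcomes = []
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for rep in range(n_repetitions):
        for condition in CONDITIONS:
            test_idx, train_idx = draw_block(pools, condition, rng)
            train, test = epochs.select(train_idx), epochs.select(test_idx)
            model = None
            if feature_mode == "cstp":
                model = fit_cstp(train, clean=clean)
            Xtr = _features(train, feature_mode, model)
            Xte = _features(test, feature_mode, model)
            clf = fit_classifier(Xtr, train.labels, seed=seed + 7919 * rep,
                                 n_estimators=n_estimators)
            pred, scores = clf.predict(Xte)
            for true, p in zip(test.labels, pred):
                confusion.loc[true, p] += 1
            block = PredictionBlock(
                condition=condition,
                target_pred=list(pred[:4]), nontarget_pred=list(pred[4:]),
                target_scores=scores[:4], nontarget_scores=scores[4:],
            )
            block.outcome = decision_rule(block)
            outcomes.append(block.outcome)
    accuracy = float(np.mean(outcomes))
    kappa = (accuracy - P0) / (1.0 - P0)
    return AccuracyReport(accuracy=accuracy, kappa=kappa, n_blocks=len(outcomes),
                          feature_mode=feature_mode, confusion=confusion,
                          outcomes=outcomes)


def single_channel_accuracy(epochs: EpochSet, seed: int = 0,
                            n_repetitions: int = 20, pool_size: int = 90,
                            n_estimators: int = 100) -> pd.Series:
    """Raw-feature offline accuracy using one electrode at a time."""
    if epochs.n_channels < 2:
        raise ValueError("need at least two channels")
    accs = {}
    for ch in epochs.channel_labels:
        report = run_offline(epochs, feature_mode="raw", n_repetitions=n_repetitions,
                             seed=seed, pool_size=pool_size, channels=[ch],
                             n_estimators=n_estimators)
        accs[ch] = report.accuracy
    return pd.Series(accs, name="accuracy")


def group_stats(raw_accuracies=None, cstp_accuracies=None,
                electrode_table: pd.DataFrame | None = None, p0: float = P0) -> dict:
    """Group-level statistics over subjects.

    * paired Wilcoxon signed-rank of raw vs CSTP accuracies;
    * Friedman test of single-channel accuracies across electrodes
      (``electrode_table``: subjects x electrodes);
    * per-electrode Wilcoxon vs the nominal chance ``p0``,
      Bonferroni-corrected over electrodes.
    """
    out: dict = {}
    if raw_accuracies is not None and cstp_accuracies is not None:
        raw = np.asarray(raw_accuracies, dtype=float)
        cstp = np.asarray(cstp_accuracies, dtype=float)
        if len(raw) < 6:
            out["warning"] = "fewer than 6 subjects; tests are underpowered"
        if np.allclose(raw, cstp):
            out["wilcoxon_raw_vs_cstp"] = {"statistic": np.nan, "pvalue": 1.0}
        else:
            res = stats.wilcoxon(raw, cstp)
            out["wilcoxon_raw_vs_cstp"] = {"statistic": float(res.statistic),
                                           "pvalue": float(res.pvalue)}
    if electrode_table is not None:
        cols = [electrode_table[c].to_numpy(dtype=float) for c in electrode_table]
        chi2, p = stats.friedmanchisquare(*cols)
        out["friedman"] = {"chi2": float(chi2), "pvalue": float(p)}
        pvals = []
        for c in electrode_table:
            x = electrode_table[c].to_numpy(dtype=float) - p0
            if np.allclose(x, 0):
                pvals.append(1.0)
            else:
                pvals.append(float(stats.wilcoxon(x, alternative="greater").pvalue))
        reject, corrected, _, _ = multipletests(pvals, alpha=0.05, method="bonferroni")
        out["electrodes"] = pd.DataFrame(
            {"pvalue": pvals, "pvalue_bonferroni": corrected, "significant": reject},
            index=list(electrode_table.columns),
        )
    return out
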