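"""Evaluation harnesses and statistics.

* Wolpaw information transfer rate (ITR): bits per trial
  ``B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1))`` scaled by the
  classification rate ``Q = 60 / T`` trials per minute.
* leave-one-subject-out cross-validation (LOSOCV) and repeated stratified
  hold-out (default 30 repeats at 70/30).
* PERMANOVA on Euclidean distances between flattened feature vectors
  (1000 permutations) and the Wilcoxon signed-rank test for paired
  pre/post comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ITRParams",
    "CVReport",
    "itr_bits_per_trial",
    "itr",
    "losocv",
    "repeated_holdout",
    "permanova",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class ITRParams:
    n_targets: int = 4
    accuracy: float = 1.0
    trial_time: float = 4.5  # seconds per classification

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValueError("need at least 2 targets")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(f"accuracy must be in [0, 1], got {self.accuracy}")
        if self.trial_time <= 0:
            raise ValueError("trial_time must be positive")


def itr_bits_per_trial(n: int, p: float) -> float:
    """Wolpaw bits per trial, with ``0 log 0 := 0``."""
    b = np.log2(n)
    if p > 0:
        b += p * np.log2(p)
    if p < 1:
        b += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(b)


def itr(params: ITRParams) -> float:
    """ITR in bit/min.  Below-chance accuracy yields a negative value."""
    b = itr_bits_per_trial(params.n_targets, params.accuracy)
    q = 60.0 / params.trial_time
    return b * q


@dataclass
class CVReport:
    scheme: str
    fold_accuracy: list[float]
    trial_time: float = 4.5
    n_targets: int = 4
    split_ratio: float | None = None
    excluded_per_fold: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    @property
    def fold_itr(self) -> list[float]:
        return [itr(ITRParams(self.n_targets, a, self.trial_time))
                for a in self.fold_accuracy]

    @property
    def mean_itr(self) -> float:
        """Mean of per-fold ITRs (not the ITR of the mean accuracy)."""
        return float(np.mean(self.fold_itr))


def losocv(groups: dict[int, Sequence], train_fn: Callable,
           classify_fn: Callable, labels_fn: Callable,
           trial_time: float = 4.5) -> CVReport:
    """Leave-one-subject-out: train on all-but-one subject, test on the rest.

    ``train_fn(train_items) -> model``; ``classify_fn(model, item) -> label
    or None`` (``None`` marks an excluded trial, which never enters the
    accuracy denominator); ``labels_fn(item) -> true label``.
    """
    if len(groups) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")
    accs, excluded = [], []
    for held_out in sorted(groups):
        train_items = [it for s, items in groups.items() if s != held_out
                       for it in items]
        model = train_fn(train_items)
        hits = total = skipped = 0
        for item in groups[held_out]:
            pred = classify_fn(model, item)
            if pred is None:
                skipped += 1
                continue
            total += 1
            hits += int(pred == labels_fn(item))
        accs.append(hits / total if total else 0.0)
        excluded.append(skipped)
    return CVReport("losocv", accs, trial_time, excluded_per_fold=excluded)


def repeated_holdout(items: Sequence, labels: Sequence[int],
                     train_fn: Callable, classify_fn: Callable,
                     ratio: float = 0.3, repeats: int = 30, seed: int = 0,
                     trial_time: float = 5.0) -> CVReport:
    """Stratified repeated hold-out (within-subject validation)."""
    from sklearn.model_selection import StratifiedShuffleSplit

    y = np.asarray(labels)
    accs = []
    splitter = StratifiedShuffleSplit(n_splits=repeats, test_size=ratio,
                                      random_state=seed)
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        model = train_fn([items[i] for i in train_idx],
                         [int(y[i]) for i in train_idx])
        preds = [classify_fn(model, items[i]) for i in test_idx]
        accs.append(float(np.mean([p == y[i]
                                   for p, i in zip(preds, test_idx)])))
    return CVReport("repeated_holdout", accs, trial_time, split_ratio=ratio)


def permanova(features: np.ndarray, groups: Sequence, n_perm: int = 1000,
              seed: int = 0) -> tuple[float, float]:
    """Permutational MANOVA on Euclidean distances between feature vectors.

    Returns ``(pseudo_F, p)`` with ``p = (1 + #{perm F >= obs}) / (1 + n_perm)``.
    """
    from scipy.spatial.distance import pdist, squareform

    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        x = x.reshape(x.shape[0], -1)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2 or counts.min() < 3:
        raise ValueError("PERMANOVA needs >= 2 groups with >= 3 members each")
    d2 = squareform(pdist(x, metric="euclidean")) ** 2
    n = x.shape[0]
    g = np.asarray(groups)

    def pseudo_f(perm_g: np.ndarray) -> float:
        sst = d2.sum() / (2 * n)
        ssw = 0.0
        for lab in labels:
            mask = perm_g == lab
            nj = mask.sum()
            ssw += d2[np.ix_(mask, mask)].sum() / (2 * nj)
        ssa = sst - ssw
        dfa = labels.size - 1
        dfw = n - labels.size
        return (ssa / dfa) / (ssw / dfw)

    f_obs = pseudo_f(g)
    rng = np.random.default_rng(seed)
    count = sum(pseudo_f(rng.permutation(g)) >= f_obs for _ in range(n_perm))
    return float(f_obs), float((1 + count) / (1 + n_perm))


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float]
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; zero differences are dropped."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    if np.all(pre == post):
        raise ValueError("all differences are zero; test is degenerate")
    res = stats.wilcoxon(pre, post, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)
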