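"""Site-stratified train/validation/test partitioning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit


@dataclass
class SplitAssignment:
    """Exhaustive, disjoint participant partition stratified by site."""

    train: np.ndarray  # integer row indices
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def labels(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=object)
        out[self.train] = "train"
        out[self.val] = "val"
        out[self.test] = "test"
        return out

    def indices(self, which: str) -> np.ndarray:
        return {"train": self.train, "val": self.val, "test": self.test}[which]


def stratified_split(
    n_or_table,
    site_labels,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Randomized 80/10/10 split preserving per-site proportions.

    ``n_or_table`` is either a participant count or any object with an
    ``n_participants`` attribute. Two stratified shuffle-splits are chained:
    train vs holdout, then holdout into validation and test.
    """
    n = getattr(n_or_table, "n_participants", n_or_table)
    site_labels = np.asarray(site_labels)
    if len(site_labels) != n:
        raise ValueError("site_labels length does not match participant count")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    _, counts = np.unique(site_labels, return_counts=True)
    small = np.unique(site_labels)[counts < 3]
    if small.size:
        raise ValueError(f"sites with fewer than 3 participants cannot be split: {small.tolist()}")

    f_train, f_val, f_test = fractions
    holdout = f_val + f_test
    sss1 = StratifiedShuffleSplit(n_splits=1, test_size=holdout, random_state=seed)
    train_idx, hold_idx = next(sss1.split(np.zeros(n), site_labels))
    sss2 = StratifiedShuffleSplit(
        n_splits=1, test_size=f_test / holdout, random_state=seed + 1
    )
    v_rel, t_rel = next(sss2.split(np.zeros(len(hold_idx)), site_labels[hold_idx]))
    return SplitAssignment(
        train=np.sort(train_idx),
        val=np.sort(hold_idx[v_rel]),
        test=np.sort(hold_idx[t_rel]),
        fractions=fractions,
        seed=seed,
    )
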