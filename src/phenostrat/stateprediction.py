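"""State-of-residence prediction from SES-only component scores.

The multidimensionality check: if the chosen components carry genuinely
distinct socioeconomic signatures, then a participant's SES-only component
scores — dot products of their curated Socioeconomic measurements with each
component's (masked) SES loadings — should predict geography. A one-vs-rest
L2-regularized logistic regression under stratified 10-fold cross-validation
pools out-of-fold predictions into a states x states confusion matrix;
per-state coefficient means across folds identify the most influential
component per state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier

from .components import LoadingMatrix, ThresholdMask


@dataclass
class SesScores:
    """Participants x chosen-components SES-only scores."""

    values: np.ndarray
    components: list[str]
    participant_ids: list
    masked: bool = True

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.participant_ids, columns=self.components)


@dataclass
class StatePredictionResult:
    confusion: pd.DataFrame  # states x states, row percentages
    per_state_accuracy: pd.Series  # diagonal of the confusion matrix
    coefficients: pd.DataFrame  # states x components, mean over folds
    chance_level: float  # percent
    above_chance: list  # states with accuracy > chance
    overall_accuracy: float  # percent of pooled out-of-fold predictions correct
    densities: dict = field(default_factory=dict)  # state -> component -> (grid, density)
    n_folds: int = 10
    seed: int = 0


def chance_level(n_states: int) -> float:
    """Chance accuracy for equiprobable class guessing, in percent."""
    return 100.0 / n_states


def ses_component_scores(x, loadings: LoadingMatrix, mask: ThresholdMask,
                         components: list[str], meta, masked: bool = True,
                         category: str = "Socioeconomic",
                         participant_ids=None) -> SesScores:
    """Dot product of curated SES values with per-component SES loadings.

    With ``masked`` (default) only SES variables retained in each component
    contribute; unmasked mode uses all SES loadings, for sensitivity checks.
    """
    xv = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    names = list(getattr(x, "variable_names", loadings.r.index))
    if participant_ids is None:
        participant_ids = list(getattr(x, "participant_ids", range(xv.shape[0])))
    from .profiles import _variable_categories

    cats = _variable_categories(meta, names)
    ses = np.array([cats.get(v) == category for v in names])
    if not ses.any():
        raise ValueError(f"no variables in category {category!r}")
    col_of = {v: j for j, v in enumerate(names)}

    out = np.zeros((xv.shape[0], len(components)))
    for jc, comp in enumerate(components):
        if comp not in loadings.r.columns:
            raise ValueError(f"component {comp!r} not in loadings")
        w = loadings.r[comp].copy()
        if masked:
            w = w.where(mask.mask[comp], 0.0)
        w_ses = [(v, w[v]) for v in loadings.r.index if cats.get(v) == category]
        active = [v for v, wv in w_ses if wv != 0.0]
        if masked and not active:
            raise ValueError(f"no SES variables retained in component {comp!r}")
        cols = np.array([col_of[v] for v, _ in w_ses])
        vec = np.array([wv for _, wv in w_ses])
        out[:, jc] = xv[:, cols] @ vec
    return SesScores(values=out, components=list(components),
                     participant_ids=participant_ids, masked=masked)


def predict_state(scores: SesScores, state_labels, n_folds: int = 10, seed: int = 0,
                  C: float = 1.0, density_grid: int = 64) -> StatePredictionResult:
    """One-vs-rest logistic regression under stratified k-fold CV.

    Out-of-fold predictions are pooled into a row-percentage confusion
    matrix; coefficients are averaged over folds per state; per-state score
    density curves (Gaussian KDE on a fixed grid) summarise the component
    distributions.
    """
    y = np.asarray(state_labels)
    xs = scores.values
    states, counts = np.unique(y, return_counts=True)
    short = states[counts < n_folds]
    if short.size:
        raise ValueError(
            f"states with fewer than {n_folds} participants: {short.tolist()}"
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    coef_sums = np.zeros((len(states), xs.shape[1]))
    state_row = {s: i for i, s in enumerate(states)}
    for train_idx, test_idx in skf.split(xs, y):
        # ridge-type (L2) penalty at strength 1/C — sklearn's default penalty
        clf = OneVsRestClassifier(LogisticRegression(C=C, max_iter=2000))
        clf.fit(xs[train_idx], y[train_idx])
        y_pred[test_idx] = clf.predict(xs[test_idx])
        for est, cls in zip(clf.estimators_, clf.classes_):
            coef_sums[state_row[cls]] += est.coef_[0]
    coef_mean = coef_sums / n_folds

    conf_counts = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(y_pred, name="predicted"), dropna=False
    ).reindex(index=states, columns=states, fill_value=0)
    confusion = 100.0 * conf_counts.div(conf_counts.sum(axis=1), axis=0)
    per_state = pd.Series(np.diag(confusion), index=states, name="accuracy_pct")
    chance = chance_level(len(states))
    overall = 100.0 * float(np.mean(y_pred == y))

    densities: dict = {}
    for s in states:
        rows = xs[y == s]
        densities[s] = {}
        for jc, comp in enumerate(scores.components):
            col = rows[:, jc]
            lo, hi = float(xs[:, jc].min()), float(xs[:, jc].max())
            grid = np.linspace(lo, hi, density_grid)
            if np.std(col) == 0:
                dens = np.zeros_like(grid)
            else:
                dens = gaussian_kde(col)(grid)
            densities[s][comp] = (grid, dens)

    return StatePredictionResult(
        confusion=confusion,
        per_state_accuracy=per_state,
        coefficients=pd.DataFrame(coef_mean, index=states, columns=scores.components),
        chance_level=chance,
        above_chance=[s for s in states if per_state[s] > chance],
        overall_accuracy=overall,
        densities=densities,
        n_folds=n_folds,
        seed=seed,
    )


def most_influential_component(result: StatePredictionResult) -> pd.Series:
    """Per state, the component with the largest mean |coefficient|.

    Ties (including the all-zero degenerate case) resolve to the earliest
    component in column order.
    """
    coefs = result.coefficients.abs().to_numpy()
    idx = np.argmax(coefs, axis=1)  # argmax takes the first maximum
    return pd.Series(
        [result.coefficients.columns[i] for i in idx],
        index=result.coefficients.index,
        name="most_influential_component",
    )


def permutation_null_accuracies(scores: SesScores, state_labels, n_permutations: int = 20,
                                n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Overall CV accuracy under label permutation — the chance band."""
    rng = np.random.default_rng(seed)
    y = np.asarray(state_labels)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(y))
        res = predict_state(scores, y[perm], n_folds=n_folds, seed=seed + i + 1,
                            density_grid=2)
        out[i] = res.overall_accuracy
    return out
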