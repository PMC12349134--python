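"""Latent-component scores, loadings, ablation ranking and thresholding.

A component is one coordinate of the trained latent space; a participant's
score on it is the encoder posterior mean (a seeded sample optionally). A
variable's loading on a component is the Pearson correlation between the
component's scores and the variable across a participant subset; its
absolute value is the weight strength used for attribution. Components are
ranked by single-component ablation: decode from each component alone (all
other latent coordinates zeroed, conditioning untouched) and order by the
resulting test reconstruction error, ascending — the best-ranked components
degrade reconstruction least on their own.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LatentScores:
    """Participants x K component scores with provenance."""

    values: np.ndarray
    participant_ids: list
    mode: str = "posterior_mean"
    split: str = "test"

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.participant_ids,
            columns=[f"comp{j:03d}" for j in range(self.k)],
        )


@dataclass
class LoadingMatrix:
    """Variables x K Pearson loadings; weight strength is |r|."""

    r: pd.DataFrame  # index: variable names, columns: component ids
    zero_variance_variables: list[str] = field(default_factory=list)

    @property
    def weight_strength(self) -> pd.DataFrame:
        return self.r.abs()


@dataclass
class ComponentRanking:
    order: np.ndarray  # component indices, best (lowest ablation MSE) first
    ablation_mse: np.ndarray  # K values, index = component
    elbow_cut: int | None = None
    degenerate_elbow: bool = False


@dataclass
class ThresholdMask:
    """Variables x K booleans; True where the variable is retained."""

    mask: pd.DataFrame
    retain_count: int


def compute_scores(model, x, site_labels=None, subset: np.ndarray | None = None,
                   participant_ids=None, mode: str = "posterior_mean",
                   rng: np.random.Generator | None = None) -> LatentScores:
    """Encode participants to K-dimensional component scores.

    ``subset`` selects rows (e.g. ``split.test``); default all rows.
    Deterministic under the default posterior-mean mode.
    """
    x = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    if subset is None:
        subset = np.arange(x.shape[0])
    if len(subset) == 0:
        raise ValueError("empty participant subset")
    sites = None if site_labels is None else np.asarray(site_labels)[subset]
    mu, logvar = model.encode(x[subset], sites)
    if mode == "posterior_mean":
        z = mu
    elif mode == "sample":
        rng = rng or np.random.default_rng(0)
        z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ids = (
        [participant_ids[i] for i in subset] if participant_ids is not None
        else subset.tolist()
    )
    return LatentScores(values=z, participant_ids=ids, mode=mode)


def compute_loadings(scores: LatentScores, x, variable_names=None,
                     subset: np.ndarray | None = None) -> LoadingMatrix:
    """Pearson loadings of every variable on every component.

    ``x`` rows must align with ``scores`` rows (pass ``subset`` to select the
    same participant subset used for the scores). Zero-variance variables get
    loading 0 and are flagged rather than erroring, so thresholding stays
    total.
    """
    xv = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    if variable_names is None:
        variable_names = getattr(x, "variable_names", [f"x{j}" for j in range(xv.shape[1])])
    if subset is not None:
        xv = xv[subset]
    z = scores.values
    if xv.shape[0] != z.shape[0]:
        raise ValueError(f"{xv.shape[0]} data rows vs {z.shape[0]} score rows")
    if xv.shape[0] < 3:
        raise ValueError("need at least 3 participants for correlations")

    xc = xv - xv.mean(axis=0)
    zc = z - z.mean(axis=0)
    xsd = xc.std(axis=0)
    zsd = zc.std(axis=0)
    zero_var = xsd == 0
    zsd_safe = np.where(zsd == 0, 1.0, zsd)
    xsd_safe = np.where(zero_var, 1.0, xsd)
    r = (xc.T @ zc) / xv.shape[0] / np.outer(xsd_safe, zsd_safe)
    r[zero_var, :] = 0.0
    r[:, zsd == 0] = 0.0
    r = np.clip(r, -1.0, 1.0)
    cols = [f"comp{j:03d}" for j in range(z.shape[1])]
    return LoadingMatrix(
        r=pd.DataFrame(r, index=list(variable_names), columns=cols),
        zero_variance_variables=[n for n, zv in zip(variable_names, zero_var) if zv],
    )


def ablation_mses(scores: np.ndarray, decode_fn, x_target: np.ndarray) -> np.ndarray:
    """Reconstruction MSE decoding from each component alone.

    ``decode_fn(z)`` maps latent matrices to target-space reconstructions
    (conditioning, if any, is baked in). Returns one MSE per component.
    """
    k = scores.shape[1]
    out = np.empty(k)
    for j in range(k):
        z = np.zeros_like(scores)
        z[:, j] = scores[:, j]
        xhat = decode_fn(z)
        out[j] = float(np.mean(np.sum((x_target - xhat) ** 2, axis=1)))
    return out


def ablation_rank(model, x, site_labels=None, split=None, elbow: bool = True,
                  elbow_override: int | None = None) -> ComponentRanking:
    """Rank components by single-component ablation test MSE, ascending."""
    xv = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    idx = split.test if split is not None else np.arange(xv.shape[0])
    sites = None if site_labels is None else np.asarray(site_labels)[idx]
    sc = compute_scores(model, xv, site_labels, subset=idx)
    mses = ablation_mses(sc.values, lambda z: model.decode(z, sites), xv[idx])
    order = np.argsort(mses, kind="stable")
    ranking = ComponentRanking(order=order, ablation_mse=mses)
    if elbow and len(mses) >= 3:
        ranking.elbow_cut = find_elbow(ranking, override=elbow_override)
    return ranking


def find_elbow(ranking: ComponentRanking, override: int | None = None) -> int:
    """Elbow of the sorted ablation-MSE curve by maximal distance to chord.

    Finds the point of the sorted curve farthest from the straight line
    joining its endpoints and returns the number of components to interpret:
    when that point lies above the chord (the curve jumps up to a plateau of
    uninformative components) the cut stops just before it; when it lies
    below (the curve accelerates away late) it is included. A configured
    ``override`` takes precedence and is recorded. An exactly linear curve
    has no elbow; returns 1 with a degeneracy flag.
    """
    if override is not None:
        ranking.degenerate_elbow = False
        return int(override)
    y = ranking.ablation_mse[ranking.order]
    k = len(y)
    if k < 3:
        raise ValueError("need at least 3 components for an elbow")
    t = np.arange(k, dtype=float)
    # perpendicular distance of each point to the chord (t0,y0)-(tK,yK)
    dy, dt = y[-1] - y[0], t[-1] - t[0]
    norm = np.hypot(dt, dy)
    dist = np.abs(dy * t - dt * y + dt * y[0] - dy * t[0]) / norm
    if np.allclose(dist, 0.0):
        ranking.degenerate_elbow = True
        return 1
    i = int(np.argmax(dist))
    chord = y[0] + (y[-1] - y[0]) * t / t[-1]
    cut = i if y[i] > chord[i] else i + 1
    return max(cut, 1)


def threshold_95(loadings: LoadingMatrix, percentile: float = 0.95) -> ThresholdMask:
    """Retain each variable only in its top ceil((1-p)*K) components.

    With K=100 and the default 95th percentile each variable survives in
    exactly its 5 strongest components. Ties break toward the lower
    component index (deterministic).
    """
    ws = loadings.weight_strength.to_numpy()
    k = ws.shape[1]
    # round before ceil: (1 - 0.95) * 100 is 5.000000000000004 in floats
    retain = max(int(np.ceil(round((1.0 - percentile) * k, 9))), 1)
    # stable sort on descending strength => ties keep lower component index
    order = np.argsort(-ws, axis=1, kind="stable")
    mask = np.zeros_like(ws, dtype=bool)
    rows = np.repeat(np.arange(ws.shape[0]), retain)
    cols = order[:, :retain].ravel()
    mask[rows, cols] = True
    return ThresholdMask(
        mask=pd.DataFrame(mask, index=loadings.r.index, columns=loadings.r.columns),
        retain_count=retain,
    )


def component_letters(ranking: ComponentRanking, n: int | None = None) -> dict[str, int]:
    """Label the top-ranked components 'A', 'B', ... in ablation order."""
    n = n if n is not None else (ranking.elbow_cut or len(ranking.order))
    n = min(n, len(ranking.order), len(string.ascii_uppercase))
    return {string.ascii_uppercase[i]: int(ranking.order[i]) for i in range(n)}
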