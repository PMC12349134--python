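"""Test-split reconstruction error and replicated architecture selection.

The reconstruction error convention throughout the package: squared error
summed over curated variables (ambient space, front-end inverted), averaged
over participants. This makes architectures with different front-end sizes
and the PCA baseline directly comparable, and on standardized data a
zero-predictor scores approximately the number of variables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cvae import CVAEConfig, CVAEModel, TrainingDivergedError, train_cvae
from .splits import SplitAssignment


def reconstruction_mse(model, x: np.ndarray, site_labels=None) -> float:
    """Mean over rows of the variable-summed squared reconstruction error."""
    x = np.asarray(x, dtype=float)
    xhat = model.reconstruct(x, site_labels)
    return float(np.mean(np.sum((x - xhat) ** 2, axis=1)))


def mse_test(model, x, site_labels=None, split: SplitAssignment | None = None) -> float:
    """Reconstruction MSE on the untouched test split."""
    x = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    if split is None:
        raise ValueError("split required")
    idx = split.test
    if len(idx) == 0:
        raise ValueError("empty test split")
    sites = None if site_labels is None else np.asarray(site_labels)[idx]
    return reconstruction_mse(model, x[idx], sites)


@dataclass
class ModelSelectionTable:
    """Replicated test-MSE comparison across candidate architectures."""

    rows: pd.DataFrame  # architecture, frontend_dim, hidden_dim, mean_mse, sd_mse, n_ok, n_failed
    winner: int  # positional index into rows (minimal mean among qualified)
    models: list[list[CVAEModel]]  # per candidate, the successful replicates

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out["winner"] = False
        out.loc[out.index[self.winner], "winner"] = True
        return out

    def best_model(self) -> CVAEModel:
        """Winning candidate's best single replicate by its own test MSE."""
        reps = self.models[self.winner]
        mses = self.rows.loc[self.rows.index[self.winner], "_replicate_mses"]
        return reps[int(np.argmin(mses))]


def select_architecture(
    candidates: list[CVAEConfig],
    x,
    site_labels,
    split: SplitAssignment,
    n_replicates: int = 25,
    base_seed: int = 0,
    keep_models: bool = True,
) -> ModelSelectionTable:
    """Train every candidate ``n_replicates`` times with distinct seeds and
    rank by mean test MSE.

    Replicates that diverge are recorded and excluded; a candidate with fewer
    than 80% successful replicates is disqualified from winning.
    """
    if not candidates:
        raise ValueError("at least one candidate architecture required")
    x = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    records = []
    all_models: list[list[CVAEModel]] = []
    for ci, cfg in enumerate(candidates):
        mses, models, failed = [], [], 0
        for r in range(n_replicates):
            seed = (base_seed + 10_000 * ci + r) % (2**31 - 1)
            try:
                m = train_cvae(x, site_labels, split, replace(cfg, seed=seed))
                sites = None if m.site_categories is None else site_labels
                mses.append(mse_test(m, x, sites, split))
                if keep_models:
                    models.append(m)
            except TrainingDivergedError:
                failed += 1
        qualified = len(mses) >= 0.8 * n_replicates and len(mses) > 0
        records.append(
            {
                "architecture": ci + 1,
                "frontend_dim": cfg.frontend_dim,
                "hidden_dim": cfg.hidden_dim,
                "latent_dim": cfg.latent_dim,
                "mean_mse": float(np.mean(mses)) if mses else np.nan,
                "sd_mse": float(np.std(mses, ddof=1)) if len(mses) > 1 else 0.0,
                "n_ok": len(mses),
                "n_failed": failed,
                "qualified": qualified,
                "_replicate_mses": mses,
            }
        )
        all_models.append(models)
    rows = pd.DataFrame.from_records(records)
    qualified = rows.index[rows["qualified"]]
    if len(qualified) == 0:
        raise TrainingDivergedError("no candidate architecture had enough successful replicates")
    winner = int(qualified[np.argmin(rows.loc[qualified, "mean_mse"].to_numpy())])
    return ModelSelectionTable(rows=rows, winner=winner, models=all_models)
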