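"""PCA reconstruction baseline at matched latent dimensionality."""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .splits import SplitAssignment


class PCABaseline:
    """Rank-n linear reconstruction model (project + back-project).

    Wraps a PCA fit on the training split; the randomized SVD solver, when
    sklearn selects it for large inputs, is seeded for reproducibility.
    """

    def __init__(self, n_components: int, seed: int = 0):
        self.n_components = n_components
        self.seed = seed
        self._pca: PCA | None = None

    def fit(self, x_train: np.ndarray) -> "PCABaseline":
        if self.n_components > min(x_train.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min dimension {min(x_train.shape)}"
            )
        self._pca = PCA(n_components=self.n_components, random_state=self.seed)
        self._pca.fit(x_train)
        return self

    @property
    def mean_(self) -> np.ndarray:
        return self._pca.mean_

    @property
    def components_(self) -> np.ndarray:
        return self._pca.components_

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(x, dtype=float))

    def reconstruct(self, x: np.ndarray, site_labels=None) -> np.ndarray:
        # site_labels accepted (and ignored) for interface parity with the CVAE
        x = np.asarray(x, dtype=float)
        return self._pca.inverse_transform(self._pca.transform(x))


def fit_pca_baseline(x, split: SplitAssignment, n_components: int = 100, seed: int = 0) -> PCABaseline:
    """Fit the PCA baseline on the training split of the curated matrix."""
    x = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    return PCABaseline(n_components, seed=seed).fit(x[split.train])
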