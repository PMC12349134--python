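"""Shared fixtures: small synthetic draws and a reusable trained model.

Everything is generated programmatically and seeded; the session-scoped
trained model keeps the component-analysis tests cheap.
"""

import numpy as np
import pandas as pd
import pytest

import phenostrat as ps
from phenostrat.phenome import PhenomeTable, VariableMeta


def make_table(values: np.ndarray, dtypes=None, categories=None, events=None) -> PhenomeTable:
    """Assemble a PhenomeTable from a raw array with simple defaults."""
    n, v = values.shape
    dtypes = dtypes or ["continuous"] * v
    categories = categories or ["Behavior"] * v
    events = events or ["baseline"] * v
    names = [f"x{j:03d}" for j in range(v)]
    df = pd.DataFrame(values, index=[f"p{i:04d}" for i in range(n)], columns=names)
    meta = [VariableMeta(names[j], categories[j], dtypes[j], events[j]) for j in range(v)]
    return PhenomeTable(df, meta)


@pytest.fixture(scope="session")
def small_draw():
    """A modest synthetic cohort: 600 x 80, all structure switched on."""
    cfg = ps.GeneratorConfig(
        n_participants=600, n_variables=80, n_sites=6, n_states=5,
        missing_rate=0.05, outlier_rate=0.005, seed=42,
    )
    table, truth = ps.generate_phenome(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_curated(small_draw):
    cfg, table, truth = small_draw
    curated, report = ps.curate(table)
    return curated, report, truth


@pytest.fixture(scope="session")
def small_split(small_curated):
    curated, _, truth = small_curated
    return ps.stratified_split(curated, truth.site_labels, seed=7)


@pytest.fixture(scope="session")
def small_model(small_curated, small_split):
    """One trained site-conditioned CVAE on the small cohort."""
    curated, _, truth = small_curated
    cfg = ps.CVAEConfig(
        frontend_dim=40, hidden_dim=32, latent_dim=10,
        learning_rate=2e-3, max_epochs=80, patience=10, seed=3,
    )
    return ps.train_cvae(curated, truth.site_labels, small_split, cfg)
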