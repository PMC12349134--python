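"""Synthetic phenome generator with planted latent structure.

Emulates the statistical features of a large multi-site child-development
cohort phenome: a low-rank latent factor model with heterogeneous factor
variances, additive per-site batch offsets, a squashing nonlinearity on a
subset of factor->phenotype links, mixed continuous/discrete variables,
completely-at-random missingness, heavy-tailed outliers, a Socioeconomic
variable category tied to a designated SES factor, and state-of-residence
labels whose SES-factor means differ by state. The generating parameters are
returned as ground truth so downstream stages can be tested for recovery.

The value model for participant i, variable v:

    eta[i, v]  = sum_f scores[i, f] * loadings[v, f]
    x[i, v]    = g_v(eta[i, v]) + site_offset[site_i, v] + eps[i, v]

with eps ~ N(0, noise_sd^2), g_v identity for linear variables and a scaled
odd squashing a*tanh(./a) for the flagged nonlinear fraction. Discrete
variables are produced by thresholding the continuous latent at column
quantiles into >=2 ordinal levels. Factor scores are N(0, factor_variance);
the first factor is the SES factor and participants of state s have their
SES-factor scores shifted by a state-specific offset of magnitude
``state_ses_shift``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenome import CATEGORIES, PhenomeTable, VariableMeta

_EVENTS = ("baseline", "screener", "6_month", "1_year")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic phenome draw.

    Defaults are the package's scaled-down stand-in for the real cohort:
    2,000 participants x 300 variables (vs 11,875 x 13,638), 5 latent factors
    with 2x-separated variances, 21 collection sites, 17 states, ~30%
    discrete variables, a quarter of links nonlinear, 5% missingness and a
    0.2% rate of 8x multiplicative outliers.
    """

    n_participants: int = 2000
    n_variables: int = 300
    n_factors: int = 5
    factor_variances: tuple[float, ...] = (16.0, 8.0, 4.0, 2.0, 1.0)
    frac_discrete: float = 0.3
    frac_nonlinear: float = 0.25
    noise_sd: float = 1.0
    n_sites: int = 21
    site_effect_sd: float = 0.5
    missing_rate: float = 0.05
    outlier_rate: float = 0.002
    outlier_scale: float = 8.0
    n_states: int = 17
    state_ses_shift: float = 1.0
    category_assignment: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_discrete", "frac_nonlinear", "missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.n_factors >= self.n_variables:
            raise ValueError("n_factors must be < n_variables")
        if len(self.factor_variances) != self.n_factors:
            raise ValueError("factor_variances length must equal n_factors")
        fv = np.asarray(self.factor_variances, dtype=float)
        if np.any(fv <= 0) or np.any(np.diff(fv) > 0):
            raise ValueError("factor_variances must be strictly positive and non-increasing")
        if self.noise_sd < 0 or self.site_effect_sd < 0 or self.state_ses_shift < 0:
            raise ValueError("noise_sd, site_effect_sd, state_ses_shift must be non-negative")
        if self.outlier_scale <= 1:
            raise ValueError("outlier_scale must exceed 1")
        for name in ("n_participants", "n_variables", "n_sites", "n_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.category_assignment is not None:
            bad = set(self.category_assignment.values()) - set(CATEGORIES)
            if bad:
                raise ValueError(f"unknown categories in assignment: {sorted(bad)}")


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic draw, for recovery tests."""

    factor_loadings: np.ndarray  # variables x factors
    factor_scores: np.ndarray  # participants x factors (state shift included)
    site_labels: np.ndarray  # participants,
    site_offsets: np.ndarray  # sites x variables
    state_labels: np.ndarray  # participants,
    state_offsets: np.ndarray  # states, (shift applied to the SES factor)
    ses_variable_index: list[str]  # names of "Socioeconomic" variables
    nonlinear_variables: list[str]
    discrete_variables: list[str]
    missing_mask: np.ndarray  # participants x variables booleans
    outlier_mask: np.ndarray  # participants x variables booleans

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            factor_loadings=self.factor_loadings,
            factor_scores=self.factor_scores,
            site_labels=self.site_labels,
            site_offsets=self.site_offsets,
            state_labels=self.state_labels,
            state_offsets=self.state_offsets,
            ses_variable_index=np.array(self.ses_variable_index),
            nonlinear_variables=np.array(self.nonlinear_variables),
            discrete_variables=np.array(self.discrete_variables),
            missing_mask=self.missing_mask,
            outlier_mask=self.outlier_mask,
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "GroundTruth":
        z = np.load(path, allow_pickle=False)
        return cls(
            factor_loadings=z["factor_loadings"],
            factor_scores=z["factor_scores"],
            site_labels=z["site_labels"],
            site_offsets=z["site_offsets"],
            state_labels=z["state_labels"],
            state_offsets=z["state_offsets"],
            ses_variable_index=[str(s) for s in z["ses_variable_index"]],
            nonlinear_variables=[str(s) for s in z["nonlinear_variables"]],
            discrete_variables=[str(s) for s in z["discrete_variables"]],
            missing_mask=z["missing_mask"],
            outlier_mask=z["outlier_mask"],
        )


def _default_categories(names: list[str]) -> dict[str, str]:
    # round-robin over the closed category list; guarantees a Socioeconomic
    # block of ~1/23 of the variables
    return {n: CATEGORIES[i % len(CATEGORIES)] for i, n in enumerate(names)}


def null_state_variant(config: GeneratorConfig) -> GeneratorConfig:
    """Negative-control variant: identical conditions, no state->SES signal."""
    return dataclasses.replace(config, state_ses_shift=0.0)


def generate_phenome(config: GeneratorConfig) -> tuple[PhenomeTable, GroundTruth]:
    """Draw one phenome table plus its generating ground truth.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, v, f = config.n_participants, config.n_variables, config.n_factors

    names = [f"v{i:04d}" for i in range(v)]
    cats = config.category_assignment or _default_categories(names)
    missing_cat = [nm for nm in names if nm not in cats]
    if missing_cat:
        raise ValueError(f"category_assignment missing variables, e.g. {missing_cat[:3]}")
    ses_names = [nm for nm in names if cats[nm] == "Socioeconomic"]
    ses_rows = np.array([cats[nm] == "Socioeconomic" for nm in names])

    # factor loadings; SES variables load predominantly on the SES factor
    # (factor 0) so that SES-only component scores carry the state signal
    loadings = rng.normal(0.0, 1.0 / np.sqrt(f), size=(v, f))
    if ses_rows.any():
        loadings[ses_rows, 0] *= 3.0
        if f > 1:
            loadings[ses_rows, 1:] *= 0.5

    variances = np.asarray(config.factor_variances, dtype=float)
    scores = rng.normal(size=(n, f)) * np.sqrt(variances)

    # state labels; state s shifts the SES-factor mean by shift * u_s with
    # u_s equally spaced in [-1, 1] (zero-mean across states)
    state_labels = rng.integers(0, config.n_states, size=n)
    u = np.linspace(-1.0, 1.0, config.n_states) if config.n_states > 1 else np.zeros(1)
    state_offsets = config.state_ses_shift * u
    scores[:, 0] += state_offsets[state_labels]

    site_labels = rng.integers(0, config.n_sites, size=n)
    site_offsets = rng.normal(0.0, config.site_effect_sd, size=(config.n_sites, v))

    eta = scores @ loadings.T

    # odd squashing nonlinearity on a flagged fraction of links; the scale
    # a = sd/2 saturates ~2-sigma excursions while preserving column scale
    n_nl = int(round(config.frac_nonlinear * v))
    nl_idx = rng.choice(v, size=n_nl, replace=False) if n_nl else np.array([], dtype=int)
    for j in nl_idx:
        sd = float(np.sqrt(loadings[j] ** 2 @ variances))
        if sd > 0:
            a = sd / 2.0
            eta[:, j] = a * np.tanh(eta[:, j] / a)

    x = eta + site_offsets[site_labels] + (
        rng.normal(0.0, config.noise_sd, size=(n, v)) if config.noise_sd > 0 else 0.0
    )

    # ordinalize a fraction of variables by thresholding the continuous latent
    n_disc = int(round(config.frac_discrete * v))
    disc_idx = rng.choice(v, size=n_disc, replace=False) if n_disc else np.array([], dtype=int)
    disc_set = set(disc_idx.tolist())
    for j in disc_idx:
        k = int(rng.integers(2, 4))  # 2 or 3 levels
        qs = np.sort(rng.uniform(0.2, 0.8, size=k - 1))
        cuts = np.quantile(x[:, j], qs)
        x[:, j] = np.searchsorted(cuts, x[:, j]).astype(float)

    # multiplicative heavy-tailed outliers on continuous variables only
    outlier_mask = np.zeros((n, v), dtype=bool)
    if config.outlier_rate > 0:
        cont = np.array([j not in disc_set for j in range(v)])
        m = rng.random((n, v)) < config.outlier_rate
        m[:, ~cont] = False
        x = np.where(m, x * config.outlier_scale, x)
        outlier_mask = m

    missing_mask = np.zeros((n, v), dtype=bool)
    if config.missing_rate > 0:
        missing_mask = rng.random((n, v)) < config.missing_rate
        x = np.where(missing_mask, np.nan, x)

    values = pd.DataFrame(x, index=[f"p{i:05d}" for i in range(n)], columns=names)
    meta = [
        VariableMeta(
            name=nm,
            category=cats[nm],
            dtype="discrete" if j in disc_set else "continuous",
            event=_EVENTS[j % len(_EVENTS)],
        )
        for j, nm in enumerate(names)
    ]
    table = PhenomeTable(values, meta)
    truth = GroundTruth(
        factor_loadings=loadings,
        factor_scores=scores,
        site_labels=site_labels,
        site_offsets=site_offsets,
        state_labels=state_labels,
        state_offsets=state_offsets,
        ses_variable_index=ses_names,
        nonlinear_variables=[names[j] for j in sorted(nl_idx.tolist())],
        discrete_variables=[names[j] for j in sorted(disc_idx.tolist())],
        missing_mask=missing_mask,
        outlier_mask=outlier_mask,
    )
    return table, truth
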