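"""Phenome table container and delimited-text I/O.

A phenome table is a participants x variables matrix of mixed continuous and
discrete measurements with missing entries, plus a per-variable metadata
sidecar (category, declared type, collection event). Values live in a pandas
DataFrame indexed by participant id; missingness is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# The closed list of predefined phenotype categories. Instrument-level
# category names for the cohort; editable metadata, but every VariableMeta
# category must come from this list. "Socioeconomic" is required by the
# SES-overlap and state-prediction stages.
CATEGORIES: tuple[str, ...] = (
    "Socioeconomic",
    "Mental Health Summary",
    "Neuropsychological Tests",
    "Social Responsiveness",
    "Demographics",
    "Parent Characteristics",
    "Social Adjustment",
    "Diagnostic (KSADS)",
    "Behavior",
    "Nutrition",
    "Cognitive Capacity",
    "Mania",
    "Extracurricular",
    "Deep Phenotyping Assessments",
    "Physical Health",
    "Sleep",
    "Substance Use",
    "Screen Time",
    "Culture & Environment",
    "Family History",
    "Medical History",
    "Pubertal Development",
    "Physical Activity",
)


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one phenome variable."""

    name: str
    category: str
    dtype: str  # "continuous" | "discrete" | "indicator" (one-hot child)
    event: str = "baseline"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for variable {self.name!r}")
        if self.dtype not in ("continuous", "discrete", "indicator"):
            raise ValueError(
                f"dtype must be 'continuous', 'discrete' or 'indicator', got {self.dtype!r}"
            )


class PhenomeTable:
    """Participants x variables value matrix with per-variable metadata.

    Parameters
    ----------
    values
        DataFrame, rows indexed by participant id, columns named by variable.
        Missing entries are NaN.
    meta
        One :class:`VariableMeta` per column, same order as ``values.columns``.
    """

    def __init__(self, values: pd.DataFrame, meta: list[VariableMeta]):
        if values.index.has_duplicates:
            raise ValueError("duplicate participant ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate variable names")
        if len(meta) != values.shape[1]:
            raise ValueError(f"{len(meta)} metadata entries for {values.shape[1]} columns")
        for m, c in zip(meta, values.columns):
            if m.name != c:
                raise ValueError(f"metadata order mismatch: {m.name!r} vs column {c!r}")
        self.values = values
        self.meta = list(meta)

    # -- basic queries -------------------------------------------------
    @property
    def participant_ids(self) -> list:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def meta_for(self, name: str) -> VariableMeta:
        return self.meta[self.values.columns.get_loc(name)]

    def dtypes(self) -> np.ndarray:
        return np.array([m.dtype for m in self.meta])

    def categories(self) -> np.ndarray:
        return np.array([m.category for m in self.meta])

    def continuous_columns(self) -> list[str]:
        return [m.name for m in self.meta if m.dtype == "continuous"]

    def discrete_columns(self) -> list[str]:
        return [m.name for m in self.meta if m.dtype == "discrete"]

    def subset_variables(self, names: list[str]) -> "PhenomeTable":
        names = list(names)
        idx = {m.name: m for m in self.meta}
        return PhenomeTable(self.values[names].copy(), [idx[n] for n in names])

    def copy(self) -> "PhenomeTable":
        return PhenomeTable(self.values.copy(), list(self.meta))

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [m.name for m in self.meta],
                "category": [m.category for m in self.meta],
                "dtype": [m.dtype for m in self.meta],
                "event": [m.event for m in self.meta],
            }
        )

    # -- I/O -----------------------------------------------------------
    def to_files(self, values_path: str | Path, meta_path: str | Path) -> None:
        """Write values (first column = participant id) and metadata as TSV."""
        df = self.values.copy()
        df.insert(0, "participant_id", df.index)
        df.to_csv(values_path, sep="\t", index=False)
        self.meta_frame().to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, values_path: str | Path, meta_path: str | Path) -> "PhenomeTable":
        df = pd.read_csv(values_path, sep="\t")
        df = df.set_index("participant_id")
        df.index.name = None
        mf = pd.read_csv(meta_path, sep="\t")
        meta = [
            VariableMeta(str(r.variable), str(r.category), str(r.dtype), str(r.event))
            for r in mf.itertuples()
        ]
        return cls(df, meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhenomeTable({self.n_participants} participants x {self.n_variables} variables)"
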