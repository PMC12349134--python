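"""Phenome curation: event retention, pruning, encoding, imputation, scaling.

The curation protocol turns a raw mixed-type phenome table into the dense
numeric matrix consumed by the embedding models:

1. retain only variables from collection events covering >=95% of baseline
   participants;
2. prune variables populated for fewer than 80% of participants;
3. drop near-constant variables (most frequent value > 99% of non-missing
   entries);
4. recode participant non-compliance sentinel codes to missing;
5. one-hot encode discrete variables into per-level indicator columns;
6. impute remaining missingness (continuous: column median; indicators:
   column mode);
7. winsorize continuous columns at |z| = 4 (replace with the largest
   magnitude in-range observed value) and z-score them.

Every input variable is accounted for exactly once in the consolidated
:class:`CurationReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenome import PhenomeTable, VariableMeta


@dataclass
class CurationConfig:
    min_populated: float = 0.80
    near_constant: float = 0.99
    z_max: float = 4.0
    min_family_fraction: float = 0.95
    noncompliance_codes: tuple[float, ...] = (777.0, 999.0)
    impute: str = "median-mode"  # "median-mode" | "none"
    # z-scoring statistics from the full sample by default (curation precedes
    # splitting); pass train participant ids for a leakage-free variant
    standardize_on: list | None = None


@dataclass
class CurationReport:
    dropped_event: list[tuple[str, float]] = field(default_factory=list)  # (variable, event coverage)
    dropped_missingness: list[tuple[str, float]] = field(default_factory=list)  # (variable, populated frac)
    dropped_near_constant: list[tuple[str, float]] = field(default_factory=list)  # (variable, top-value frac)
    encoded: dict[str, list[str]] = field(default_factory=dict)  # discrete variable -> indicator columns
    winsorized_counts: dict[str, int] = field(default_factory=dict)
    noncompliance_counts: dict[str, int] = field(default_factory=dict)
    retained_events: list[str] = field(default_factory=list)
    zero_variance_flags: list[str] = field(default_factory=list)
    input_variables: list[str] = field(default_factory=list)
    output_variables: list[str] = field(default_factory=list)

    def merge(self, other: "CurationReport") -> None:
        self.dropped_event += other.dropped_event
        self.dropped_missingness += other.dropped_missingness
        self.dropped_near_constant += other.dropped_near_constant
        self.encoded.update(other.encoded)
        self.winsorized_counts.update(other.winsorized_counts)
        self.noncompliance_counts.update(other.noncompliance_counts)
        self.retained_events += [e for e in other.retained_events if e not in self.retained_events]
        self.zero_variance_flags += other.zero_variance_flags

    def accounted_variables(self) -> set[str]:
        """Each input variable is dropped, encoded, or retained — exactly once."""
        dropped = {v for v, _ in self.dropped_event}
        dropped |= {v for v, _ in self.dropped_missingness}
        dropped |= {v for v, _ in self.dropped_near_constant}
        children = {c for cs in self.encoded.values() for c in cs}
        passthrough = set(self.output_variables) - children
        return dropped | set(self.encoded) | passthrough


def _require_nonempty(table: PhenomeTable) -> None:
    if table.n_variables == 0 or table.n_participants == 0:
        raise ValueError("empty phenome table")


def retain_events(table: PhenomeTable, min_family_fraction: float = 0.95) -> tuple[PhenomeTable, CurationReport]:
    """Keep variables whose collection event covers enough baseline participants.

    An event's coverage is the fraction of participants with at least one
    observed value among that event's variables; the baseline event has
    coverage 1 by definition of the participant roster.
    """
    _require_nonempty(table)
    events = pd.Series([m.event for m in table.meta], index=table.values.columns)
    coverage: dict[str, float] = {}
    for ev in events.unique():
        cols = events.index[events == ev]
        observed_any = table.values[cols].notna().any(axis=1)
        coverage[ev] = float(observed_any.mean())
    kept_events = [ev for ev, c in coverage.items() if c >= min_family_fraction]
    if not kept_events:
        raise ValueError(
            f"no collection event reaches coverage {min_family_fraction}; coverages: {coverage}"
        )
    report = CurationReport(retained_events=sorted(kept_events))
    keep = [m.name for m in table.meta if m.event in kept_events]
    report.dropped_event = [
        (m.name, coverage[m.event]) for m in table.meta if m.event not in kept_events
    ]
    return table.subset_variables(keep), report


def prune_missingness(table: PhenomeTable, min_populated: float = 0.80) -> tuple[PhenomeTable, CurationReport]:
    """Drop variables populated for fewer than ``min_populated`` of participants."""
    if not (0.0 < min_populated <= 1.0):
        raise ValueError(f"min_populated must be in (0, 1], got {min_populated}")
    _require_nonempty(table)
    populated = table.values.notna().mean(axis=0)
    keep = populated.index[populated >= min_populated].tolist()
    if not keep:
        raise ValueError(
            f"all variables dropped at min_populated={min_populated}; "
            f"max populated fraction is {populated.max():.3f}"
        )
    report = CurationReport(
        dropped_missingness=[(v, float(populated[v])) for v in populated.index if v not in set(keep)]
    )
    return table.subset_variables(keep), report


def drop_near_constant(table: PhenomeTable, max_top_fraction: float = 0.99) -> tuple[PhenomeTable, CurationReport]:
    """Drop variables whose most frequent non-missing value exceeds the cap.

    Reading of the near-constant rule: the most common value accounts for
    more than ``max_top_fraction`` of non-missing entries. Constant columns
    (fraction 1.0) are always dropped. Indicator columns are exempt — the
    rule screens raw variables, and a sparse level of an already-screened
    discrete parent is legitimate (also keeps curation idempotent).
    """
    _require_nonempty(table)
    keep, dropped = [], []
    for name in table.variable_names:
        if table.meta_for(name).dtype == "indicator":
            keep.append(name)
            continue
        col = table.values[name].dropna()
        if col.empty:
            dropped.append((name, 1.0))
            continue
        top = float(col.value_counts(normalize=True).iloc[0])
        if top > max_top_fraction:
            dropped.append((name, top))
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all variables near-constant; nothing retained")
    return table.subset_variables(keep), CurationReport(dropped_near_constant=dropped)


def recode_noncompliance(table: PhenomeTable, codes: tuple[float, ...]) -> tuple[PhenomeTable, CurationReport]:
    """Map sentinel non-compliance codes to missing."""
    out = table.copy()
    report = CurationReport()
    if codes:
        mask = out.values.isin(list(codes))
        counts = mask.sum(axis=0)
        report.noncompliance_counts = {v: int(c) for v, c in counts.items() if c > 0}
        out.values = out.values.mask(mask)
    return out, report


def encode_discrete(table: PhenomeTable) -> tuple[PhenomeTable, CurationReport]:
    """Replace each discrete variable with per-level 0/1 indicator columns.

    A variable with k observed levels becomes k columns named
    ``<variable>=<level>``; each indicator inherits the parent's category and
    event, and is missing wherever the parent was missing.
    """
    _require_nonempty(table)
    report = CurationReport()
    frames: list[pd.Series] = []
    meta: list[VariableMeta] = []
    for m in table.meta:
        col = table.values[m.name]
        if m.dtype != "discrete":
            frames.append(col)
            meta.append(m)
            continue
        levels = sorted(col.dropna().unique().tolist())
        if len(levels) < 2:
            raise ValueError(
                f"discrete variable {m.name!r} has {len(levels)} observed level(s); "
                "it should have been removed by the near-constant filter"
            )
        children = []
        miss = col.isna()
        for lv in levels:
            lv_label = f"{lv:g}" if isinstance(lv, float) else str(lv)
            child = f"{m.name}={lv_label}"
            ind = (col == lv).astype(float).mask(miss)
            ind.name = child
            frames.append(ind)
            meta.append(VariableMeta(child, m.category, "indicator", m.event))
            children.append(child)
        report.encoded[m.name] = children
    values = pd.concat(frames, axis=1)
    return PhenomeTable(values, meta), report


def impute_missing(table: PhenomeTable, method: str = "median-mode") -> PhenomeTable:
    """Fill missing entries: continuous -> column median, indicator -> mode."""
    if method == "none":
        return table
    if method != "median-mode":
        raise ValueError(f"unknown imputation method {method!r}")
    out = table.copy()
    for m in out.meta:
        col = out.values[m.name]
        if not col.isna().any():
            continue
        if m.dtype == "continuous":
            fill = col.median()
        else:
            fill = col.mode(dropna=True).iloc[0]
        out.values[m.name] = col.fillna(fill)
    return out


def robust_zscore_winsorize(
    table: PhenomeTable, z_max: float = 4.0, stats_rows: list | None = None
) -> tuple[PhenomeTable, CurationReport]:
    """Winsorize then z-score every continuous column.

    Per column: compute mean m and SD s over observed values; entries with
    |x - m| / s > z_max are replaced by the observed value of largest
    magnitude among in-range entries; the column is then standardized with
    its post-replacement mean and SD. Because replacing extreme values
    shrinks the SD, detection and replacement repeat until no entry exceeds
    the bound under the current statistics (a fixed point, reached in one or
    two rounds in practice), so the bound also holds under the final
    standardization and the operation is idempotent. Indicator columns pass
    through untouched (bounded by construction). When ``stats_rows`` is
    given (e.g. the training split), all statistics and the replacement
    value are computed from those rows only, avoiding leakage from
    evaluation splits.
    """
    _require_nonempty(table)
    out = table.copy()
    report = CurationReport()
    stat_sel = (
        out.values.index.isin(stats_rows) if stats_rows is not None
        else np.ones(out.n_participants, dtype=bool)
    )
    for m in out.meta:
        if m.dtype != "continuous":
            continue
        col = out.values[m.name].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        ref = np.where(stat_sel, col, np.nan)
        total_replaced = 0
        for _ in range(100):  # fixed point, typically 1-2 rounds
            mu = float(np.nanmean(ref))
            sd = float(np.nanstd(ref))
            if sd == 0.0:
                raise ValueError(
                    f"zero-SD continuous column {m.name!r}; "
                    "should have been removed by the near-constant filter"
                )
            inliers_ref = ~np.isnan(ref) & (np.abs(ref - mu) / sd <= z_max)
            outliers = obs & (np.abs(col - mu) / sd > z_max)
            n_out = int(outliers.sum())
            if n_out == 0:
                break
            if not inliers_ref.any():
                raise ValueError(f"column {m.name!r} has no in-range values to winsorize with")
            in_vals = ref[inliers_ref]
            replacement = float(in_vals[np.argmax(np.abs(in_vals))])
            col = np.where(outliers, replacement, col)
            ref = np.where(~np.isnan(ref) & (np.abs(ref - mu) / sd > z_max), replacement, ref)
            total_replaced += n_out
        if total_replaced:
            report.winsorized_counts[m.name] = total_replaced
        m2 = float(np.nanmean(ref))
        s2 = float(np.nanstd(ref))
        if s2 == 0.0:
            raise ValueError(f"column {m.name!r} constant after winsorization")
        out.values[m.name] = (col - m2) / s2
    return out, report


def curate(table: PhenomeTable, config: CurationConfig | None = None) -> tuple[PhenomeTable, CurationReport]:
    """Run the full curation protocol, in order, with a consolidated report."""
    config = config or CurationConfig()
    report = CurationReport(input_variables=list(table.variable_names))

    table, r = retain_events(table, config.min_family_fraction)
    report.merge(r)
    table, r = prune_missingness(table, config.min_populated)
    report.merge(r)
    table, r = drop_near_constant(table, config.near_constant)
    report.merge(r)
    table, r = recode_noncompliance(table, config.noncompliance_codes)
    report.merge(r)
    table, r = encode_discrete(table)
    report.merge(r)
    table = impute_missing(table, config.impute)
    table, r = robust_zscore_winsorize(table, config.z_max, stats_rows=config.standardize_on)
    report.merge(r)

    report.output_variables = list(table.variable_names)
    return table, report
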