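"""Category-level component profiles and SES-measure overlap set algebra.

After thresholding, each component keeps a subset of phenotypes; grouping
those by their predefined category gives a per-component profile: mean
weight strength over retained variables and the percentage of the category
retained. The SES overlap report asks, for a chosen set of components,
which Socioeconomic measures each retains uniquely versus shares — the
multidimensionality evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .components import LoadingMatrix, ThresholdMask
from .phenome import CATEGORIES


@dataclass
class CategoryProfile:
    """Per (component, category): mean weight strength and retained share."""

    table: pd.DataFrame  # columns: component, category, mean_weight_strength, retained_count, retained_proportion


@dataclass
class OverlapReport:
    components: list[str]  # component column ids
    retained_sets: dict[str, set[str]]  # component -> retained SES variables
    unique_sets: dict[str, set[str]]  # component -> variables in no other listed component
    intersections: dict[tuple[str, ...], int]  # every >=2-combo -> intersection size
    universe_size: int

    def n_in_all(self) -> int:
        return self.intersections[tuple(self.components)] if len(self.components) > 1 else len(
            self.retained_sets[self.components[0]]
        )


def _variable_categories(meta, variables) -> dict[str, str]:
    """category per variable; indicator columns inherit the parent's category."""
    if hasattr(meta, "meta"):  # a PhenomeTable
        return {m.name: m.category for m in meta.meta}
    if isinstance(meta, pd.DataFrame):
        return dict(zip(meta["variable"], meta["category"]))
    return dict(meta)


def category_profile(loadings: LoadingMatrix, mask: ThresholdMask, meta) -> CategoryProfile:
    """Mean weight strength and retained proportion per category per component.

    The mean is over retained variables only; the proportion is retained
    count over the category's total variable count, in percent. Categories
    with nothing retained report 0 / 0.
    """
    cats = _variable_categories(meta, loadings.r.index)
    unknown = [v for v in loadings.r.index if v not in cats]
    if unknown:
        raise ValueError(f"variables without category metadata, e.g. {unknown[:3]}")
    bad = set(cats.values()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown category labels: {sorted(bad)}")

    ws = loadings.weight_strength
    cat_series = pd.Series([cats[v] for v in ws.index], index=ws.index)
    cat_sizes = cat_series.value_counts()
    rows = []
    for comp in ws.columns:
        retained = mask.mask[comp]
        for cat in cat_sizes.index:
            in_cat = cat_series == cat
            sel = retained & in_cat
            n_ret = int(sel.sum())
            mean_ws = float(ws.loc[sel, comp].mean()) if n_ret else 0.0
            rows.append(
                {
                    "component": comp,
                    "category": cat,
                    "mean_weight_strength": mean_ws,
                    "retained_count": n_ret,
                    "retained_proportion": 100.0 * n_ret / int(cat_sizes[cat]),
                }
            )
    return CategoryProfile(table=pd.DataFrame(rows))


def ses_overlap(mask: ThresholdMask, meta, components: list[str],
                category: str = "Socioeconomic") -> OverlapReport:
    """Set algebra over the retained-SES sets of the named components."""
    if len(components) < 2:
        raise ValueError("need at least two components for an overlap report")
    for comp in components:
        if comp not in mask.mask.columns:
            raise ValueError(f"component {comp!r} not in mask columns")
    cats = _variable_categories(meta, mask.mask.index)
    ses_vars = [v for v in mask.mask.index if cats.get(v) == category]
    if not ses_vars:
        raise ValueError(f"no variables in category {category!r}")

    retained = {
        comp: set(mask.mask.index[mask.mask[comp] & mask.mask.index.isin(ses_vars)])
        for comp in components
    }
    unique = {
        comp: retained[comp] - set().union(*(retained[o] for o in components if o != comp))
        for comp in components
    }
    inter: dict[tuple[str, ...], int] = {}
    for r in range(2, len(components) + 1):
        for combo in combinations(components, r):
            s = set(retained[combo[0]])
            for c in combo[1:]:
                s &= retained[c]
            inter[combo] = len(s)
    return OverlapReport(
        components=list(components),
        retained_sets=retained,
        unique_sets=unique,
        intersections=inter,
        universe_size=len(ses_vars),
    )


def top_phenotype_table(loadings: LoadingMatrix, mask: ThresholdMask, component: str,
                        meta) -> pd.DataFrame:
    """Retained phenotypes of one component, strongest first, with category.

    Ties in weight strength sort by variable name for determinism. Suitable
    for Manhattan-style plotting.
    """
    if component not in loadings.r.columns:
        raise ValueError(f"component {component!r} not in loadings")
    cats = _variable_categories(meta, loadings.r.index)
    sel = mask.mask[component]
    df = pd.DataFrame(
        {
            "variable": loadings.r.index[sel],
            "category": [cats[v] for v in loadings.r.index[sel]],
            "loading": loadings.r.loc[sel, component].to_numpy(),
            "weight_strength": loadings.weight_strength.loc[sel, component].to_numpy(),
        }
    )
    return df.sort_values(
        ["weight_strength", "variable"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
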