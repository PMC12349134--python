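"""Profile components by phenotype category and SES-measure overlap.

Groups each top component's retained phenotypes into the 23 predefined
categories (mean weight strength + retained proportion), picks the
SES-centric components, and reports how their retained Socioeconomic
measures overlap — the multidimensionality evidence. Writes profiles,
per-component top-phenotype listings and the overlap report under
results/profiles/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import phenostrat as ps
from phenostrat.components import LoadingMatrix, ThresholdMask
from phenostrat.profiles import category_profile, ses_overlap, top_phenotype_table

CURATED = Path("results/curated")
COMPONENTS = Path("results/components")
OUT = Path("results/profiles")


def main(n_ses_components: int = 4) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curated = ps.PhenomeTable.from_files(CURATED / "curated.tsv", CURATED / "curated_meta.tsv")
    r = pd.read_csv(COMPONENTS / "loadings.tsv", sep="\t", index_col=0)
    loadings = LoadingMatrix(r=r)
    mframe = pd.read_csv(COMPONENTS / "threshold_mask.tsv", sep="\t", index_col=0).astype(bool)
    mask = ThresholdMask(mask=mframe, retain_count=int(mframe.sum(axis=1).iloc[0]))
    ranking = pd.read_csv(COMPONENTS / "ranking.tsv", sep="\t")

    profile = category_profile(loadings, mask, curated)
    profile.table.to_csv(OUT / "category_profile.tsv", sep="\t", index=False)

    lettered = ranking[ranking.letter.notna() & (ranking.letter != "")]
    top = lettered.component.tolist()
    for _, row in lettered.iterrows():
        top_phenotype_table(loadings, mask, row.component, curated).to_csv(
            OUT / f"top_phenotypes_{row.letter}.tsv", sep="\t", index=False)

    ses = profile.table[
        profile.table.category.eq("Socioeconomic")
        & profile.table.component.isin(top)
        & (profile.table.retained_count > 0)
    ].sort_values("mean_weight_strength", ascending=False)
    chosen = ses.head(n_ses_components).component.tolist()
    overlap = ses_overlap(mask, curated, chosen)
    (OUT / "ses_overlap.json").write_text(json.dumps({
        "components": overlap.components,
        "retained_counts": {c: len(s) for c, s in overlap.retained_sets.items()},
        "unique_counts": {c: len(s) for c, s in overlap.unique_sets.items()},
        "intersections": {"+".join(k): v for k, v in overlap.intersections.items()},
        "shared_by_all": overlap.n_in_all(),
        "ses_universe": overlap.universe_size,
    }, indent=2))

    print("SES profile of the lettered components:")
    print(ses.to_string(index=False))
    print(f"chosen SES-centric components: {chosen}")
    print(f"SES measures retained by all {len(chosen)} chosen components: "
          f"{overlap.n_in_all()} of {overlap.universe_size}")
    print("unique per component:",
          {c: len(s) for c, s in overlap.unique_sets.items()})


if __name__ == "__main__":
    main()
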