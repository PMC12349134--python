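"""Rank latent components and attribute them to phenotypes.

Loads the winning checkpoint, ranks the 20 components by single-component
ablation reconstruction error with an elbow cut, computes test-split
Pearson loadings of every curated feature on every component, applies the
95th-percentile weight-strength thresholding, and writes ranking, loadings
and the retention mask under results/components/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import phenostrat as ps
from phenostrat.components import (
    ablation_rank, component_letters, compute_loadings, compute_scores, threshold_95,
)
from phenostrat.cvae import load_model

CURATED = Path("results/curated")
MODELS = Path("results/models")
OUT = Path("results/components")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curated = ps.PhenomeTable.from_files(CURATED / "curated.tsv", CURATED / "curated_meta.tsv")
    sites = pd.read_csv("results/cohort/labels.tsv", sep="\t")["site"].to_numpy()
    split_lab = pd.read_csv(MODELS / "split.tsv", sep="\t")["split"].to_numpy()
    test_idx = np.flatnonzero(split_lab == "test")
    model = load_model(MODELS / "cvae.npz")

    ranking = ablation_rank_from(model, curated, sites, test_idx)
    letters = component_letters(ranking, 10)
    pd.DataFrame({
        "rank": np.arange(1, len(ranking.order) + 1),
        "component": [f"comp{j:03d}" for j in ranking.order],
        "ablation_mse": ranking.ablation_mse[ranking.order],
        "letter": [next((L for L, j in letters.items() if j == c), "")
                   for c in ranking.order],
    }).to_csv(OUT / "ranking.tsv", sep="\t", index=False)

    scores = compute_scores(model, curated, sites, subset=test_idx,
                            participant_ids=curated.participant_ids)
    scores.frame().to_csv(OUT / "scores_test.tsv", sep="\t", index=True)
    loadings = compute_loadings(scores, curated, subset=test_idx)
    loadings.r.to_csv(OUT / "loadings.tsv", sep="\t", index=True)
    mask = threshold_95(loadings)
    mask.mask.astype(int).to_csv(OUT / "threshold_mask.tsv", sep="\t", index=True)

    print(f"ablation elbow keeps {ranking.elbow_cut} of {len(ranking.order)} components; "
          f"letters {letters}")
    print(f"thresholding retains each feature in its top {mask.retain_count} "
          f"of {loadings.r.shape[1]} components")


def ablation_rank_from(model, curated, sites, test_idx):
    class _Split:
        test = test_idx

    return ablation_rank(model, curated.as_array(), sites, _Split())


if __name__ == "__main__":
    main()
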