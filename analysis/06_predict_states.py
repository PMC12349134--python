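"""Predict state of residence from SES-only component scores.

Builds each participant's SES-only score in the chosen SES-centric
components (dot product of curated Socioeconomic measurements with the
component's retained SES loadings) and trains one-vs-rest logistic
regression under stratified 10-fold cross-validation on the state labels.
Writes the confusion matrix, fold-averaged coefficients, per-state density
curves and a summary under results/state/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import phenostrat as ps
from phenostrat.components import LoadingMatrix, ThresholdMask
from phenostrat.stateprediction import (
    most_influential_component, predict_state, ses_component_scores,
)

CURATED = Path("results/curated")
COMPONENTS = Path("results/components")
PROFILES = Path("results/profiles")
OUT = Path("results/state")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curated = ps.PhenomeTable.from_files(CURATED / "curated.tsv", CURATED / "curated_meta.tsv")
    states = pd.read_csv("results/cohort/labels.tsv", sep="\t")["state"].to_numpy()
    loadings = LoadingMatrix(r=pd.read_csv(COMPONENTS / "loadings.tsv", sep="\t", index_col=0))
    mframe = pd.read_csv(COMPONENTS / "threshold_mask.tsv", sep="\t", index_col=0).astype(bool)
    mask = ThresholdMask(mask=mframe, retain_count=int(mframe.sum(axis=1).iloc[0]))
    chosen = json.loads((PROFILES / "ses_overlap.json").read_text())["components"]

    scores = ses_component_scores(curated, loadings, mask, chosen, curated)
    scores.frame().to_csv(OUT / "ses_scores.tsv", sep="\t")
    result = predict_state(scores, states, n_folds=10, seed=seed)
    result.confusion.to_csv(OUT / "confusion.tsv", sep="\t")
    result.coefficients.to_csv(OUT / "coefficients.tsv", sep="\t")

    curves = []
    for state, comps in result.densities.items():
        for comp, (grid, dens) in comps.items():
            curves.append(pd.DataFrame({"state": state, "component": comp,
                                        "score": grid, "density": dens}))
    pd.concat(curves).to_csv(OUT / "score_densities.tsv", sep="\t", index=False)

    influential = most_influential_component(result)
    summary = {
        "n_states": int(result.confusion.shape[0]),
        "chance_level_pct": result.chance_level,
        "overall_accuracy_pct": result.overall_accuracy,
        "states_above_chance": [int(s) for s in result.above_chance],
        "most_influential_component_per_state": {
            str(k): v for k, v in influential.items()},
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))

    print(f"SES-only scores in components {chosen} predict state residency at "
          f"{result.overall_accuracy:.1f}% overall (chance {result.chance_level:.2f}%)")
    print(f"{len(result.above_chance)} of {summary['n_states']} states above chance")
    print("most influential component per state:",
          dict(list(summary['most_influential_component_per_state'].items())[:6]), "...")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
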