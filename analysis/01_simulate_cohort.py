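"""Simulate the synthetic study cohort.

Draws the default scaled cohort — 2,000 participants x 300 mixed-type
phenome variables over 21 collection sites and 17 states, with 5 latent
factors, site offsets, 25% nonlinear links, missingness and outliers — under
the strong state->SES condition used for the geography validation, and
writes the phenome table, metadata sidecar, labels and ground truth under
results/cohort/.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import phenostrat as ps

OUT = Path("results/cohort")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = dataclasses.replace(ps.GeneratorConfig(seed=seed), state_ses_shift=8.0)
    table, truth = ps.generate_phenome(config)
    table.to_files(OUT / "phenome.tsv", OUT / "phenome_meta.tsv")
    truth.to_npz(OUT / "ground_truth.npz")
    pd.DataFrame({
        "participant_id": table.participant_ids,
        "site": truth.site_labels,
        "state": truth.state_labels,
    }).to_csv(OUT / "labels.tsv", sep="\t", index=False)

    frac_missing = float(np.isnan(table.as_array()).mean())
    print(f"cohort: {table.n_participants} participants x {table.n_variables} variables")
    print(f"  {len(truth.ses_variable_index)} Socioeconomic variables, "
          f"{len(truth.discrete_variables)} discrete, "
          f"{len(truth.nonlinear_variables)} nonlinear links")
    print(f"  observed missingness {100 * frac_missing:.1f}%")
    print(f"wrote {OUT}/phenome.tsv, phenome_meta.tsv, labels.tsv, ground_truth.npz")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
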