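"""Curate the raw phenome table.

Applies the full protocol — event retention, 80% populated pruning,
near-constant removal, non-compliance recoding, one-hot encoding of
discrete variables, median/mode imputation and iterated 4-SD winsorization
with z-scoring — and writes the curated matrix plus the curation report
under results/curated/.
"""

import json
from pathlib import Path

import phenostrat as ps

IN = Path("results/cohort")
OUT = Path("results/curated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = ps.PhenomeTable.from_files(IN / "phenome.tsv", IN / "phenome_meta.tsv")
    curated, report = ps.curate(table)
    curated.to_files(OUT / "curated.tsv", OUT / "curated_meta.tsv")
    (OUT / "curation_report.json").write_text(json.dumps({
        "n_input_variables": len(report.input_variables),
        "n_output_variables": len(report.output_variables),
        "dropped_missingness": report.dropped_missingness,
        "dropped_near_constant": report.dropped_near_constant,
        "n_encoded_discrete": len(report.encoded),
        "winsorized_entries": sum(report.winsorized_counts.values()),
        "retained_events": report.retained_events,
    }, indent=2))

    print(f"curated {len(report.input_variables)} raw variables -> "
          f"{len(report.output_variables)} model features")
    print(f"  dropped: {len(report.dropped_missingness)} under-populated, "
          f"{len(report.dropped_near_constant)} near-constant")
    print(f"  one-hot encoded {len(report.encoded)} discrete variables; "
          f"winsorized {sum(report.winsorized_counts.values())} entries")


if __name__ == "__main__":
    main()
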