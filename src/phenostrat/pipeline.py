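"""End-to-end orchestration: simulate -> curate -> embed -> attribute -> validate.

Every stage reads and writes files under the run directory so any stage can
be re-run or inspected in isolation; a manifest records the full
configuration, all seeds, the package version and a checksum per artifact,
making deterministic runs bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import fit_pca_baseline
from .components import ablation_rank, component_letters, compute_loadings, compute_scores, threshold_95
from .curation import CurationConfig, curate
from .cvae import CVAEConfig
from .phenome import PhenomeTable
from .profiles import category_profile, ses_overlap, top_phenotype_table
from .selection import ModelSelectionTable, mse_test, select_architecture
from .splits import stratified_split
from .stateprediction import predict_state, ses_component_scores
from .synthetic import GeneratorConfig, generate_phenome

_version = "0.1.0"


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run; all seeds explicit."""

    out_dir: str = "run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_seed: int = 0
    candidates: list[CVAEConfig] = field(
        default_factory=lambda: [
            CVAEConfig(frontend_dim=100, hidden_dim=64, latent_dim=20),
            CVAEConfig(frontend_dim=None, hidden_dim=64, latent_dim=20),
        ]
    )
    n_replicates: int = 3
    selection_seed: int = 0
    pca_components: int | None = None  # default: winner's latent_dim
    percentile: float = 0.95
    elbow_override: int | None = None
    n_ses_components: int = 4  # components of interest, chosen by SES weight
    state_folds: int = 10
    state_seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage order: simulate -> curate -> split -> select/train -> rank ->
    loadings -> threshold -> profile -> overlap -> predict-state. A stage
    failure raises with the stage name; artifacts written so far persist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"

    def _save_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        artifacts[name] = p

    def _save_json(objdict, name: str) -> None:
        p = out / name
        p.write_text(json.dumps(_jsonable(objdict), indent=2, sort_keys=True))
        artifacts[name] = p

    try:
        stage = "simulate"
        table, truth = generate_phenome(config.generator)
        table.to_files(out / "phenome.tsv", out / "phenome_meta.tsv")
        artifacts["phenome.tsv"] = out / "phenome.tsv"
        artifacts["phenome_meta.tsv"] = out / "phenome_meta.tsv"
        truth.to_npz(out / "ground_truth.npz")
        artifacts["ground_truth.npz"] = out / "ground_truth.npz"
        sites = truth.site_labels
        states = truth.state_labels

        stage = "curate"
        curated, report = curate(table, config.curation)
        curated.to_files(out / "curated.tsv", out / "curated_meta.tsv")
        artifacts["curated.tsv"] = out / "curated.tsv"
        artifacts["curated_meta.tsv"] = out / "curated_meta.tsv"
        _save_json(
            {
                "dropped_event": report.dropped_event,
                "dropped_missingness": report.dropped_missingness,
                "dropped_near_constant": report.dropped_near_constant,
                "encoded": report.encoded,
                "winsorized_counts": report.winsorized_counts,
                "retained_events": report.retained_events,
                "n_input_variables": len(report.input_variables),
                "n_output_variables": len(report.output_variables),
            },
            "curation_report.json",
        )

        stage = "split"
        split = stratified_split(curated, sites, config.split_fractions, config.split_seed)
        _save_json(
            {"train": split.train, "val": split.val, "test": split.test,
             "fractions": split.fractions, "seed": split.seed},
            "split.json",
        )

        stage = "select"
        x = curated.as_array()
        sel: ModelSelectionTable = select_architecture(
            config.candidates, x, sites, split,
            n_replicates=config.n_replicates, base_seed=config.selection_seed,
        )
        _save_df(sel.to_frame().drop(columns=["_replicate_mses"]), "selection.tsv")
        model = sel.best_model()
        pca_k = config.pca_components or model.config.latent_dim
        pca = fit_pca_baseline(x, split, n_components=pca_k, seed=config.selection_seed)
        _save_json(
            {
                "cvae_test_mse": mse_test(model, x, sites, split),
                "pca_test_mse": mse_test(pca, x, None, split),
                "pca_components": pca_k,
            },
            "benchmark.json",
        )

        stage = "rank"
        ranking = ablation_rank(model, x, sites, split, elbow_override=config.elbow_override)
        _save_df(
            pd.DataFrame(
                {
                    "rank": np.arange(1, len(ranking.order) + 1),
                    "component": [f"comp{j:03d}" for j in ranking.order],
                    "ablation_mse": ranking.ablation_mse[ranking.order],
                }
            ),
            "ranking.tsv",
        )
        letters = component_letters(ranking)

        stage = "loadings"
        sc = compute_scores(model, x, sites, subset=split.test,
                            participant_ids=curated.participant_ids)
        loadings = compute_loadings(sc, curated, subset=split.test)
        _save_df(loadings.r, "loadings.tsv", index=True)

        stage = "threshold"
        mask = threshold_95(loadings, config.percentile)
        _save_df(mask.mask.astype(int), "threshold_mask.tsv", index=True)

        stage = "profile"
        profile = category_profile(loadings, mask, curated)
        _save_df(profile.table, "category_profile.tsv")
        top_comps = [f"comp{j:03d}" for j in letters.values()]
        for letter, j in letters.items():
            _save_df(top_phenotype_table(loadings, mask, f"comp{j:03d}", curated),
                     f"top_phenotypes_{letter}.tsv")

        stage = "overlap"
        ses = profile.table[
            profile.table["category"].eq("Socioeconomic")
            & profile.table["component"].isin(top_comps)
        ].set_index("component")
        ses = ses[ses["retained_count"] > 0]
        if len(ses) < 2:
            raise ValueError("fewer than 2 top components retain any SES variable")
        chosen = (
            ses.sort_values("mean_weight_strength", ascending=False)
            .head(config.n_ses_components).index.tolist()
        )
        overlap = ses_overlap(mask, curated, chosen)
        _save_json(
            {
                "components": overlap.components,
                "unique_counts": {c: len(s) for c, s in overlap.unique_sets.items()},
                "retained_counts": {c: len(s) for c, s in overlap.retained_sets.items()},
                "intersections": {"+".join(k): v for k, v in overlap.intersections.items()},
                "n_in_all": overlap.n_in_all(),
                "universe_size": overlap.universe_size,
            },
            "ses_overlap.json",
        )

        stage = "predict-state"
        ses_sc = ses_component_scores(curated, loadings, mask, chosen, curated)
        result = predict_state(ses_sc, states, n_folds=config.state_folds,
                               seed=config.state_seed)
        _save_df(result.confusion, "state_confusion.tsv", index=True)
        _save_df(result.coefficients, "state_coefficients.tsv", index=True)
        _save_json(
            {
                "chance_level_pct": result.chance_level,
                "overall_accuracy_pct": result.overall_accuracy,
                "above_chance_states": result.above_chance,
                "n_states": len(result.per_state_accuracy),
                "per_state_accuracy_pct": result.per_state_accuracy.to_dict(),
            },
            "state_prediction.json",
        )

        stage = "manifest"
        _save_json(
            {
                "version": _version,
                "config": config,
                "component_letters": letters,
                "chosen_ses_components": chosen,
                "checksums": {k: _sha256(p) for k, p in sorted(artifacts.items())},
            },
            "manifest.json",
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return out
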