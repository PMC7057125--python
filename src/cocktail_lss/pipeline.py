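"""End-to-end orchestration: simulate -> NCA -> develop -> select -> validate.

Every run is fully determined by its seed and configuration; the output
directory receives long-format data, metric tables, ranked models,
cross-probe model sets, validation reports, optional diagnostic figures
and a machine-readable manifest recording the seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import CocktailLSSError, PipelineError
from .lss import enumerate_and_rank, models_to_frame, predict, predictor_matrix, bias_precision
from .nca import best_estimates, summarize_metrics
from .selection import (
    COMBINED_R2_THRESHOLD,
    admissible_times,
    analyte_exclusions,
    anova_model_sets,
    combined_ranking,
    metabolite_blq_exclusions,
    model_sets_to_frame,
)
from .simulate import default_design, load_population, simulate_cohort
from .types import AUC_RATIO, LSSModel, format_times
from .validation import (
    external_validate,
    jackknife_validate,
    plot_bland_altman,
    plot_correlation,
    reports_to_frame,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of one full limited-sampling analysis run."""

    out_dir: Path
    seed: int = 42
    n_subjects: int = 16
    population_file: Path | None = None
    candidate_window: tuple[int, int] = (60, 300)
    max_k: int = 3
    include_pm_subject: bool = False
    make_figures: bool = True
    combined_k: int = 2
    prefer_earliest: bool = True


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Stages (each tagged in logs and failure messages):
    ``simulate`` -> ``nca`` -> ``develop`` (all-subsets per probe and k)
    -> ``select`` (cross-probe combined ranking + ANOVA over the top
    sets) -> ``validate`` (external on phase 2, jack-knife on both
    phases, for the selected shared 2-point set and the best single-point
    ratio models).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cocktail-lss",
        "version": __version__,
        "seed": int(config.seed),
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
        "files": [],
    }

    def _save(frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(out / name, index=False)
        manifest["files"].append(name)

    stage = "simulate"
    try:
        population = load_population(config.population_file)
        design = default_design(population, n_subjects=config.n_subjects)
        sim = simulate_cohort(
            design, population, seed=config.seed, include_pm_subject=config.include_pm_subject
        )
        dataset = sim.dataset
        dataset.to_csv(out / "cocktail_data.csv")
        manifest["files"].append("cocktail_data.csv")
        _save(sim.truth, "truth.csv")
        with open(out / "generation_config.json", "w", encoding="utf-8") as fh:
            json.dump(dataset.provenance, fh, indent=2, sort_keys=True)
        manifest["files"].append("generation_config.json")
        manifest["stages"][stage] = {"n_records": int(len(dataset.records))}

        stage = "nca"
        exclusions = metabolite_blq_exclusions(dataset, phase=1)
        metrics1 = best_estimates(dataset, 1, exclusions)
        metrics2 = best_estimates(dataset, 2, exclusions)
        metrics = pd.concat([metrics1, metrics2], ignore_index=True)
        _save(metrics, "metrics.csv")
        _save(summarize_metrics(metrics), "metrics_summary.csv")
        manifest["stages"][stage] = {
            "excluded_subjects": {k: sorted(v) for k, v in exclusions.items()}
        }

        stage = "develop"
        adm = admissible_times(
            dataset, phase=1, exclude_subjects=analyte_exclusions(dataset, exclusions)
        )
        lo, hi = config.candidate_window
        candidates = [t for t in adm if lo <= t <= hi]
        if len(candidates) < 1:
            raise PipelineError(f"no admissible candidate times inside {config.candidate_window}")
        max_k = min(config.max_k, max(len(candidates) - 1, 1))
        ranked_frames = []
        per_probe_models: dict[str, dict[int, list[LSSModel]]] = {}
        for probe in design.probes:
            X = predictor_matrix(
                dataset, probe.name, 1, times=candidates,
                exclude_subjects=exclusions.get(probe.name, set()),
            )
            y = metrics1[metrics1["probe"] == probe.name].set_index("subject_id")["value"]
            per_probe_models[probe.name] = {}
            for k in range(1, max_k + 1):
                models = enumerate_and_rank(X, y, k, probe.name, probe.metric_kind)
                evaluations = {}
                for m in models:
                    pred = predict(m, X.loc[:, list(m.sampling_times)])
                    evaluations[(m.probe, m.sampling_times)] = bias_precision(
                        pred.to_numpy(), y.reindex(X.index).to_numpy()
                    )
                per_probe_models[probe.name][k] = models
                ranked_frames.append(models_to_frame(models, evaluations))
        lss_models = pd.concat(ranked_frames, ignore_index=True)
        _save(lss_models, "lss_models.csv")
        manifest["stages"][stage] = {
            "admissible_times": adm,
            "candidate_times": candidates,
            "max_k": max_k,
        }

        stage = "select"
        kc = min(config.combined_k, max_k)
        per_probe_r2 = {
            name: {m.sampling_times: m.training_r2 for m in per_k[kc]}
            for name, per_k in per_probe_models.items()
        }
        summaries = combined_ranking(per_probe_r2)
        _save(model_sets_to_frame(summaries), "model_sets.csv")
        flagged = [s for s in summaries if s.flag_ge_threshold]
        top_sets = flagged if len(flagged) >= 2 else summaries[:4]
        anova = None
        if len(top_sets) >= 2:
            try:
                f_stat, p_val = anova_model_sets(
                    [list(s.per_probe_r2.values()) for s in top_sets]
                )
                anova = {"f": f_stat, "p": p_val, "n_sets": len(top_sets)}
            except CocktailLSSError as exc:
                log.warning("select: ANOVA skipped (%s)", exc)
        pool = flagged or summaries
        if config.prefer_earliest:
            selected = min(pool, key=lambda s: (s.sampling_times[-1], s.sampling_times))
        else:
            selected = pool[0]
        manifest["stages"][stage] = {
            "threshold": COMBINED_R2_THRESHOLD,
            "n_flagged": len(flagged),
            "selected_times": list(selected.sampling_times),
            "anova": anova,
        }

        stage = "validate"
        chosen: list[LSSModel] = []
        for probe in design.probes:
            models = per_probe_models[probe.name][kc]
            by_times = {m.sampling_times: m for m in models}
            chosen.append(by_times[selected.sampling_times])
            if probe.metric_kind == AUC_RATIO and 1 in per_probe_models[probe.name]:
                chosen.append(per_probe_models[probe.name][1][0])
        reports = external_validate(chosen, dataset, phase=2, exclude_subjects=exclusions)
        for model in chosen:
            for phase in (1, 2):
                reports.append(
                    jackknife_validate(
                        dataset, model.probe, model.sampling_times, phase, exclusions
                    )
                )
        _save(reports_to_frame(reports), "validation_report.csv")
        manifest["stages"][stage] = {"n_reports": len(reports)}

        if config.make_figures:
            import matplotlib

            matplotlib.rcParams["svg.hashsalt"] = str(config.seed)
            for rep in reports:
                if rep.mode != "external":
                    continue
                tag = f"{rep.probe}_{format_times(rep.sampling_times).replace(';', '-')}"
                plot_correlation(
                    rep.per_subject["predicted"], rep.per_subject["best"],
                    out / f"correlation_{tag}.svg", title=f"{rep.probe} {rep.sampling_times}",
                )
                plot_bland_altman(
                    rep.per_subject["predicted"], rep.per_subject["best"],
                    out / f"bland_altman_{tag}.svg", title=f"{rep.probe} {rep.sampling_times}",
                )
                manifest["files"] += [f"correlation_{tag}.svg", f"bland_altman_{tag}.svg"]
    except CocktailLSSError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return manifest
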