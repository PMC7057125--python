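"""Validation of limited-sampling models.

Two complementary checks are provided.  External validation freezes the
training-phase coefficients and applies them to the second study phase,
comparing predictions with that phase's own best estimates.  Jack-knife
validation refits the equation n times on n-1 subjects at fixed sampling
times and predicts each left-out subject, so no subject influences the
coefficients used for its own prediction; the n out-of-fit predictions
are pooled into a single r^2/MD%/MAD% summary.  Bland-Altman limits of
agreement visualise the same comparisons on the metric scale.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, InsufficientDataError
from .lss import bias_precision, fit_ols, predict, predictor_matrix
from .nca import best_estimates
from .types import (
    EXTERNAL,
    JACKKNIFE_TRAIN,
    JACKKNIFE_VALID,
    BlandAltman,
    CocktailDataset,
    LSSModel,
    ModelEvaluation,
    ValidationReport,
)

log = logging.getLogger(__name__)


def _report(
    model: LSSModel, mode: str, pred: pd.Series, best: pd.Series, source: str
) -> ValidationReport:
    evaluation = bias_precision(pred.to_numpy(), best.to_numpy())
    per_subject = pd.DataFrame(
        {
            "subject_id": best.index,
            "best": best.to_numpy(),
            "predicted": pred.to_numpy(),
        }
    ).reset_index(drop=True)
    return ValidationReport(
        probe=model.probe,
        metric_kind=model.metric_kind,
        sampling_times=model.sampling_times,
        mode=mode,
        evaluation=evaluation,
        per_subject=per_subject,
        source=source,
    )


def external_validate(
    models: Iterable[LSSModel],
    dataset: CocktailDataset,
    phase: int = 2,
    exclude_subjects: dict[str, set[int]] | None = None,
    metrics: pd.DataFrame | None = None,
    source: str = "fitted",
) -> list[ValidationReport]:
    """Apply frozen training-phase models to another phase.

    Coefficients are never refit; predictions from the validation phase's
    concentrations (or ratios) at the model times are compared with that
    phase's best estimates.  Deterministic: rerunning on the same inputs
    reproduces the reports exactly.
    """
    exclude_subjects = exclude_subjects or {}
    if metrics is None:
        metrics = best_estimates(dataset, phase, exclude_subjects)
    reports = []
    for model in models:
        X = predictor_matrix(
            dataset,
            model.probe,
            phase,
            times=model.sampling_times,
            exclude_subjects=exclude_subjects.get(model.probe, set()),
        )
        best = (
            metrics[metrics["probe"] == model.probe]
            .set_index("subject_id")["value"]
            .reindex(X.index)
        )
        pred = predict(model, X)
        reports.append(_report(model, EXTERNAL, pred, best, source))
    return reports


def loo_predictions(X: pd.DataFrame, y: pd.Series, probe: str, metric_kind: str) -> pd.Series:
    """Leave-one-out OLS predictions at fixed sampling times.

    For each subject i the model is refit on the other n-1 subjects and
    used to predict subject i, so the prediction never depends on the
    subject's own response.  Subjects whose leave-one-out fit is
    rank-deficient are skipped with a log record.
    """
    if len(y) < X.shape[1] + 3:
        raise InsufficientDataError(
            f"need at least k+3 subjects for jack-knife (have {len(y)}, k={X.shape[1]})"
        )
    preds = {}
    for subject in y.index:
        rest = y.index.drop(subject)
        try:
            m = fit_ols(X.loc[rest], y.loc[rest], probe, metric_kind)
        except FitError as exc:
            log.warning("jack-knife: skipping subject %s (%s)", subject, exc)
            continue
        preds[subject] = float(predict(m, X.loc[[subject]]).iloc[0])
    return pd.Series(preds, name="predicted")


def jackknife_validate(
    dataset: CocktailDataset,
    probe_name: str,
    sampling_times: Sequence[int],
    phase: int,
    exclude_subjects: dict[str, set[int]] | None = None,
    metrics: pd.DataFrame | None = None,
) -> ValidationReport:
    """Jack-knife (leave-one-subject-out) validation of one time set.

    Applied to a single phase at a time; the report mode records whether
    the phase is the training (phase 1) or validation (phase 2) dataset.
    The pooled out-of-fit predictions are summarised in one evaluation,
    matching the one-R^2-per-model convention of limited-sampling reports.
    """
    exclude_subjects = exclude_subjects or {}
    if metrics is None:
        metrics = best_estimates(dataset, phase, exclude_subjects)
    probe = dataset.design.probe(probe_name)
    times = tuple(int(t) for t in sampling_times)
    X = predictor_matrix(
        dataset,
        probe_name,
        phase,
        times=times,
        exclude_subjects=exclude_subjects.get(probe_name, set()),
    )
    y = (
        metrics[metrics["probe"] == probe_name]
        .set_index("subject_id")["value"]
        .reindex(X.index)
    )
    pred = loo_predictions(X, y, probe_name, probe.metric_kind)
    best = y.loc[pred.index]
    model = LSSModel(
        probe=probe_name,
        metric_kind=probe.metric_kind,
        sampling_times=times,
        intercept=float("nan"),
        coefficients=tuple(float("nan") for _ in times),
        training_r2=None,
    )
    mode = JACKKNIFE_TRAIN if phase == 1 else JACKKNIFE_VALID
    return _report(model, mode, pred, best, source="jackknife")


def bland_altman(predicted, best) -> BlandAltman:
    """Mean difference and 1.96-SD limits of agreement, on the metric scale."""
    pred = np.asarray(predicted, dtype=float)
    bst = np.asarray(best, dtype=float)
    if pred.shape != bst.shape or pred.size < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 paired values")
    d = pred - bst
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_diff=mean, sd_diff=sd, loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd
    )


def evaluation_from_report(report: ValidationReport) -> ModelEvaluation:
    """Recompute the summary statistics from the per-subject rows."""
    return bias_precision(
        report.per_subject["predicted"].to_numpy(),
        report.per_subject["best"].to_numpy(),
    )


def reports_to_frame(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    from .types import format_times

    rows = []
    for r in reports:
        e = r.evaluation
        rows.append(
            {
                "probe": r.probe,
                "metric_kind": r.metric_kind,
                "times": format_times(r.sampling_times),
                "mode": r.mode,
                "source": r.source,
                "n_subjects": e.n_subjects,
                "r2": e.r2,
                "md_pct_mean": e.md_pct_mean,
                "md_pct_sd": e.md_pct_sd,
                "mad_pct_mean": e.mad_pct_mean,
                "mad_pct_sd": e.mad_pct_sd,
            }
        )
    return pd.DataFrame(rows)


def plot_bland_altman(predicted, best, path, title: str = "") -> None:
    """Difference-vs-mean agreement plot written as a vector file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred = np.asarray(predicted, dtype=float)
    bst = np.asarray(best, dtype=float)
    ba = bland_altman(pred, bst)
    x = (pred + bst) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, pred - bst, s=25, color="black")
    for yv, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="grey")
    ax.set_xlabel("mean of predicted and best estimate")
    ax.set_ylabel("predicted - best estimate")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def plot_correlation(predicted, best, path, title: str = "") -> None:
    """Predicted-vs-best scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred = np.asarray(predicted, dtype=float)
    bst = np.asarray(best, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(bst, pred, s=25, color="black")
    lo = min(bst.min(), pred.min())
    hi = max(bst.max(), pred.max())
    ax.plot([lo, hi], [lo, hi], color="grey", linewidth=1)
    ax.set_xlabel("best estimate")
    ax.set_ylabel("LSS-predicted")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
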