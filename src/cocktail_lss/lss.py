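"""All-subsets limited-sampling model development.

A limited-sampling strategy (LSS) predicts a full-profile phenotypic
metric from concentrations at a handful of fixed times via an ordinary
least-squares equation

    metric = A0 + A1*C(t1) + ... + An*C(tn).

Development enumerates every size-k subset of the candidate times, fits
each by OLS against the best-estimate metrics, and ranks the equations by
the training coefficient of determination R^2.  For ratio probes the
predictors are per-time parent:metabolite concentration ratios instead of
raw concentrations.

Two distinct R^2 notions are kept apart deliberately: ``training_r2`` is
the OLS coefficient of determination of a fit, while evaluation r^2
(in :func:`bias_precision`) is the squared Pearson correlation between
predicted and best-estimate values on whatever dataset is being judged.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataValidationError,
    FitError,
    InsufficientDataError,
    PredictionError,
)
from .nca import ratio_profile
from .types import AUC, AUC_RATIO, CocktailDataset, LSSModel, ModelEvaluation

log = logging.getLogger(__name__)

#: Two R^2 values closer than this are treated as tied when ranking.
R2_TIE_TOL = 1e-10


def predictor_matrix(
    dataset: CocktailDataset,
    probe_name: str,
    phase: int,
    times: Sequence[int] | None = None,
    exclude_subjects: Iterable[int] = (),
) -> pd.DataFrame:
    """Per-subject predictor values at the requested times.

    Rows are subjects, columns sampling times (minutes).  For AUC probes
    the entries are parent concentrations; for ratio probes they are the
    per-time parent:metabolite concentration ratios.  Times where a ratio
    is invalid (metabolite zero/BLQ) come back as NaN so that downstream
    fits fail loudly rather than silently absorbing them.
    """
    probe = dataset.design.probe(probe_name)
    excluded = set(exclude_subjects)
    if times is not None:
        times = [int(t) for t in times]
    rows: dict[int, pd.Series] = {}
    for subject in dataset.subjects():
        if subject in excluded:
            continue
        parent = dataset.profile(subject, phase, probe.parent)
        if probe.metric_kind == AUC:
            series = pd.Series(
                parent.conc_ng_ml, index=parent.times_min.astype(int), dtype=float
            )
        else:
            metab = dataset.profile(subject, phase, probe.metabolite)
            rp = ratio_profile(parent, metab)
            series = pd.Series(rp["ratio"].to_numpy(), index=rp["time_min"], dtype=float)
        rows[subject] = series
    X = pd.DataFrame(rows).T.sort_index()
    X.index.name = "subject_id"
    if times is not None:
        missing = [t for t in times if t not in X.columns]
        if missing:
            raise PredictionError(f"dataset lacks sampling times {missing} for {probe_name}")
        X = X.loc[:, times]
    return X


def fit_ols(
    X: pd.DataFrame,
    y: pd.Series,
    probe: str,
    metric_kind: str,
) -> LSSModel:
    """Ordinary least-squares fit of the metric on timed predictors.

    ``X`` is subjects x times (columns are sampling times in minutes),
    ``y`` the best-estimate metric aligned on the same subjects.  The
    training R^2 is 1 - SS_res/SS_tot (defined as 0 when the response is
    constant).  Raises :class:`FitError` on rank-deficient designs,
    naming the offending time columns.
    """
    if metric_kind not in (AUC, AUC_RATIO):
        raise ConfigurationError(f"unknown metric kind {metric_kind!r}")
    X = X.reindex(index=y.index)
    if X.isna().any().any() or y.isna().any():
        bad = [int(c) for c in X.columns[X.isna().any()]]
        raise DataValidationError(
            f"missing predictor/response values (times {bad}) for probe {probe!r}"
        )
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError(
            f"{n} subjects cannot support a {k}-time model (need > k+1)"
        )
    times = tuple(int(c) for c in X.columns)
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        offenders = _rank_deficient_columns(X)
        raise FitError(
            f"rank-deficient design for probe {probe!r}: offending times {offenders}"
        )
    yv = y.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return LSSModel(
        probe=probe,
        metric_kind=metric_kind,
        sampling_times=times,
        intercept=float(beta[0]),
        coefficients=tuple(float(b) for b in beta[1:]),
        training_r2=r2,
    )


def _rank_deficient_columns(X: pd.DataFrame) -> list[int]:
    """Identify constant or duplicated predictor columns for error messages."""
    offenders: list[int] = []
    arr = X.to_numpy(dtype=float)
    for i, col in enumerate(X.columns):
        if np.allclose(arr[:, i], arr[0, i]):
            offenders.append(int(col))
    for i, j in itertools.combinations(range(arr.shape[1]), 2):
        if np.allclose(arr[:, i], arr[:, j]):
            offenders.extend([int(X.columns[i]), int(X.columns[j])])
    return sorted(set(offenders)) or [int(c) for c in X.columns]


def _rank_key(model: LSSModel):
    # Descending R^2 with ties (to R2_TIE_TOL) broken toward the subset
    # whose latest sample comes earliest, then lexicographically earlier
    # times: shorter clinic visits win when the fit is equal.
    quantized = round(model.training_r2 / R2_TIE_TOL)
    return (-quantized, model.sampling_times[-1], model.sampling_times)


def enumerate_and_rank(
    X_all: pd.DataFrame,
    y: pd.Series,
    k: int,
    probe: str,
    metric_kind: str,
    candidate_times: Sequence[int] | None = None,
) -> list[LSSModel]:
    """Fit every size-k subset of candidate times and rank by training R^2.

    Exhaustive all-subsets enumeration: C(len(candidates), k) OLS fits.
    The returned list is sorted best-first with a deterministic tie-break
    (earlier latest time, then lexicographic order).
    """
    if k < 1:
        raise ConfigurationError("subset size k must be >= 1")
    candidates = (
        [int(c) for c in X_all.columns]
        if candidate_times is None
        else [int(t) for t in candidate_times]
    )
    missing = [t for t in candidates if t not in X_all.columns]
    if missing:
        raise ConfigurationError(f"candidate times {missing} absent from predictors")
    if k > len(candidates):
        raise ConfigurationError(
            f"subset size {k} exceeds {len(candidates)} candidate times"
        )
    models = [
        fit_ols(X_all.loc[:, list(subset)], y, probe, metric_kind)
        for subset in itertools.combinations(sorted(candidates), k)
    ]
    return sorted(models, key=_rank_key)


def predict(model: LSSModel, concentrations) -> pd.Series:
    """Apply a fitted (or published) LSS equation to timed predictor values.

    ``concentrations`` is a DataFrame (subjects x times), a Series or a
    mapping keyed by sampling time.  Negative predictions are possible
    for low profiles; they are returned as-is and logged, never truncated
    (truncation would bias the bias statistics).
    """
    if isinstance(concentrations, Mapping):
        concentrations = pd.Series(dict(concentrations))
    if isinstance(concentrations, pd.Series):
        frame = concentrations.to_frame().T
        single = True
    else:
        frame = concentrations
        single = False
    cols = [int(c) for c in frame.columns]
    missing = [t for t in model.sampling_times if t not in cols]
    if missing:
        raise PredictionError(
            f"missing sampling times {missing} for {model.probe} model"
        )
    frame = frame.copy()
    frame.columns = cols
    values = frame.loc[:, list(model.sampling_times)].to_numpy(dtype=float)
    pred = model.intercept + values @ np.asarray(model.coefficients)
    n_neg = int((pred < 0).sum())
    if n_neg:
        log.warning(
            "%s model %s produced %d negative prediction(s); reported as-is",
            model.probe,
            model.sampling_times,
            n_neg,
        )
    if single:
        return pd.Series(pred, index=[0])
    return pd.Series(pred, index=frame.index, name="predicted")


def bias_precision(predicted, best) -> ModelEvaluation:
    """Bias and precision of model-derived metrics against best estimates.

    Per subject, d = (predicted - best)/best * 100.  Bias MD% is
    mean(d) +/- sample SD; precision MAD% is mean(|d|) +/- sample SD of
    |d|; r2 is the squared Pearson correlation of the paired values.
    """
    pred = np.asarray(predicted, dtype=float)
    bst = np.asarray(best, dtype=float)
    if pred.shape != bst.shape:
        raise DataValidationError("predicted and best vectors differ in length")
    if pred.size < 2:
        raise InsufficientDataError("need at least 2 paired values")
    if np.any(bst == 0.0):
        raise DataValidationError("percentage differences undefined: a best estimate is 0")
    d = (pred - bst) / bst * 100.0
    ad = np.abs(d)
    if np.std(pred) == 0.0 or np.std(bst) == 0.0:
        r2 = 1.0 if np.allclose(pred, bst) else 0.0
    else:
        r = float(np.corrcoef(pred, bst)[0, 1])
        r2 = r * r
    return ModelEvaluation(
        r2=r2,
        md_pct_mean=float(np.mean(d)),
        md_pct_sd=float(np.std(d, ddof=1)),
        mad_pct_mean=float(np.mean(ad)),
        mad_pct_sd=float(np.std(ad, ddof=1)),
        n_subjects=int(pred.size),
    )


def models_to_frame(models: Iterable[LSSModel], evaluations=None) -> pd.DataFrame:
    """Serialize models (optionally with evaluations) to the CSV schema."""
    from .types import format_times

    rows = []
    evaluations = evaluations or {}
    for rank, m in enumerate(models, start=1):
        ev: ModelEvaluation | None = evaluations.get((m.probe, m.sampling_times))
        rows.append(
            {
                "probe": m.probe,
                "metric_kind": m.metric_kind,
                "k": len(m.sampling_times),
                "rank": rank,
                "times": format_times(m.sampling_times),
                "intercept": m.intercept,
                "coefficients": ";".join(repr(c) for c in m.coefficients),
                "r2": m.training_r2,
                "md_pct_mean": ev.md_pct_mean if ev else np.nan,
                "md_pct_sd": ev.md_pct_sd if ev else np.nan,
                "mad_pct_mean": ev.mad_pct_mean if ev else np.nan,
                "mad_pct_sd": ev.mad_pct_sd if ev else np.nan,
            }
        )
    return pd.DataFrame(rows)


def frame_to_models(frame: pd.DataFrame) -> list[LSSModel]:
    from .types import parse_times

    out = []
    for _, row in frame.iterrows():
        out.append(
            LSSModel(
                probe=row["probe"],
                metric_kind=row["metric_kind"],
                sampling_times=parse_times(row["times"]),
                intercept=float(row["intercept"]),
                coefficients=tuple(float(c) for c in str(row["coefficients"]).split(";")),
                training_r2=float(row["r2"]) if not pd.isna(row.get("r2")) else None,
            )
        )
    return out
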