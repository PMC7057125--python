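"""Non-compartmental best-estimate metrics.

The "best estimate" of each phenotypic index uses every available sample:
the linear-trapezoidal AUC(0-12h) for AUC probes, and the ratio of parent
to metabolite AUC(0-12h) for ratio probes.  Limited-sampling predictions
are judged against these values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataValidationError,
    InsufficientDataError,
    UndefinedRatioError,
)
from .types import (
    AUC,
    MIN_PER_H,
    T_END_MIN,
    CocktailDataset,
    ConcentrationProfile,
)

log = logging.getLogger(__name__)


def trapezoid_auc(
    profile: ConcentrationProfile,
    t_start: float = 0.0,
    t_end: float = T_END_MIN,
) -> float:
    """Linear-trapezoidal AUC over [t_start, t_end], in ng*h/mL.

    Sums (t_{i+1} - t_i) * (C_i + C_{i+1}) / 2 over the profile points
    inside the window and divides by 60 exactly once (times are minutes,
    AUC is reported in hours).  Exact for piecewise-linear profiles.

    BLQ points contribute their recorded concentration; BLQ handling by
    time-point exclusion happens at the model-selection stage, not here.
    """
    if t_start >= t_end:
        raise DataValidationError("t_start must be below t_end")
    t = np.asarray(profile.times_min, dtype=float)
    c = np.asarray(profile.conc_ng_ml, dtype=float)
    mask = (t >= t_start) & (t <= t_end)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"fewer than 2 points in [{t_start}, {t_end}] for "
            f"subject {profile.subject_id} {profile.analyte}"
        )
    return float(np.trapezoid(c[mask], t[mask])) / MIN_PER_H


def auc_ratio(parent: ConcentrationProfile, metabolite: ConcentrationProfile) -> float:
    """Parent:metabolite AUC(0-12h) ratio for one subject and phase."""
    if (parent.subject_id, parent.phase) != (metabolite.subject_id, metabolite.phase):
        raise DataValidationError("parent and metabolite profiles must share subject and phase")
    num = trapezoid_auc(parent)
    den = trapezoid_auc(metabolite)
    if den == 0.0:
        raise UndefinedRatioError(
            f"metabolite AUC is zero for subject {parent.subject_id}, "
            f"phase {parent.phase} ({metabolite.analyte})"
        )
    return num / den


def ratio_profile(
    parent: ConcentrationProfile, metabolite: ConcentrationProfile
) -> pd.DataFrame:
    """Per-time parent:metabolite concentration ratios.

    Returns a frame with columns ``time_min``, ``ratio`` and ``valid``.
    Times where the metabolite is BLQ or zero are flagged invalid (ratio
    NaN) rather than dropped, so callers see exactly which points failed.
    """
    tp = np.asarray(parent.times_min, dtype=float)
    tm = np.asarray(metabolite.times_min, dtype=float)
    if tp.shape != tm.shape or np.any(tp != tm):
        raise DataValidationError("parent and metabolite profiles are on different time grids")
    cm = np.asarray(metabolite.conc_ng_ml, dtype=float)
    cp = np.asarray(parent.conc_ng_ml, dtype=float)
    invalid = (cm == 0.0) | np.asarray(metabolite.blq, dtype=bool)
    ratio = np.full_like(cp, np.nan)
    ok = ~invalid
    ratio[ok] = cp[ok] / cm[ok]
    return pd.DataFrame({"time_min": tp.astype(int), "ratio": ratio, "valid": ok})


def best_estimates(
    dataset: CocktailDataset,
    phase: int,
    exclude_subjects: dict[str, set[int]] | None = None,
) -> pd.DataFrame:
    """Best-estimate phenotypic metric for every subject x probe in a phase.

    Returns columns ``subject_id, phase, probe, metric_kind, value``.
    ``exclude_subjects`` maps probe name -> subjects to omit for that
    probe only (e.g. a poor metabolizer whose metabolite ratio is
    unusable); other probes keep the subject.
    """
    exclude_subjects = exclude_subjects or {}
    rows: list[dict] = []
    for probe in dataset.design.probes:
        excluded = exclude_subjects.get(probe.name, set())
        for subject in dataset.subjects():
            if subject in excluded:
                continue
            try:
                parent = dataset.profile(subject, phase, probe.parent)
            except DataValidationError as exc:
                raise ConfigurationError(
                    f"probe {probe.name!r}: missing parent records"
                ) from exc
            if probe.metric_kind == AUC:
                value = trapezoid_auc(parent)
            else:
                try:
                    metab = dataset.profile(subject, phase, probe.metabolite)
                except DataValidationError as exc:
                    raise ConfigurationError(
                        f"probe {probe.name!r}: metabolite {probe.metabolite!r} absent"
                    ) from exc
                value = auc_ratio(parent, metab)
            rows.append(
                {
                    "subject_id": subject,
                    "phase": phase,
                    "probe": probe.name,
                    "metric_kind": probe.metric_kind,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) of each probe metric, one row per probe x phase."""
    def _q(s, q):
        return float(np.percentile(s, q))

    out = []
    for (probe, phase), grp in metrics.groupby(["probe", "phase"]):
        v = grp["value"].to_numpy()
        out.append(
            {
                "probe": probe,
                "phase": phase,
                "metric_kind": grp["metric_kind"].iloc[0],
                "n": len(v),
                "median": float(np.median(v)),
                "iqr_low": _q(v, 25),
                "iqr_high": _q(v, 75),
            }
        )
    return pd.DataFrame(out)
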