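"""Candidate-time admissibility and cross-probe model-set selection.

Sampling times are admissible only when no analysed analyte is BLQ at
that time for any subject — a single BLQ record disqualifies the time for
everyone, because a shared cocktail schedule must work for every probe
simultaneously.  Among admissible times, candidate k-subsets are compared
across probes by the mean +/- SD of the per-probe training R^2 values,
and close contenders can be tested for real differences with a one-way
ANOVA.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateVarianceError,
    EmptyAdmissibleSetError,
)
from .types import AUC_RATIO, CocktailDataset, ModelSetSummary

log = logging.getLogger(__name__)

#: Mean-R^2 level above which a shared sampling-time set is flagged as
#: adequate for all probes at once.
COMBINED_R2_THRESHOLD = 0.95


def admissible_times(
    dataset: CocktailDataset,
    phase: int | None = None,
    exclude_subjects: Mapping[str, set[int]] | None = None,
    analytes: Sequence[str] | None = None,
) -> list[int]:
    """Times with no BLQ record for any analysed analyte in any subject.

    ``exclude_subjects`` maps analyte -> subject ids to ignore (e.g. the
    poor metabolizer removed from the metoprolol analysis); their BLQ
    records then do not disqualify a time.  Raises
    :class:`EmptyAdmissibleSetError` with per-time diagnostics when
    nothing survives.
    """
    rec = dataset.records
    if phase is not None:
        rec = rec[rec["phase"] == phase]
    if analytes is not None:
        rec = rec[rec["analyte"].isin(set(analytes))]
    if rec.empty:
        raise DataValidationError("no records to assess admissibility on")
    if exclude_subjects:
        keep = np.ones(len(rec), dtype=bool)
        for analyte, subjects in exclude_subjects.items():
            keep &= ~(
                (rec["analyte"] == analyte).to_numpy()
                & rec["subject_id"].isin(set(subjects)).to_numpy()
            )
        rec = rec[keep]
    blq_counts = rec.groupby("time_min")["blq"].sum()
    times = sorted(int(t) for t in rec["time_min"].unique())
    admissible = [t for t in times if int(blq_counts.get(t, 0)) == 0]
    if not admissible:
        diag = ", ".join(f"{t} min: {int(blq_counts.get(t, 0))} BLQ" for t in times)
        raise EmptyAdmissibleSetError(f"every time point has BLQ records ({diag})")
    return admissible


def metabolite_blq_exclusions(
    dataset: CocktailDataset, phase: int, blq_fraction: float = 0.5
) -> dict[str, set[int]]:
    """Subjects to drop per ratio probe because the metabolite is mostly BLQ.

    A subject whose metabolite is below LLOQ in more than ``blq_fraction``
    of samples (e.g. a poor metabolizer) has no usable metabolic-ratio
    metric; the subject is excluded from that probe only.
    Returns a probe-name -> subject-id-set mapping (empty sets omitted).
    """
    out: dict[str, set[int]] = {}
    rec = dataset.records[dataset.records["phase"] == phase]
    for probe in dataset.design.probes:
        if probe.metric_kind != AUC_RATIO:
            continue
        sub = rec[rec["analyte"] == probe.metabolite]
        frac = sub.groupby("subject_id")["blq"].mean()
        bad = {int(s) for s, f in frac.items() if f > blq_fraction}
        if bad:
            log.info(
                "probe %s: excluding subjects %s (metabolite BLQ fraction > %.0f%%)",
                probe.name,
                sorted(bad),
                100 * blq_fraction,
            )
            out[probe.name] = bad
    return out


def analyte_exclusions(
    dataset: CocktailDataset, probe_exclusions: Mapping[str, set[int]]
) -> dict[str, set[int]]:
    """Translate per-probe subject exclusions into per-analyte exclusions."""
    out: dict[str, set[int]] = {}
    for probe_name, subjects in probe_exclusions.items():
        probe = dataset.design.probe(probe_name)
        for analyte in probe.analytes:
            out.setdefault(analyte, set()).update(subjects)
    return out


def combined_ranking(
    per_probe_r2: Mapping[str, Mapping[tuple[int, ...], float]],
    threshold: float = COMBINED_R2_THRESHOLD,
) -> list[ModelSetSummary]:
    """Rank shared sampling-time sets by their mean R^2 across probes.

    ``per_probe_r2`` maps probe -> {time-subset: training R^2}; every
    probe must cover the same subsets.  Returns summaries sorted by mean
    R^2 descending (ties: earlier latest time), each flagged when the
    mean exceeds ``threshold``.  The flag is advisory — final choice
    among flagged sets is the caller's, typically on convenience grounds.
    """
    if not per_probe_r2:
        raise ConfigurationError("no per-probe R^2 tables supplied")
    probes = sorted(per_probe_r2)
    subsets = {tuple(s) for s in per_probe_r2[probes[0]]}
    for p in probes[1:]:
        other = {tuple(s) for s in per_probe_r2[p]}
        if other != subsets:
            diff = subsets.symmetric_difference(other)
            raise ConfigurationError(
                f"probe {p!r} does not cover the same subsets (mismatch: {sorted(diff)[:5]})"
            )
    out = []
    for subset in subsets:
        values = {p: float(per_probe_r2[p][subset]) for p in probes}
        arr = np.array(list(values.values()))
        out.append(
            ModelSetSummary(
                sampling_times=tuple(int(t) for t in subset),
                per_probe_r2=values,
                mean_r2=float(arr.mean()),
                sd_r2=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                flag_ge_threshold=bool(arr.mean() > threshold),
            )
        )
    return sorted(
        out, key=lambda s: (-s.mean_r2, s.sampling_times[-1], s.sampling_times)
    )


def anova_model_sets(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over groups of per-probe R^2 values.

    Each group holds the per-probe R^2 of one candidate model set; the
    test asks whether any set outperforms the others beyond within-set
    scatter.  Returns (F, p).
    """
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ConfigurationError("each ANOVA group needs at least 2 values")
    if all(np.allclose(a, a[0]) for a in arrays):
        raise DegenerateVarianceError("zero within-group variance in every group")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def model_sets_to_frame(summaries: Sequence[ModelSetSummary]) -> pd.DataFrame:
    from .types import format_times

    probes = sorted(summaries[0].per_probe_r2) if summaries else []
    rows = []
    for s in summaries:
        row = {
            "times": format_times(s.sampling_times),
            "mean_r2": s.mean_r2,
            "sd_r2": s.sd_r2,
        }
        row.update({f"{p}_r2": s.per_probe_r2[p] for p in probes})
        row["flag_ge_0.95"] = int(s.flag_ge_threshold)
        rows.append(row)
    return pd.DataFrame(rows)
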