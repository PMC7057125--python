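"""Core domain containers.

The package models a two-phase phenotyping-cocktail study: every subject
receives subtherapeutic doses of several enzyme/transporter-selective
probe drugs and plasma is sampled on a fixed 0-720 min grid.  The
phenotypic metric is either the probe's AUC(0-12h) or the probe:metabolite
AUC(0-12h) ratio, and limited-sampling models predict that metric from a
linear combination of concentrations (or concentration ratios) at one to
three sampling times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError, ParameterError

# Metric kinds
AUC = "auc"
AUC_RATIO = "auc_ratio"

# Analyte identifiers (ASCII-safe column values)
CAFFEINE = "caffeine"
FEXOFENADINE = "fexofenadine"
MIDAZOLAM = "midazolam"
METOPROLOL = "metoprolol"
A_OH_METOPROLOL = "alpha_oh_metoprolol"
OMEPRAZOLE = "omeprazole"
OH_OMEPRAZOLE = "5_oh_omeprazole"

#: The trial's sampling grid, minutes post-dose.
STUDY_TIMES_MIN = (0, 15, 30, 45, 60, 90, 120, 180, 240, 300, 360, 480, 600, 720)

#: End of the AUC window (12 h).
T_END_MIN = 720

#: Minutes per hour; applied exactly once when converting trapezoid sums to ng*h/mL.
MIN_PER_H = 60.0


@dataclass(frozen=True)
class ProbeSpec:
    """One probe drug and the phenotypic metric derived from it.

    ``metric_kind`` is :data:`AUC` for probes whose AUC(0-12h) is the
    phenotypic index (caffeine/CYP1A2, fexofenadine/ABCB1,
    midazolam/CYP3A) and :data:`AUC_RATIO` for probes indexed by the
    parent:metabolite AUC ratio (metoprolol/CYP2D6, omeprazole/CYP2C19).
    """

    name: str
    parent: str
    metabolite: str | None
    metric_kind: str

    def __post_init__(self) -> None:
        if self.metric_kind not in (AUC, AUC_RATIO):
            raise ConfigurationError(f"unknown metric kind {self.metric_kind!r}")
        if self.metric_kind == AUC_RATIO and self.metabolite is None:
            raise ConfigurationError(
                f"probe {self.name!r}: ratio metric requires a metabolite"
            )

    @property
    def analytes(self) -> tuple[str, ...]:
        return (self.parent,) if self.metabolite is None else (self.parent, self.metabolite)


DEFAULT_PROBES: tuple[ProbeSpec, ...] = (
    ProbeSpec(CAFFEINE, CAFFEINE, None, AUC),
    ProbeSpec(FEXOFENADINE, FEXOFENADINE, None, AUC),
    ProbeSpec(MIDAZOLAM, MIDAZOLAM, None, AUC),
    ProbeSpec(METOPROLOL, METOPROLOL, A_OH_METOPROLOL, AUC_RATIO),
    ProbeSpec(OMEPRAZOLE, OMEPRAZOLE, OH_OMEPRAZOLE, AUC_RATIO),
)


@dataclass(frozen=True)
class PKParameters:
    """Subject-level kinetic parameters for one parent/metabolite pair.

    One-compartment, first-order absorption.  ``bioavail_scale`` folds
    bioavailability and all unit conversions (mg dose, L volume, ng/mL
    concentration) into a single dimensionless multiplier, so the
    concentration formulas stay unit-agnostic.

    Rate constants are per hour; times fed to the concentration functions
    are minutes and converted internally.
    """

    dose: float  # mg
    bioavail_scale: float  # dimensionless, > 0
    ka: float  # absorption rate constant, 1/h
    ke: float  # parent elimination rate constant, 1/h
    vd_f: float  # apparent distribution volume, L
    fm: float = 0.0  # fraction of elimination forming the metabolite, in [0, 1]
    km: float = 0.0  # metabolite elimination rate constant, 1/h (0 if no metabolite)
    metab_scale: float = 1.0  # parent:metabolite volume ratio Vp/Vm folded into one constant

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.bioavail_scale <= 0 or self.vd_f <= 0:
            raise ParameterError("dose, bioavail_scale and vd_f must be positive")
        if self.ka <= 0 or self.ke <= 0:
            raise ParameterError("rate constants ka and ke must be positive")
        if not 0.0 <= self.fm <= 1.0:
            raise ParameterError(f"fm must lie in [0, 1], got {self.fm}")
        if self.km < 0:
            raise ParameterError("km must be non-negative")
        if self.metab_scale <= 0:
            raise ParameterError("metab_scale must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Layout of one cocktail study: subjects x phases x analytes x times."""

    n_subjects: int = 16
    sampling_times: tuple[int, ...] = STUDY_TIMES_MIN
    probes: tuple[ProbeSpec, ...] = DEFAULT_PROBES
    lloq: Mapping[str, float] = field(default_factory=dict)
    n_phases: int = 2

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ConfigurationError("sampling_times must be strictly increasing")
        if t[0] != 0 or t[-1] != T_END_MIN:
            raise ConfigurationError(
                f"sampling grid must start at 0 and end at {T_END_MIN} min"
            )
        if self.n_subjects < 1 or self.n_phases < 1:
            raise ConfigurationError("need at least one subject and one phase")
        if not self.probes:
            raise ConfigurationError("probe list is empty")
        parents = [p.parent for p in self.probes]
        if len(set(parents)) != len(parents):
            raise ConfigurationError("duplicate parent analyte across probes")

    @property
    def analytes(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.probes:
            out.extend(p.analytes)
        return tuple(out)

    def probe(self, name: str) -> ProbeSpec:
        for p in self.probes:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown probe {name!r}")


#: Canonical column order of the long-format concentration table.
RECORD_COLUMNS = ("subject_id", "phase", "analyte", "time_min", "conc_ng_ml", "blq")


@dataclass
class CocktailDataset:
    """Long-format concentration records plus the design they instantiate.

    ``records`` has one row per (subject, phase, analyte, time) with
    columns :data:`RECORD_COLUMNS`; ``blq`` is 0/1.  ``provenance`` holds
    the generator seed and parameters for synthetic data and is empty for
    real data.
    """

    design: StudyDesign
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise DataValidationError(f"records missing columns {sorted(missing)}")
        if (self.records["conc_ng_ml"] < 0).any():
            raise DataValidationError("negative concentrations in records")
        keys = ["subject_id", "phase", "analyte", "time_min"]
        if self.records.duplicated(subset=keys).any():
            raise DataValidationError("duplicate (subject, phase, analyte, time) rows")

    def profile(self, subject_id: int, phase: int, analyte: str) -> "ConcentrationProfile":
        sel = self.records[
            (self.records["subject_id"] == subject_id)
            & (self.records["phase"] == phase)
            & (self.records["analyte"] == analyte)
        ].sort_values("time_min")
        if sel.empty:
            raise DataValidationError(
                f"no records for subject {subject_id}, phase {phase}, analyte {analyte!r}"
            )
        return ConcentrationProfile(
            subject_id=subject_id,
            phase=phase,
            analyte=analyte,
            times_min=sel["time_min"].to_numpy(dtype=float),
            conc_ng_ml=sel["conc_ng_ml"].to_numpy(dtype=float),
            blq=sel["blq"].to_numpy(dtype=bool),
        )

    def subjects(self) -> list[int]:
        return sorted(self.records["subject_id"].unique())

    def to_csv(self, path) -> None:
        out = self.records.loc[:, list(RECORD_COLUMNS)].copy()
        out["blq"] = out["blq"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: StudyDesign | None = None) -> "CocktailDataset":
        rec = pd.read_csv(path)
        rec["blq"] = rec["blq"].astype(bool)
        if design is None:
            design = _design_from_records(rec)
        return cls(design=design, records=rec)


def _design_from_records(rec: pd.DataFrame) -> StudyDesign:
    """Reconstruct a StudyDesign from a concentration table.

    Probe links are recovered from the default probe map restricted to the
    analytes present; datasets with non-standard probes must pass an
    explicit design.
    """
    analytes = set(rec["analyte"].unique())
    probes = tuple(
        p for p in DEFAULT_PROBES if set(p.analytes) <= analytes
    )
    if not probes:
        raise ConfigurationError(
            "cannot infer probes from analytes; supply a StudyDesign explicitly"
        )
    times = tuple(int(t) for t in sorted(rec["time_min"].unique()))
    return StudyDesign(
        n_subjects=rec["subject_id"].nunique(),
        sampling_times=times,
        probes=probes,
        n_phases=rec["phase"].nunique(),
    )


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject x phase x analyte concentration-time series."""

    subject_id: int
    phase: int
    analyte: str
    times_min: np.ndarray
    conc_ng_ml: np.ndarray
    blq: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.conc_ng_ml, dtype=float)
        if t.shape != c.shape:
            raise DataValidationError("times and concentrations differ in length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise DataValidationError("profile times must be strictly increasing")
        if np.any(c < 0):
            raise DataValidationError("negative concentration in profile")


@dataclass(frozen=True)
class LSSModel:
    """A fitted limited-sampling equation: metric = A0 + sum_i Ai * C(t_i).

    For ratio probes the C(t_i) are per-time parent:metabolite
    concentration ratios and the coefficients are dimensionless; for AUC
    probes they are plasma concentrations in ng/mL and the coefficients
    carry units of hours.
    """

    probe: str
    metric_kind: str
    sampling_times: tuple[int, ...]
    intercept: float
    coefficients: tuple[float, ...]
    training_r2: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.sampling_times):
            raise ConfigurationError("one coefficient required per sampling time")
        if len(self.sampling_times) >= 2 and any(
            b <= a for a, b in zip(self.sampling_times, self.sampling_times[1:])
        ):
            raise ConfigurationError("sampling times must be strictly increasing")


@dataclass(frozen=True)
class ModelEvaluation:
    """Agreement between model-derived and best-estimate metrics.

    ``r2`` is the squared Pearson correlation between predicted and best
    estimates; MD% (signed) measures bias and MAD% (absolute) precision,
    each summarised as mean +/- sample SD over subjects.
    """

    r2: float
    md_pct_mean: float
    md_pct_sd: float
    mad_pct_mean: float
    mad_pct_sd: float
    n_subjects: int


# Validation modes
EXTERNAL = "external"
JACKKNIFE_TRAIN = "jackknife_train"
JACKKNIFE_VALID = "jackknife_valid"


@dataclass(frozen=True)
class ValidationReport:
    """Per-model validation output: summary statistics plus the paired values."""

    probe: str
    metric_kind: str
    sampling_times: tuple[int, ...]
    mode: str
    evaluation: ModelEvaluation
    per_subject: pd.DataFrame  # columns: subject_id, best, predicted
    source: str = "fitted"


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference and 1.96-SD limits of agreement for paired metrics."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_diff <= self.loa_high or math.isnan(self.mean_diff)):
            raise DataValidationError("limits of agreement must bracket the mean difference")


@dataclass(frozen=True)
class ModelSetSummary:
    """Cross-probe performance of one shared set of sampling times."""

    sampling_times: tuple[int, ...]
    per_probe_r2: Mapping[str, float]
    mean_r2: float
    sd_r2: float
    flag_ge_threshold: bool


@dataclass(frozen=True)
class PublishedModelEntry:
    """One published limited-sampling equation with its reported statistics.

    ``reported_*`` values are stored verbatim from the source table and are
    never recomputed; recomputed quantities always travel in separate,
    explicitly labelled fields/columns.
    """

    probe: str
    metric_kind: str
    sampling_times: tuple[int, ...]
    intercept: float
    coefficients: tuple[float, ...]
    source_table: str
    reported_r2: float
    reported_md_mean: float
    reported_md_sd: float
    reported_mad_mean: float
    reported_mad_sd: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.sampling_times):
            raise ConfigurationError("coefficient count must match sampling times")
        if self.source_table not in ("Table2", "Table3"):
            raise ConfigurationError(f"unknown source table {self.source_table!r}")

    def as_model(self) -> LSSModel:
        return LSSModel(
            probe=self.probe,
            metric_kind=self.metric_kind,
            sampling_times=self.sampling_times,
            intercept=self.intercept,
            coefficients=self.coefficients,
            training_r2=None,
        )


def format_times(times: Sequence[int]) -> str:
    """Serialize a time tuple as a semicolon-joined string, e.g. ``'90;240'``."""
    return ";".join(str(int(t)) for t in times)


def parse_times(text: str) -> tuple[int, ...]:
    return tuple(int(tok) for tok in str(text).split(";") if tok != "")
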