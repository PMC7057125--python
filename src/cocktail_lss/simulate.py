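"""Synthetic two-phase cocktail-study generator.

The trial being emulated sampled 16 healthy adults at 14 fixed times over
12 h in two phases 15 days apart, assaying caffeine, fexofenadine,
midazolam, metoprolol (+ alpha-OH metoprolol) and omeprazole
(+ 5-OH omeprazole).  The raw concentrations of such trials are rarely
published, so this module generates datasets with the same structure:

* parent drugs follow a one-compartment model with first-order absorption
  (the Bateman function);
* metabolites follow formation-limited one-compartment kinetics driven by
  the parent curve, with the metabolite distribution volume folded into a
  single scale constant;
* between-subject variability is lognormal around per-probe typical
  values, with phase 2 adding inter-occasion variability on the
  bioavailability scale;
* residual assay error is combined proportional + additive, truncated at
  zero, and records below the analyte's LLOQ are flagged (value retained).

Alongside the noisy dataset the generator returns the noise-free analytic
AUC(0-12h) (or parent:metabolite AUC ratio) per subject and phase, which
downstream recovery tests use as ground truth.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError
from .types import (
    AUC,
    MIN_PER_H,
    RECORD_COLUMNS,
    CocktailDataset,
    PKParameters,
    StudyDesign,
    T_END_MIN,
)

_RATE_TOL = 1e-9


def _separate_rates(ka: float, ke: float, km: float) -> tuple[float, float, float]:
    """Jitter coincident rate constants apart.

    The closed-form concentration solutions are singular when any two of
    ka, ke, km coincide; a relative nudge of 1e-9 is far below any
    physiological resolution and keeps the formulas well-conditioned.
    """
    while abs(ka - ke) / ke < _RATE_TOL:
        ke *= 1.0 + 1e-9
    if km > 0:
        while abs(km - ke) / ke < _RATE_TOL:
            km *= 1.0 + 1e-9
        while abs(km - ka) / ka < _RATE_TOL:
            km *= 1.0 + 1e-9
    return ka, ke, km


def bateman_concentration(params: PKParameters, t_min) -> np.ndarray | float:
    """Parent plasma concentration at ``t_min`` minutes post-dose.

    C(t) = S * D * ka / (Vd/F * (ka - ke)) * (exp(-ke*t) - exp(-ka*t)),
    with t in hours and S = ``bioavail_scale`` absorbing bioavailability
    and unit conversion.  Continuous in t; C(0) = 0.
    """
    if params.ka <= 0 or params.ke <= 0:
        raise ParameterError("rate constants must be positive")
    ka, ke, _ = _separate_rates(params.ka, params.ke, 0.0)
    t_h = np.asarray(t_min, dtype=float) / MIN_PER_H
    if np.any(t_h < 0):
        raise ParameterError("time must be non-negative")
    amp = params.bioavail_scale * params.dose * ka / (params.vd_f * (ka - ke))
    out = amp * (np.exp(-ke * t_h) - np.exp(-ka * t_h))
    return float(out) if np.isscalar(t_min) else out


def metabolite_concentration(params: PKParameters, t_min) -> np.ndarray | float:
    """Metabolite plasma concentration at ``t_min`` minutes post-dose.

    Solves dCm/dt = fm * ke * Cp(t) * (Vp/Vm) - km * Cm with Cm(0) = 0,
    the parent:metabolite volume ratio folded into the single constant
    ``metab_scale``:

        Cm(t) = metab_scale * fm * ke * A * [ (e^{-ke t} - e^{-km t}) / (km - ke)
                                            - (e^{-ka t} - e^{-km t}) / (km - ka) ]

    where A is the Bateman amplitude.  Callers must avoid km == ka or
    km == ke (a tiny jitter is applied automatically).
    """
    if params.km <= 0:
        raise ParameterError("metabolite requires km > 0")
    ka, ke, km = _separate_rates(params.ka, params.ke, params.km)
    t_h = np.asarray(t_min, dtype=float) / MIN_PER_H
    if np.any(t_h < 0):
        raise ParameterError("time must be non-negative")
    amp = params.bioavail_scale * params.dose * ka / (params.vd_f * (ka - ke))
    term_e = (np.exp(-ke * t_h) - np.exp(-km * t_h)) / (km - ke)
    term_a = (np.exp(-ka * t_h) - np.exp(-km * t_h)) / (km - ka)
    out = params.metab_scale * params.fm * ke * amp * (term_e - term_a)
    return float(out) if np.isscalar(t_min) else out


def _expdecay_auc(rate: float, t_h: float) -> float:
    return (1.0 - math.exp(-rate * t_h)) / rate


def parent_auc(params: PKParameters, t_end_min: float = T_END_MIN) -> float:
    """Closed-form AUC(0, t_end) of the parent curve, ng*h/mL."""
    ka, ke, _ = _separate_rates(params.ka, params.ke, 0.0)
    t_h = t_end_min / MIN_PER_H
    amp = params.bioavail_scale * params.dose * ka / (params.vd_f * (ka - ke))
    return amp * (_expdecay_auc(ke, t_h) - _expdecay_auc(ka, t_h))


def metabolite_auc(params: PKParameters, t_end_min: float = T_END_MIN) -> float:
    """Closed-form AUC(0, t_end) of the metabolite curve, ng*h/mL."""
    ka, ke, km = _separate_rates(params.ka, params.ke, params.km)
    t_h = t_end_min / MIN_PER_H
    amp = params.bioavail_scale * params.dose * ka / (params.vd_f * (ka - ke))
    f_ke, f_ka, f_km = (_expdecay_auc(r, t_h) for r in (ke, ka, km))
    return (
        params.metab_scale
        * params.fm
        * ke
        * amp
        * ((f_ke - f_km) / (km - ke) - (f_ka - f_km) / (km - ka))
    )


@dataclass(frozen=True)
class ErrorModel:
    """Residual assay error: combined proportional + additive, truncated at 0.

    ``additive_sd_lloq_frac`` expresses the additive SD as a fraction of
    the analyte's LLOQ, the usual magnitude of noise near the assay floor.
    ``iov_cv`` is the inter-occasion (phase-to-phase) lognormal CV applied
    to the bioavailability scale in phase 2 and beyond.
    """

    proportional_cv: float = 0.10
    additive_sd_lloq_frac: float = 0.5
    iov_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd_lloq_frac < 0 or self.iov_cv < 0:
            raise ParameterError("error-model CVs must be non-negative")


@dataclass(frozen=True)
class ProbePopulation:
    """Typical kinetic values and between-subject lognormal CVs for one probe."""

    typical: PKParameters
    bsv_cv: Mapping[str, float] = field(default_factory=dict)  # keys: bioavail_scale, ka, ke, km, fm
    lloq: Mapping[str, float] = field(default_factory=dict)  # analyte -> ng/mL

    def __post_init__(self) -> None:
        for name, cv in self.bsv_cv.items():
            if cv < 0:
                raise ParameterError(f"negative BSV CV for {name!r}")


@dataclass(frozen=True)
class Population:
    """Per-probe population models plus the shared residual-error model."""

    probes: Mapping[str, ProbePopulation]
    error_model: ErrorModel = field(default_factory=ErrorModel)

    def lloq_table(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for pop in self.probes.values():
            out.update(pop.lloq)
        return out

    def pure_scaling(self) -> "Population":
        """Variant with BSV only on ``bioavail_scale`` and zero noise.

        Every subject's profile is then a scalar multiple of the typical
        shape — the degenerate cohort used by proportionality tests.
        """
        probes = {
            name: replace(
                pop,
                bsv_cv={"bioavail_scale": pop.bsv_cv.get("bioavail_scale", 0.3)},
            )
            for name, pop in self.probes.items()
        }
        return Population(
            probes=probes,
            error_model=ErrorModel(proportional_cv=0.0, additive_sd_lloq_frac=0.0, iov_cv=0.0),
        )

    def noise_free(self) -> "Population":
        return Population(
            probes=dict(self.probes),
            error_model=ErrorModel(proportional_cv=0.0, additive_sd_lloq_frac=0.0, iov_cv=0.0),
        )


def load_population(path=None) -> Population:
    """Load a population configuration; defaults to the packaged calibration.

    The packaged file was calibrated once so that simulated cohort medians
    bracket the published typical AUC(0-12h) values for each probe.
    """
    if path is None:
        ref = importlib.resources.files("cocktail_lss").joinpath("data/default_population.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if "probes" not in raw:
        raise ConfigurationError("population file lacks a 'probes' section")
    probes: dict[str, ProbePopulation] = {}
    for name, cfg in raw["probes"].items():
        typ = cfg["typical"]
        params = PKParameters(
            dose=float(cfg["dose_mg"]),
            bioavail_scale=float(typ["bioavail_scale"]),
            ka=float(typ["ka_per_h"]),
            ke=float(typ["ke_per_h"]),
            vd_f=float(typ["vd_f_l"]),
            fm=float(typ.get("fm", 0.0)),
            km=float(typ.get("km_per_h", 0.0)),
            metab_scale=float(typ.get("metab_scale", 1.0)),
        )
        probes[name] = ProbePopulation(
            typical=params,
            bsv_cv={k: float(v) for k, v in cfg.get("bsv_cv", {}).items()},
            lloq={k: float(v) for k, v in cfg.get("lloq_ng_ml", {}).items()},
        )
    err = raw.get("error_model", {})
    error_model = ErrorModel(
        proportional_cv=float(err.get("proportional_cv", 0.10)),
        additive_sd_lloq_frac=float(err.get("additive_sd_lloq_frac", 0.5)),
        iov_cv=float(err.get("iov_cv", 0.10)),
    )
    return Population(probes=probes, error_model=error_model)


def default_design(population: Population | None = None, n_subjects: int = 16) -> StudyDesign:
    """Study design matching the emulated trial, with LLOQs from the population."""
    population = population or load_population()
    return StudyDesign(n_subjects=n_subjects, lloq=population.lloq_table())


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal deviate with median 1 and the given CV."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


#: fm for the optional CYP2D6 poor-metabolizer subject: essentially no
#: metabolite formation, so alpha-OH metoprolol sits below LLOQ at most times.
PM_SUBJECT_FM = 0.02


@dataclass
class SimulationResult:
    dataset: CocktailDataset
    truth: pd.DataFrame  # subject_id, phase, probe, metric_kind, true_value
    parameters: pd.DataFrame  # per subject x probe sampled PKParameters


def _sample_subject_params(
    rng: np.random.Generator, pop: ProbePopulation
) -> PKParameters:
    cv = pop.bsv_cv
    t = pop.typical
    # Draw order is fixed so a given seed always yields the same cohort.
    scale = t.bioavail_scale * _lognormal_factor(rng, cv.get("bioavail_scale", 0.0))
    ka = t.ka * _lognormal_factor(rng, cv.get("ka", 0.0))
    ke = t.ke * _lognormal_factor(rng, cv.get("ke", 0.0))
    km = t.km * _lognormal_factor(rng, cv.get("km", 0.0)) if t.km > 0 else 0.0
    fm = min(t.fm * _lognormal_factor(rng, cv.get("fm", 0.0)), 0.95) if t.fm > 0 else 0.0
    return PKParameters(
        dose=t.dose,
        bioavail_scale=scale,
        ka=ka,
        ke=ke,
        vd_f=t.vd_f,
        fm=fm,
        km=km,
        metab_scale=t.metab_scale,
    )


def simulate_cohort(
    design: StudyDesign,
    population: Population,
    seed: int,
    error_model: ErrorModel | None = None,
    include_pm_subject: bool = False,
) -> SimulationResult:
    """Simulate a full two-phase cocktail study.

    Subjects' kinetic parameters are drawn lognormally around the
    population typical values; phase >= 2 re-draws residual error and
    applies inter-occasion variability to the bioavailability scale.
    When ``include_pm_subject`` is set, the last subject's metoprolol
    metabolite formation fraction is forced to :data:`PM_SUBJECT_FM`,
    mimicking a CYP2D6 poor metabolizer whose metabolite is BLQ in most
    samples.

    Returns the LLOQ-flagged dataset plus noise-free analytic ground-truth
    metrics per subject and phase.
    """
    if not design.probes:
        raise ConfigurationError("design has no probes")
    error_model = error_model or population.error_model
    for p in design.probes:
        if p.name not in population.probes:
            raise ConfigurationError(f"population lacks parameters for probe {p.name!r}")
    rng = np.random.default_rng(seed)
    times = np.asarray(design.sampling_times, dtype=float)
    lloq = dict(design.lloq) or population.lloq_table()

    rec_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    param_rows: list[dict] = []

    subjects = list(range(1, design.n_subjects + 1))
    pm_subject = subjects[-1] if include_pm_subject else None

    for subject in subjects:
        for probe in design.probes:
            pop = population.probes[probe.name]
            params = _sample_subject_params(rng, pop)
            if subject == pm_subject and probe.name == "metoprolol":
                params = replace(params, fm=PM_SUBJECT_FM)
            param_rows.append(
                {
                    "subject_id": subject,
                    "probe": probe.name,
                    **{k: getattr(params, k) for k in ("dose", "bioavail_scale", "ka", "ke", "vd_f", "fm", "km", "metab_scale")},
                }
            )
            for phase in range(1, design.n_phases + 1):
                occ = params
                if phase > 1:
                    occ = replace(
                        params,
                        bioavail_scale=params.bioavail_scale
                        * _lognormal_factor(rng, error_model.iov_cv),
                    )
                curves = {probe.parent: bateman_concentration(occ, times)}
                if probe.metabolite is not None:
                    curves[probe.metabolite] = metabolite_concentration(occ, times)
                for analyte, clean in curves.items():
                    a_lloq = lloq.get(analyte, 0.0)
                    noisy = _apply_error(rng, clean, a_lloq, error_model)
                    rec_rows.append(
                        pd.DataFrame(
                            {
                                "subject_id": subject,
                                "phase": phase,
                                "analyte": analyte,
                                "time_min": times.astype(int),
                                "conc_ng_ml": noisy,
                                "blq": False,
                            }
                        )
                    )
                # Noise-free ground truth for this occasion.
                if probe.metric_kind == AUC:
                    value = parent_auc(occ)
                else:
                    m_auc = metabolite_auc(occ)
                    value = parent_auc(occ) / m_auc if m_auc > 0 else math.inf
                truth_rows.append(
                    {
                        "subject_id": subject,
                        "phase": phase,
                        "probe": probe.name,
                        "metric_kind": probe.metric_kind,
                        "true_value": value,
                    }
                )

    records = pd.concat(rec_rows, ignore_index=True).loc[:, list(RECORD_COLUMNS)]
    dataset = CocktailDataset(
        design=design,
        records=records,
        provenance={
            "generator": "cocktail_lss.simulate",
            "seed": int(seed),
            "error_model": {
                "proportional_cv": error_model.proportional_cv,
                "additive_sd_lloq_frac": error_model.additive_sd_lloq_frac,
                "iov_cv": error_model.iov_cv,
            },
            "include_pm_subject": bool(include_pm_subject),
        },
    )
    dataset = censor_lloq(dataset, lloq)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(
        dataset=dataset, truth=truth, parameters=pd.DataFrame(param_rows)
    )


def _apply_error(
    rng: np.random.Generator, clean: np.ndarray, lloq: float, em: ErrorModel
) -> np.ndarray:
    prop = rng.normal(0.0, em.proportional_cv, size=clean.shape) if em.proportional_cv > 0 else 0.0
    add_sd = em.additive_sd_lloq_frac * lloq
    add = rng.normal(0.0, add_sd, size=clean.shape) if add_sd > 0 else 0.0
    return np.maximum(clean * (1.0 + prop) + add, 0.0)


def censor_lloq(dataset: CocktailDataset, lloq_table: Mapping[str, float]) -> CocktailDataset:
    """Flag records below their analyte's LLOQ; concentrations are retained.

    Flag-only censoring leaves the downstream policy (exclude the whole
    time point, impute, or keep) to the selection stage, which is how the
    emulated analysis handled BLQ data.
    """
    analytes = set(dataset.records["analyte"].unique())
    missing = analytes - set(lloq_table)
    if missing:
        raise ConfigurationError(f"LLOQ table lacks analytes: {sorted(missing)}")
    for a, v in lloq_table.items():
        if v < 0:
            raise ConfigurationError(f"negative LLOQ for {a!r}")
    rec = dataset.records.copy()
    thresholds = rec["analyte"].map(lloq_table).astype(float)
    rec["blq"] = rec["conc_ng_ml"].to_numpy() < thresholds.to_numpy()
    return CocktailDataset(design=dataset.design, records=rec, provenance=dict(dataset.provenance))
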