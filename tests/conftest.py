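import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cocktail_lss import (
    CocktailDataset,
    StudyDesign,
    default_design,
    load_population,
    simulate_cohort,
)
from cocktail_lss.types import RECORD_COLUMNS

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: Seed at which the packaged population was calibrated and checked.
CALIBRATION_SEED = 42


@pytest.fixture(scope="session")
def population():
    return load_population()


@pytest.fixture(scope="session")
def design(population):
    return default_design(population)


@pytest.fixture(scope="session")
def default_sim(design, population):
    """The default-calibrated two-phase cohort (moderate BSV, 10% noise)."""
    return simulate_cohort(design, population, seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def noise_free_sim(design, population):
    pop = population.noise_free()
    return simulate_cohort(design, pop, seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def pure_scaling_sim(design, population):
    """BSV only on the bioavailability scale, zero residual error."""
    pop = population.pure_scaling()
    return simulate_cohort(design, pop, seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def typical_sim(population):
    """Zero BSV, zero noise: every subject is the typical subject."""
    from dataclasses import replace

    from cocktail_lss.simulate import Population

    pop = population.noise_free()
    pop = Population(
        probes={n: replace(p, bsv_cv={}) for n, p in pop.probes.items()},
        error_model=pop.error_model,
    )
    return simulate_cohort(default_design(pop, n_subjects=4), pop, seed=CALIBRATION_SEED)


def make_constant_dataset(
    value: float = 1.0, n_subjects: int = 2, phases=(1,), design: StudyDesign | None = None
) -> CocktailDataset:
    """Toy dataset with every concentration equal to ``value``."""
    design = design or StudyDesign(n_subjects=n_subjects)
    rows = []
    for s in range(1, n_subjects + 1):
        for ph in phases:
            for a in design.analytes:
                for t in design.sampling_times:
                    rows.append((s, ph, a, t, value, 0))
    rec = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    rec["blq"] = rec["blq"].astype(bool)
    return CocktailDataset(design=design, records=rec)
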