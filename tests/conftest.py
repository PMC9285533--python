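import numpy as np
import pytest

from phenocount.model_core import ElevationScaler, ParameterSet, SurveyDataset
from phenocount.synthetic_data import SimulationDesign, simulate_counts


@pytest.fixture
def scaler():
    return ElevationScaler.from_elevations([1000.0, 1500.0, 2000.0])


@pytest.fixture
def simple_params():
    """Single-site parameter set with mild elevation and yearly effects."""
    return ParameterSet(
        site_peaks={"a": 50.0, "b": 20.0},
        peak_day=200.0,
        duration_sd=14.0,
        overdispersion=1.0,
        h1=0.03,
        Q={2004: 3.0, 2005: -3.0},
        U={2004: 0.2, 2005: -0.2},
    )


def random_small_dataset(rng: np.random.Generator) -> tuple[SurveyDataset, ParameterSet, ElevationScaler]:
    """Tiny random dataset + random valid parameters for oracle checks."""
    n_sites = int(rng.integers(2, 5))
    sites = [f"s{i}" for i in range(n_sites)]
    elevations = {s: float(rng.uniform(900, 2100)) for s in sites}
    # guard against a degenerate all-equal draw
    if len(set(elevations.values())) < 2:
        elevations[sites[0]] += 100.0
    years = list(range(2004, 2004 + int(rng.integers(2, 4))))
    records = []
    for s in sites:
        for y in years:
            for d in rng.integers(140, 280, size=int(rng.integers(3, 7))):
                records.append((s, y, int(d), int(rng.integers(0, 30))))
    scaler = ElevationScaler.from_elevations(elevations.values())

    def effects(sd):
        draws = rng.normal(0, sd, len(years))
        draws -= draws.mean()
        return dict(zip(years, draws.tolist()))

    params = ParameterSet(
        site_peaks={s: float(rng.uniform(2, 60)) for s in sites},
        peak_day=float(rng.uniform(170, 230)),
        duration_sd=float(rng.uniform(8, 25)),
        overdispersion=float(rng.uniform(0.05, 2.5)),
        h1=float(rng.normal(0, 0.02)),
        h2=float(rng.normal(0, 0.005)),
        g=float(rng.normal(0, 0.05)),
        Q=effects(4.0),
        R=effects(0.1),
        U=effects(0.3),
    )
    data = SurveyDataset.from_records(records, elevations)
    return data, params, scaler


@pytest.fixture(scope="session")
def small_survey():
    """One deterministic small simulated survey reused across fast tests."""
    design = SimulationDesign(
        seed=11, n_sites=6, years=tuple(range(2004, 2009)), miss_probability=0.0
    )
    data, truth = simulate_counts(design)
    return design, data, truth
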