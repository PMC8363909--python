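import numpy as np
import pandas as pd
import pytest

from plasmafrac import fracmetrics as fm
from plasmafrac import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_plasma():
    return sd.make_default_plasma(0)


@pytest.fixture(scope="session")
def noisefree_sec(default_plasma):
    return sd.simulate_sec(default_plasma, sd.SECColumnModel(noise_cv=0.0), seed=0)


@pytest.fixture(scope="session")
def noisefree_odg(noisefree_sec):
    extract = sd.pool_extract(noisefree_sec, [5, 6])
    return sd.simulate_odg(extract, sd.DensityGradientModel(noise_cv=0.0), seed=0)


def random_run(rng, n_fractions=8, markers=("M1", "M2"), lossless=True):
    """A hand-built random FractionationRun with known reference totals."""
    table = pd.DataFrame(
        {
            "fraction_id": np.arange(1, n_fractions + 1),
            "volume_ml": 1.0,
            "density_g_ml": np.linspace(1.02, 1.2, n_fractions),
            "particle_count": rng.uniform(10, 100, n_fractions),
            "protein_mass": rng.uniform(1, 10, n_fractions),
        }
    )
    for m in markers:
        table[m] = rng.uniform(0.1, 5, n_fractions)
    reference = {
        "particles": float(table["particle_count"].sum()),
        "protein": float(table["protein_mass"].sum()),
    }
    for m in markers:
        reference[m] = float(table[m].sum())
    if not lossless:
        reference = {k: v * 1.25 for k, v in reference.items()}
    return fm.FractionationRun(stage="SEC", reference=reference, fractions=table)


@pytest.fixture
def toy_intensity():
    """6 + 6 sample log2 matrix with NaN holes and two planted features."""
    rng = np.random.default_rng(7)
    samples = [f"A_{i}" for i in range(6)] + [f"B_{i}" for i in range(6)]
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=samples, name="group")
    values = rng.normal(25, 1.0, size=(40, 12))
    values[0, :6] += 4.0   # up in A
    values[1, 6:] += 4.0   # up in B
    matrix = pd.DataFrame(values, index=[f"F{i:02d}" for i in range(40)], columns=samples)
    matrix.iloc[5, [0, 1, 2, 3]] = np.nan       # 2/6 valid in A, 6/6 in B
    matrix.iloc[6, [0, 1, 2, 6, 7, 8]] = np.nan  # 3/6 in both groups
    return matrix, groups
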