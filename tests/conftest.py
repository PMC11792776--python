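import numpy as np
import pandas as pd
import pytest

from nksynergy.study_data import DonorGroup, FoldExpansionTable
from nksynergy.synthetic_data import SyntheticSpec, generate_dataset, synthetic_condition_registry


@pytest.fixture(scope="session")
def registry12():
    """The 12 modeled conditions of the synthetic study."""
    return [c for c in synthetic_condition_registry() if c.condition_id <= 12]


@pytest.fixture(scope="session")
def default_table():
    """A seeded synthetic dataset at the default (heterogeneous) settings."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def mild_table():
    """Synthetic data in the identifiable regime (mild noise/heterogeneity)."""
    return generate_dataset(SyntheticSpec(seed=0, noise_scale=0.03, donor_log_scale_sd=0.1))


def make_paired_table(values: dict[int, dict[int, dict[int, float]]], conditions=(1, 3)) -> FoldExpansionTable:
    """Build a one-group table from {donor: {condition: {day: value}}}."""
    rows = [
        (donor, cond, day, v)
        for donor, conds in values.items()
        for cond, days in conds.items()
        for day, v in days.items()
    ]
    df = pd.DataFrame(rows, columns=["donor_id", "condition_id", "day", "fold_expansion"])
    groups = (DonorGroup("A", tuple(sorted(values)), tuple(conditions)),)
    return FoldExpansionTable(df, groups)


def random_paired_table(rng: np.random.Generator, n_donors: int, conditions=(1, 3), shift: float = 0.0) -> FoldExpansionTable:
    """Null-ish paired data: both conditions share a donor-level growth law.

    ``shift`` multiplies the trajectory of the second listed condition.
    """
    values = {}
    for d in range(1, n_donors + 1):
        base = float(np.exp(rng.normal(2.3, 0.4)))  # day-9 level ~ 10-fold
        values[d] = {}
        for j, cond in enumerate(conditions):
            level = base * (1.0 + shift if j == 1 else 1.0)
            traj = {}
            for day, frac in ((2, 0.15), (4, 0.4), (7, 0.8), (9, 1.0)):
                traj[day] = max(level**frac * float(np.exp(rng.normal(0, 0.1))), 1e-3)
            values[d][cond] = traj
    return make_paired_table(values, conditions)
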