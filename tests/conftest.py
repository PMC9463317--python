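import numpy as np
import pandas as pd
import pytest

from selgen.simulate import GeneratorConfig, generate_cohort


def clean_config(**overrides) -> GeneratorConfig:
    """A generator config with every confounding channel switched off.

    Single birth year, no subgroup multipliers, no ascertainment, no
    score-linked parental fertility, no heritable fertility noise — so the
    score-fertility coupling is exactly the configured gamma.
    """
    base = dict(
        n=10_000,
        n_scores=1,
        score_hc_corr=(0.0,),
        gamma=(-0.05,),
        subgroup_multipliers={},
        mediation_frac=0.0,
        ascertainment_strength=0.0,
        parent_gamma_scale=0.0,
        fertility_heritability=0.0,
        income_hc_weight=0.0,
        birth_year_range=(1950, 1950),
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small default-mechanism cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n=6_000, n_scores=4, seed=123))


@pytest.fixture()
def single_year_table():
    """Hand-built one-cohort-year table factory for identity checks."""

    def _make(z, n_children, **extra):
        z = np.asarray(z, dtype=float)
        n = len(z)
        tab = pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
                "birth_year": 1950,
                "n_children": np.asarray(n_children),
                "n_siblings": 1,
                "income_band": 1,
                "edu_age_band": 1,
                "aflb": np.nan,
                "n_sex_partners": 2,
                "lives_with_partner": 1,
                "risk_attitude": 0,
                "weight": 1.0,
                "pgs_1": z,
            }
        )
        for key, val in extra.items():
            tab[key] = val
        return tab

    return _make
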