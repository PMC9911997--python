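import numpy as np
import pytest

from colrpph import (
    ContinuousOutcomeLogisticRegression,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study design (677/409/223 subjects)."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def fitted_default(default_cohort):
    """The transformation model fitted to the default synthetic cohort."""
    est = ContinuousOutcomeLogisticRegression()
    est.fit(default_cohort.covariate_matrix(), default_cohort.mbl)
    return est


@pytest.fixture
def toy_csv(tmp_path):
    """Write a small cohort CSV and return its path."""

    def _write(text, name="cohort.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


HEADER = (
    "mbl,delivery_mode,platelets_pre,hemoglobin_pre,fibrinogen_pre,"
    "fii_pre,fxiii_pre,platelets_post,fxiii_post\n"
)


@pytest.fixture
def header():
    return HEADER


def make_rows(n, seed=0, mode="vaginal"):
    """Plain numeric rows for CSV fixtures."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        rows.append(
            f"{rng.uniform(150, 900):.1f},{mode},{rng.uniform(100, 300):.0f},"
            f"{rng.uniform(110, 140):.0f},{rng.uniform(3, 6):.1f},"
            f"{rng.uniform(100, 160):.0f},{rng.uniform(60, 140):.0f},"
            f"{rng.uniform(100, 300):.0f},{rng.uniform(50, 120):.0f}"
        )
    return "\n".join(rows) + "\n"
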