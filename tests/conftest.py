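import numpy as np
import pandas as pd
import pytest

from lncsponge.simulate import CohortConfig, generate_cohort
from lncsponge.types import ClinicalTable, ExpressionMatrix


def small_cohort_config(seed: int = 1, **overrides) -> CohortConfig:
    """A fast cohort for structural tests: 10 pairs, ~300 genes."""
    base = dict(
        n_pairs=10, n_mrna=150, n_lncrna=90, n_mirna=60,
        n_modules=2, module_size=30, n_triplets=12, n_candidates=3,
        mirnas_per_candidate=2, frac_de=0.2, seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (50 pairs, 2000/500/150 genes), seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture()
def toy_expr():
    """4 genes x 6 samples with hand-checkable values."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.uniform(1, 10, size=(4, 6)),
        index=["G1", "G2", "G3", "G4"],
        columns=[f"S{i}" for i in range(6)],
    )
    return ExpressionMatrix(data, role="mRNA", unit="log2CPM")


def paired_clinical(n_pairs: int) -> ClinicalTable:
    patients = [f"P{i}" for i in range(n_pairs)]
    return ClinicalTable(pd.DataFrame(
        {
            "sample_id": [f"{p}-T" for p in patients] + [f"{p}-N" for p in patients],
            "patient_id": patients * 2,
            "condition": ["tumor"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": patients * 2,
            "tnm_stage": ["I"] * n_pairs + [None] * n_pairs,
            "survival_time": [np.nan] * 2 * n_pairs,
            "event": [np.nan] * 2 * n_pairs,
        }
    ))
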