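import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from smacsf import CohortDesign, generate_cohort
from smacsf.rf import RFConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def null_design(seed: int, n_proteins: int = 300, n_per_subtype=(20, 20, 20), **kw) -> CohortDesign:
    """A cohort with no planted structure at all: pure Gaussian noise around
    per-protein baselines plus per-sample shifts."""
    base = dict(
        n_per_subtype=n_per_subtype,
        n_proteins=n_proteins,
        n_baseline_markers=0,
        baseline_effect=0.0,
        age_effect_proteins=0,
        age_slope=0.0,
        treatment_shared_size=0,
        treatment_subtype_size=0,
        responder_set_size=0,
        responder_extra_effect=0.0,
        missing_rate=0.0,
        seed=seed,
    )
    base.update(kw)
    return CohortDesign(**base)


def strong_design(seed: int = 1, **kw) -> CohortDesign:
    """Three classes with strong planted separation: 300 proteins, 50
    baseline markers shifted 2 log2-units between adjacent subtypes, noise
    sd 0.5, 20 patients per subtype."""
    base = dict(
        n_per_subtype=(20, 20, 20),
        n_proteins=300,
        n_baseline_markers=50,
        baseline_effect=2.0,
        noise_sd=0.5,
        missing_rate=0.0,
        age_effect_proteins=0,
        age_slope=0.0,
        treatment_shared_size=0,
        treatment_subtype_size=0,
        responder_set_size=0,
        seed=seed,
    )
    base.update(kw)
    return CohortDesign(**base)


def small_rf_config(**kw) -> RFConfig:
    base = dict(n_trees=200, seeds=tuple(range(1, 11)))
    base.update(kw)
    return RFConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with every kind of planted structure."""
    design = CohortDesign(
        n_per_subtype=(10, 10, 10),
        n_proteins=200,
        n_baseline_markers=5,
        baseline_effect=2.0,
        treatment_shared_size=8,
        treatment_subtype_size=8,
        responder_set_size=8,
        noise_sd=0.5,
        missing_rate=0.05,
        seed=11,
    )
    matrix, meta, truth = generate_cohort(design)
    return design, matrix, meta, truth


@pytest.fixture()
def toy_metadata():
    rows = []
    for k, (subtype, n) in enumerate(zip(("SMA1", "SMA2", "SMA3"), (19, 19, 23))):
        for j in range(n):
            pid = f"{subtype}_{j:02d}"
            for tp in ("T0", "T302"):
                rows.append(
                    {
                        "sample_id": f"{pid}_{tp}",
                        "patient_id": pid,
                        "subtype": subtype,
                        "timepoint": tp,
                        "age_years": 2.0 + 5 * k + 0.1 * j,
                        "sex": "F" if j % 2 else "M",
                        "smn2_copies": 2 + k,
                        "bmi_group": "normal",
                        "motor_score": 10.0,
                        "responder": j % 2 == 0,
                    }
                )
    return pd.DataFrame(rows)


def rng_frame(rng: np.random.Generator, n_proteins: int, sample_ids) -> pd.DataFrame:
    """Random complete log2-scale matrix with readable IDs."""
    return pd.DataFrame(
        rng.normal(25, 1, size=(n_proteins, len(sample_ids))),
        index=[f"P{i:03d}" for i in range(n_proteins)],
        columns=list(sample_ids),
    )
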