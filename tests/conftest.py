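import numpy as np
import pandas as pd
import pytest

from mtewas.synthetic import MARKERS, SimConfig, generate_cohort


def auto_covariates(pheno: pd.DataFrame) -> list[str]:
    """The pipeline's default covariate list (one cell type dropped as reference)."""
    return (
        ["age"]
        + [c for c in pheno.columns if c.startswith("covariate_")]
        + [c for c in pheno.columns if c.startswith("celltype_") and c != "celltype_gran"]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-platform cohort with planted effects, reused across tests."""
    cfg = SimConfig(
        n_samples_per_platform=150,
        n_cpgs_platform1=120,
        n_cpgs_platform2=130,
        n_cpgs_shared=100,
        n_chips=8,
        effect_classes={"null": 0.9, "shared": 0.05, "single_il6": 0.05},
        effect_size_scale=0.2,
        seed=101,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A single-platform null-only cohort for calibration checks."""
    cfg = SimConfig(
        n_samples_per_platform=300,
        n_cpgs_platform1=1000,
        n_cpgs_platform2=50,
        n_cpgs_shared=50,
        effect_classes={"null": 1.0},
        seed=77,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_pheno():
    rng = np.random.default_rng(5)
    n = 30
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "il6": rng.lognormal(0.7, 0.6, n),
            "scd14": rng.lognormal(0.5, 0.3, n),
            "ddimer": rng.lognormal(-1.2, 0.7, n),
            "age": rng.normal(51, 8, n),
            "chip_id": [f"c{i % 3}" for i in range(n)],
        }
    )


MARKER_LIST = list(MARKERS)
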