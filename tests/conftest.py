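import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grspipe.cohort_io import Cohort, GenotypeMatrix
from grspipe.panel import SnpPanel, load_default_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: published effect-allele frequencies for the bundled panel, used as
#: generator targets throughout the suite
GENERAL_FREQS = [0.2945, 0.8278, 0.3136, 0.5882, 0.3558, 0.1141, 0.7364,
                 0.2938, 0.4760, 0.2905, 0.5793, 0.7037, 0.8867, 0.6406,
                 0.4462, 0.8693]
ROMA_FREQS = [0.2421, 0.8527, 0.2545, 0.6062, 0.3234, 0.0853, 0.7909,
              0.3542, 0.3745, 0.3323, 0.5888, 0.7163, 0.8929, 0.5929,
              0.4787, 0.8634]


@pytest.fixture(scope="session")
def panel() -> SnpPanel:
    return load_default_panel()


@pytest.fixture(scope="session")
def small_panel() -> SnpPanel:
    return SnpPanel.from_entries(
        [("rs1", "G1", "T", 1.40), ("rs2", "G2", "A", 1.20),
         ("rs3", "G3", "C", 1.10)]
    )


def make_cohort(dosages, panel, label="General", fg=None, sample_ids=None,
                **pheno_overrides) -> Cohort:
    """Hand-build a cohort with benign default phenotypes."""
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.shape[0]
    ids = sample_ids or [f"{label}_{i}" for i in range(n)]
    gm = GenotypeMatrix(dosages=dosages, sample_ids=ids, panel=panel)
    pheno = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "age": np.linspace(30, 60, n),
            "bmi": np.linspace(22, 32, n),
            "hdl": np.linspace(1.0, 1.8, n),
            "tg": np.linspace(0.9, 2.4, n),
            "fasting_glucose": fg if fg is not None else np.linspace(4.2, 5.4, n),
            "on_treatment": [False] * n,
            "population": label,
        }
    )
    for key, value in pheno_overrides.items():
        pheno[key] = value
    return Cohort(genotypes=gm, phenotypes=pheno, label=label)
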