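import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fingopred.simulate import SimulationSpec, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A small but fully featured two-center cohort specification."""
    return SimulationSpec(n_samples_per_cohort=(150, 50), n_snps=300, seed=17)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """(genotypes, clinical, followups) for the small specification."""
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def complete_cohort():
    """Cohort without any missingness: every patient is classifiable."""
    spec = SimulationSpec(
        n_samples_per_cohort=(120, 40),
        n_snps=200,
        missing_genotype_rate=0.0,
        clinical_missing_rate=0.0,
        seed=29,
    )
    return spec, simulate_cohort(spec)


def make_genotypes(dosage, chrom=None, pos=None, maf_ids=None):
    """Wrap a raw dosage array in a GenotypeMatrix with minimal metadata."""
    from fingopred.data import GenotypeMatrix

    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    variants = pd.DataFrame(
        {
            "id": maf_ids if maf_ids is not None else [f"s{j}" for j in range(p)],
            "chrom": chrom if chrom is not None else np.ones(p, dtype=int),
            "pos": pos if pos is not None else 1000 * (1 + np.arange(p)),
            "allele1": "A",
            "allele2": "G",
            "minor_allele": "A",
        }
    )
    samples = pd.DataFrame(
        {"id": [f"p{i}" for i in range(n)], "cohort": "A", "sex": "F"}
    )
    return GenotypeMatrix(dosage=dosage, variants=variants, samples=samples)
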