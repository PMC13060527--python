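import numpy as np
import pandas as pd
import pytest

from gxebp.harmonize import AnalysisSlice, build_slices
from gxebp.gwis import fit_variants
from gxebp.simulate import SimulationConfig, simulate_cohort


def make_slice(y, alc, covariates=None, extra=None) -> AnalysisSlice:
    """Build an analysis slice directly from arrays (for unit tests)."""
    n = len(y)
    table = pd.DataFrame({"id": [f"i{k}" for k in range(n)], "Y": y, "Alc": alc})
    covs = []
    for name, values in (extra or {}).items():
        table[name] = values
        covs.append(name)
    if covariates is not None:
        covs = covariates
    return AnalysisSlice(
        trait="SBP",
        contrast="CURDRINK",
        sex_group="combined",
        table=table,
        row_index=np.arange(n),
        covariates=covs,
    )


@pytest.fixture(scope="session")
def null_fit():
    """Summary statistics for 2,000 null variants in one simulated cohort.

    All genetic effects are zero, so interaction, 2df, and marginal
    p-values should be uniform; shared by calibration, genomic-control,
    and screening-independence checks.
    """
    cfg = SimulationConfig(
        n_individuals=1500, n_variants=2000, allele_freqs=0.3, seed=20240917
    )
    cohort = simulate_cohort(cfg)
    slices = build_slices(
        cohort, traits=["SBP"], contrasts=["CURDRINK"], sex_groups=["combined"]
    )
    stats_df, skipped = fit_variants(slices[0], cohort.genotypes, cohort.variant_meta)
    assert len(skipped) == 0
    return stats_df


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a handful of true main and interaction effects."""
    n_causal, n_null = 4, 56
    cfg = SimulationConfig(
        n_individuals=4000,
        n_variants=n_causal + n_null,
        allele_freqs=0.3,
        beta_g=[0.8] * n_causal + [0.0] * n_null,
        beta_gxalc=[1.2] * n_causal + [0.0] * n_null,
        seed=77,
    )
    return simulate_cohort(cfg)
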