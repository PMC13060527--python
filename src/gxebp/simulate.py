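"""Synthetic cohort generator for gene-alcohol interaction studies.

Generates individual-level cohorts with the statistical structure the
downstream GWIS assumes: Hardy-Weinberg genotypes with controllable
imputation (dosage) quality, sex-specific drinks-per-week mixtures,
antihypertensive-medication use driven by latent blood pressure, and
SBP/DBP generated from a linear model with genetic main effects and
gene-by-alcohol interaction effects.

All randomness flows from a single ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; draw order is fixed (sex, age, drinks-per-week,
hard genotypes, dosage noise, SBP noise, DBP noise, medication), so an
identical configuration yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_bp",
    "simulate_cohort",
    "impq_blend_weight",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _as_variant_array(value, n_variants: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_variants,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort.

    Genetic effect sizes are in mmHg per effect allele on SBP; the DBP
    linear predictor reuses the genetic and exposure terms scaled by
    ``dbp_effect_scale``.  ``generative_contrast`` names the binary
    exposure that enters the generative interaction term (the analysis
    may still evaluate all contrasts).
    """

    n_individuals: int = 1000
    n_variants: int = 10
    allele_freqs: float | list | np.ndarray = 0.3
    target_impq: float | list | np.ndarray = 1.0

    # per-variant genetic effects (scalar broadcasts to all variants)
    beta_g: float | list | np.ndarray = 0.0
    beta_gxalc: float | list | np.ndarray = 0.0

    # exposure and covariate effects (SBP scale, mmHg)
    beta_alc: float = 2.0
    beta_age: float = 0.45
    beta_age2: float = 0.0
    beta_sex: float = 4.0  # male minus female
    intercept_sbp: float = 115.0
    intercept_dbp: float = 72.0
    dbp_effect_scale: float = 0.6
    noise_sd_sbp: float = 15.0
    noise_sd_dbp: float = 10.0

    # sex-specific drinks-per-week mixture: point mass at 0 plus lognormal
    p_never_female: float = 0.40
    p_never_male: float = 0.25
    dpw_meanlog_female: float = float(np.log(4.0))
    dpw_sdlog_female: float = 0.7
    dpw_meanlog_male: float = float(np.log(7.0))
    dpw_sdlog_male: float = 0.8

    # medication: logistic on latent SBP, centred at 140 mmHg
    med_intercept: float = -1.5
    med_slope: float = 0.08
    # true (generative) BP reduction in treated individuals; larger than the
    # +15/+10 analysis adjustment, so that adjustment is a partial correction
    treatment_effect_sbp: float = 20.0
    treatment_effect_dbp: float = 12.0

    age_min: float = 35.0
    age_max: float = 75.0
    p_male: float = 0.5

    generative_contrast: str = "CURDRINK"
    seed: int = 0

    # genome layout: variants are placed far apart so they are unlinked
    variant_spacing_bp: int = 1_000_000
    n_chromosomes: int = 22

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        freqs = _as_variant_array(self.allele_freqs, self.n_variants, "allele_freqs")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ConfigurationError("allele frequencies must lie in (0, 1)")
        impq = _as_variant_array(self.target_impq, self.n_variants, "target_impq")
        if np.any(impq <= 0.0) or np.any(impq > 1.0):
            raise ConfigurationError("target_impq must lie in (0, 1]")
        for name in ("noise_sd_sbp", "noise_sd_dbp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("dpw_sdlog_female", "dpw_sdlog_male"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("p_never_female", "p_never_male"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    @property
    def allele_freq_array(self) -> np.ndarray:
        return _as_variant_array(self.allele_freqs, self.n_variants, "allele_freqs")

    @property
    def target_impq_array(self) -> np.ndarray:
        return _as_variant_array(self.target_impq, self.n_variants, "target_impq")

    @property
    def beta_g_array(self) -> np.ndarray:
        return _as_variant_array(self.beta_g, self.n_variants, "beta_g")

    @property
    def beta_gxalc_array(self) -> np.ndarray:
        return _as_variant_array(self.beta_gxalc, self.n_variants, "beta_gxalc")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("allele_freqs", "target_impq", "beta_g", "beta_gxalc"):
            v = d[key]
            if isinstance(v, np.ndarray):
                d[key] = v.tolist()
        return d


@dataclass
class SimulatedCohort:
    """Individual-level cohort: phenotype table, dosage matrix, variant meta."""

    individuals: pd.DataFrame
    genotypes: np.ndarray  # n_individuals x n_variants dosages in [0, 2]
    variant_meta: pd.DataFrame
    hard_genotypes: np.ndarray | None = None
    config: SimulationConfig | None = None

    def write(self, out_dir: str | Path) -> None:
        """Write individuals/variant-meta/dosage TSVs to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(out / "individuals.tsv", sep="\t", index=False)
        self.variant_meta.to_csv(out / "variants.tsv", sep="\t", index=False)
        dosages = pd.DataFrame(
            self.genotypes, columns=self.variant_meta["variant_id"].tolist()
        )
        dosages.insert(0, "id", self.individuals["id"].to_numpy())
        dosages.to_csv(out / "dosages.tsv", sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, in_dir: str | Path) -> "SimulatedCohort":
        src = Path(in_dir)
        individuals = pd.read_csv(src / "individuals.tsv", sep="\t")
        variant_meta = pd.read_csv(src / "variants.tsv", sep="\t")
        dosages = pd.read_csv(src / "dosages.tsv", sep="\t")
        genotypes = dosages.drop(columns=["id"]).to_numpy(dtype=float)
        return cls(individuals=individuals, genotypes=genotypes, variant_meta=variant_meta)


def impq_blend_weight(target_r2: float) -> float:
    """Convex blend weight ``w`` so that corr^2(dosage, hard genotype) = target.

    The dosage is ``w * G + (1 - w) * G'`` with ``G'`` an independent draw
    from the same Binomial(2, f) law; then corr(D, G) = w / sqrt(w^2 + (1-w)^2)
    and solving corr^2 = r2 gives w = s / (1 + s) with s = sqrt(r2 / (1 - r2)).
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ConfigurationError("target imputation quality must lie in (0, 1]")
    if target_r2 == 1.0:
        return 1.0
    s = np.sqrt(target_r2 / (1.0 - target_r2))
    return float(s / (1.0 + s))


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw Hardy-Weinberg hard genotypes and noisy dosages.

    Returns ``(dosages, hard_genotypes, variant_meta)``.  Dosage quality is
    controlled per variant: the dosage is a convex blend of the hard genotype
    with an independent Binomial(2, f) draw, with blend weight solved so that
    the squared correlation between dosage and hard genotype matches
    ``target_impq`` in expectation.  Dosages stay in [0, 2] by construction.
    """
    n, v = config.n_individuals, config.n_variants
    freqs = config.allele_freq_array
    impq = config.target_impq_array

    hard = rng.binomial(2, freqs[None, :], size=(n, v)).astype(float)
    weights = np.array([impq_blend_weight(q) for q in impq])
    # independent draw consumed even when impq == 1 keeps the stream layout
    # stable across configs that differ only in target_impq
    indep = rng.binomial(2, freqs[None, :], size=(n, v)).astype(float)
    dosages = weights[None, :] * hard + (1.0 - weights[None, :]) * indep

    chrom = (np.arange(v) % config.n_chromosomes) + 1
    pos = 1 + (np.arange(v) // config.n_chromosomes) * config.variant_spacing_bp
    variant_meta = pd.DataFrame(
        {
            "variant_id": [f"var{i + 1}" for i in range(v)],
            "chromosome": chrom,
            "position": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "frequency": dosages.mean(axis=0) / 2.0,
            "impq": impq,
        }
    )
    return dosages, hard, variant_meta


def simulate_exposure(config: SimulationConfig, individuals: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Draw drinks-per-week: sex-specific zero mass plus lognormal drinkers."""
    sex = individuals["sex"].to_numpy()
    n = len(sex)
    is_male = sex == "M"
    p_never = np.where(is_male, config.p_never_male, config.p_never_female)
    never = rng.uniform(size=n) < p_never
    meanlog = np.where(is_male, config.dpw_meanlog_male, config.dpw_meanlog_female)
    sdlog = np.where(is_male, config.dpw_sdlog_male, config.dpw_sdlog_female)
    dpw = rng.lognormal(mean=meanlog, sigma=sdlog)
    dpw[never] = 0.0
    return dpw


def _generative_alc(config: SimulationConfig, dpw: np.ndarray, sex: np.ndarray) -> np.ndarray:
    # Late import avoids a cycle: harmonize owns the contrast definitions.
    from gxebp.harmonize import classify_exposure

    alc = classify_exposure(dpw, sex, config.generative_contrast)
    return np.nan_to_num(alc, nan=0.0)


def simulate_bp(
    config: SimulationConfig,
    individuals: pd.DataFrame,
    hard_genotypes: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate observed SBP/DBP and medication status.

    Latent BP is the linear predictor (intercept, exposure, genetic main and
    interaction terms, age, age^2, sex) plus Gaussian noise; medication is a
    logistic function of latent SBP; observed BP subtracts the treatment
    effect in medicated individuals.
    """
    sex = individuals["sex"].to_numpy()
    age = individuals["age"].to_numpy()
    dpw = individuals["dpw"].to_numpy()
    alc = _generative_alc(config, dpw, sex)
    male = (sex == "M").astype(float)

    genetic = hard_genotypes @ config.beta_g_array
    interaction = (hard_genotypes @ config.beta_gxalc_array) * alc
    shared = config.beta_alc * alc + genetic + interaction
    covar = config.beta_age * age + config.beta_age2 * age**2 + config.beta_sex * male

    sbp_lat = config.intercept_sbp + shared + covar + rng.normal(0.0, config.noise_sd_sbp, len(age))
    dbp_lat = (
        config.intercept_dbp
        + config.dbp_effect_scale * (shared + covar)
        + rng.normal(0.0, config.noise_sd_dbp, len(age))
    )

    p_med = expit(config.med_intercept + config.med_slope * (sbp_lat - 140.0))
    medicated = (rng.uniform(size=len(age)) < p_med).astype(int)

    sbp_raw = sbp_lat - config.treatment_effect_sbp * medicated
    dbp_raw = dbp_lat - config.treatment_effect_dbp * medicated
    return pd.DataFrame(
        {"medicated": medicated, "sbp_raw": sbp_raw, "dbp_raw": dbp_raw}
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    sex = np.where(rng.uniform(size=n) < config.p_male, "M", "F")
    age = rng.uniform(config.age_min, config.age_max, size=n)
    individuals = pd.DataFrame(
        {"id": [f"ind{i + 1}" for i in range(n)], "sex": sex, "age": age}
    )
    individuals["dpw"] = simulate_exposure(config, individuals, rng)

    dosages, hard, variant_meta = simulate_genotypes(config, rng)
    bp = simulate_bp(config, individuals, hard, rng)
    individuals = pd.concat([individuals, bp], axis=1)

    return SimulatedCohort(
        individuals=individuals,
        genotypes=dosages,
        variant_meta=variant_meta,
        hard_genotypes=hard,
        config=config,
    )
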