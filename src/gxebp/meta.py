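"""Fixed-effects meta-analysis of per-cohort summary statistics.

Pooling follows the METAL conventions: 1df inverse-variance weighting for
the interaction and marginal effects, and inverse-covariance (multivariate)
weighting for the joint (main, interaction) pair whose pooled 2df Wald
chi-square tests both effects at once.  Cochran's Q quantifies
heterogeneity of the interaction effect across studies or populations.
Pooling runs within each population first; the cross-population
meta-analysis (CPMA) then pools the population-level records by the same
estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from gxebp.qc import harmonize_alleles, _wald_2df

__all__ = [
    "ivw_meta",
    "joint_meta_2df",
    "cochran_q",
    "meta_cohorts",
    "cross_population",
    "reporting_filter",
    "REPORTING_THRESHOLDS",
]

#: minimum pooled N for a population-specific result to be reportable
REPORTING_THRESHOLDS = {
    "AFR": 5000,
    "BRA": 5000,
    "HIS": 5000,
    "SAS": 5000,
    "EUR": 20000,
    "EAS": 20000,
    "CPMA": 20000,
}


def ivw_meta(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance-weighted fixed-effects pooling of one coefficient.

    Returns ``(beta, se, p)`` with weights 1/se^2 and a two-sided normal
    p-value.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("no studies to pool")
    if np.any(ses <= 0) or not np.all(np.isfinite(ses)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return beta, se, p


def joint_meta_2df(betas, covariances):
    """Inverse-covariance-weighted pooling of (main, interaction) vectors.

    Parameters
    ----------
    betas : array (k, 2)
    covariances : array (k, 2, 2), each positive-definite

    Returns
    -------
    (beta_pooled, cov_pooled, chi2_2df, p_2df)
    """
    B = np.asarray(betas, dtype=float).reshape(-1, 2)
    V = np.asarray(covariances, dtype=float).reshape(-1, 2, 2)
    if B.shape[0] != V.shape[0] or B.shape[0] == 0:
        raise ValueError("betas and covariances must have matching nonzero length")
    precision = np.zeros((2, 2))
    weighted = np.zeros(2)
    for b, v in zip(B, V):
        det = v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]
        if det <= 0 or v[0, 0] <= 0 or v[1, 1] <= 0:
            raise np.linalg.LinAlgError("covariance not positive-definite")
        vi = np.array([[v[1, 1], -v[0, 1]], [-v[1, 0], v[0, 0]]]) / det
        precision += vi
        weighted += vi @ b
    cov_pooled = np.linalg.inv(precision)
    beta_pooled = cov_pooled @ weighted
    chi2 = float(beta_pooled @ precision @ beta_pooled)
    p = float(stats.chi2.sf(chi2, 2))
    return beta_pooled, cov_pooled, chi2, p


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test; returns ``(Q, df, p)``.

    With fewer than two studies the test is undefined and ``(nan, 0, nan)``
    is returned.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        return float("nan"), 0, float("nan")
    w = 1.0 / ses**2
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = int(betas.size - 1)
    p = float(stats.chi2.sf(q, df))
    return q, df, p


_META_KEYS = ["variant_id", "chromosome", "position", "effect_allele", "other_allele"]


def _pool_tables(
    tables: list[pd.DataFrame],
    min_studies: int = 2,
    label: str = "",
    n_col: str = "n",
    k_col: str = "k_studies",
) -> pd.DataFrame:
    """Pool a list of aligned summary tables per variant.

    Generic engine used both for cohorts-within-population and for
    populations-within-CPMA.  Variants present in fewer than ``min_studies``
    tables are dropped.
    """
    stacked = pd.concat(tables, ignore_index=True)
    records = []
    for vid, grp in stacked.groupby("variant_id", sort=False):
        k = len(grp)
        if k < min_studies:
            continue
        bi = grp["beta_int"].to_numpy(dtype=float)
        si = grp["se_int"].to_numpy(dtype=float)
        bg = grp["beta_g"].to_numpy(dtype=float)
        sg = grp["se_g"].to_numpy(dtype=float)
        cv = grp["cov_g_int"].to_numpy(dtype=float)
        bm = grp["beta_marg"].to_numpy(dtype=float)
        sm = grp["se_marg"].to_numpy(dtype=float)
        # the joint (2df) stage propagates its own interaction component so
        # that re-pooling pooled records is exact; at cohort level the joint
        # and IVW interaction inputs coincide (same Model 1 estimate)
        bi_j = grp["beta_int_joint"].to_numpy(dtype=float) if "beta_int_joint" in grp else bi
        si_j = grp["se_int_joint"].to_numpy(dtype=float) if "se_int_joint" in grp else si

        beta_int, se_int, p_int = ivw_meta(bi, si)
        beta_marg, se_marg, p_marg = ivw_meta(bm, sm)
        covs = np.stack(
            [np.array([[g**2, c], [c, i**2]]) for g, i, c in zip(sg, si_j, cv)]
        )
        try:
            bvec, cov_pool, chi2, p_2df = joint_meta_2df(
                np.column_stack([bg, bi_j]), covs
            )
        except np.linalg.LinAlgError:
            continue
        q, qdf, p_het = cochran_q(bi, si)

        first = grp.iloc[0]
        records.append(
            {
                "variant_id": vid,
                "chromosome": first["chromosome"],
                "position": first["position"],
                "effect_allele": first["effect_allele"],
                "other_allele": first["other_allele"],
                "eaf": float(np.average(grp["eaf"], weights=grp[n_col])),
                "n_total": int(grp[n_col].sum()),
                k_col: k,
                "beta_g": float(bvec[0]),
                "se_g": float(np.sqrt(cov_pool[0, 0])),
                "beta_int": beta_int,
                "se_int": se_int,
                "p_int": p_int,
                "beta_int_joint": float(bvec[1]),
                "se_int_joint": float(np.sqrt(cov_pool[1, 1])),
                "cov_g_int": float(cov_pool[0, 1]),
                "chi2_2df": chi2,
                "p_2df": p_2df,
                "beta_marg": beta_marg,
                "se_marg": se_marg,
                "p_marg": p_marg,
                "q_het": q,
                "df_het": qdf,
                "p_het": p_het,
                "label": label,
            }
        )
    return pd.DataFrame(records)


def meta_cohorts(
    cohort_tables: list[pd.DataFrame],
    population: str = "",
    min_studies: int = 2,
    align_alleles: bool = True,
    log: list | None = None,
) -> pd.DataFrame:
    """Within-population fixed-effects meta-analysis of cohort tables.

    Effect alleles are aligned to the first cohort's orientation before
    pooling.  Variants contributed by fewer than ``min_studies`` cohorts are
    dropped, matching the reporting rule of at least two contributing
    studies per variant.
    """
    if not cohort_tables:
        raise ValueError("no cohort tables")
    if align_alleles:
        cohort_tables = harmonize_alleles(cohort_tables, log=log)
    return _pool_tables(
        cohort_tables, min_studies=min_studies, label=population,
        n_col="n", k_col="k_studies",
    )


def cross_population(
    population_tables: dict[str, pd.DataFrame], min_populations: int = 1
) -> pd.DataFrame:
    """Cross-population meta-analysis of population-level pooled records.

    Pools the population records per variant with the same estimators used
    within populations, and attaches across-population heterogeneity of the
    interaction effect (``q_het``/``p_het`` and ``k_populations``).
    """
    tables = []
    for pop, df in population_tables.items():
        if len(df) == 0:
            continue
        d = df.copy()
        d["n"] = d["n_total"]
        tables.append(d)
    if not tables:
        raise ValueError("no population tables")
    pooled = _pool_tables(
        tables, min_studies=min_populations, label="CPMA",
        n_col="n", k_col="k_populations",
    )
    return pooled


def reporting_filter(records: pd.DataFrame, thresholds: dict | None = None) -> pd.Series:
    """Boolean reportable flag per meta-analysis record.

    Population-specific records need pooled N above the population threshold
    (5,000 for AFR/BRA/HIS/SAS, 20,000 for EUR/EAS) with at least two
    contributing studies; CPMA records need N above 20,000 and at least two
    contributing populations.
    """
    thresholds = {**REPORTING_THRESHOLDS, **(thresholds or {})}
    flags = np.zeros(len(records), dtype=bool)
    labels = records["label"].to_numpy()
    n = records["n_total"].to_numpy(dtype=float)
    for i, label in enumerate(labels):
        if label not in thresholds:
            raise ValueError(f"unknown population label {label!r}")
        if label == "CPMA":
            k = records["k_populations"].iloc[i]
            flags[i] = n[i] > thresholds[label] and k >= 2
        else:
            k = records["k_studies"].iloc[i]
            flags[i] = n[i] > thresholds[label] and k >= 2
    return pd.Series(flags, index=records.index, name="reportable")
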