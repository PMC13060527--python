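"""Summary-statistics quality control and genomic control.

Variant filters: imputation quality < 0.5, and effective information
MAC x R2 < 20 in the exposed, unexposed, or total sample.  Cohort filter:
< 100 individuals, or < 50 in either exposure group.  Genomic control:
the inflation factor lambda is the median 1df Wald chi-square divided by
the chi-square(1) median 0.45494; when lambda > 1 the chi-squares are
divided by lambda (equivalently SEs are inflated by sqrt(lambda)) and the
p-values recomputed.  Lambda is estimated and applied separately to the
interaction test, the genetic main effect, and the marginal test; the 2df
joint statistic is rebuilt from the corrected components, with the
main/interaction covariance scaled by sqrt(lambda_g * lambda_int).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHI2_1DF_MEDIAN",
    "QCReport",
    "filter_variants",
    "filter_cohorts",
    "lambda_gc",
    "genomic_control",
    "harmonize_alleles",
]

#: median of the chi-square distribution with 1 df, to 5 decimals
CHI2_1DF_MEDIAN = 0.45494

MIN_IMPQ = 0.5
MIN_MAC_R2 = 20.0
MIN_COHORT_N = 100
MIN_STRATUM_N = 50


@dataclass
class QCReport:
    """Per-filter removal counts and genomic-control inflation factors."""

    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)
    lambda_int: float | None = None
    lambda_g: float | None = None
    lambda_marg: float | None = None
    cohort_verdicts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "removed": dict(self.removed),
            "lambda_int": self.lambda_int,
            "lambda_g": self.lambda_g,
            "lambda_marg": self.lambda_marg,
            "cohort_verdicts": dict(self.cohort_verdicts),
        }


def filter_variants(stats_df: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop variants failing the imputation-quality or MAC x R2 filters.

    A variant is removed if impq < 0.5 or MAC x impq < 20 in the exposed,
    unexposed, or total sample.  Removal counts are attributed to the first
    failing filter in a fixed order, so they sum to input minus output rows;
    the filters themselves are an order-independent conjunction.
    """
    required = ["impq", "mac_exposed", "mac_unexposed", "mac_total"]
    missing = [c for c in required if c not in stats_df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    impq = stats_df["impq"].to_numpy(dtype=float)
    checks = [
        ("impq_lt_0.5", impq < MIN_IMPQ),
        ("mac_r2_exposed_lt_20", stats_df["mac_exposed"].to_numpy(dtype=float) * impq < MIN_MAC_R2),
        ("mac_r2_unexposed_lt_20", stats_df["mac_unexposed"].to_numpy(dtype=float) * impq < MIN_MAC_R2),
        ("mac_r2_total_lt_20", stats_df["mac_total"].to_numpy(dtype=float) * impq < MIN_MAC_R2),
    ]
    report = QCReport(n_input=len(stats_df))
    attributed = np.zeros(len(stats_df), dtype=bool)
    drop = np.zeros(len(stats_df), dtype=bool)
    for name, mask in checks:
        newly = mask & ~attributed
        report.removed[name] = int(newly.sum())
        attributed |= mask
        drop |= mask
    out = stats_df.loc[~drop].copy()
    report.n_output = len(out)
    return out, report


def filter_cohorts(n_total: int, n_exposed: int, n_unexposed: int) -> tuple[bool, str]:
    """Cohort/slice inclusion verdict for the meta-analysis.

    Excluded if fewer than 100 individuals in total, or fewer than 50 in
    either the exposed or unexposed group.
    """
    if n_total < MIN_COHORT_N:
        return False, f"n_total={n_total}<{MIN_COHORT_N}"
    if n_exposed < MIN_STRATUM_N:
        return False, f"n_exposed={n_exposed}<{MIN_STRATUM_N}"
    if n_unexposed < MIN_STRATUM_N:
        return False, f"n_unexposed={n_unexposed}<{MIN_STRATUM_N}"
    return True, "included"


def lambda_gc(p_values) -> float:
    """Genomic-control inflation factor from 1df p-values."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values to estimate lambda from")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def _lambda_from_z2(z2: np.ndarray) -> float:
    z2 = z2[np.isfinite(z2)]
    if z2.size == 0:
        raise ValueError("no statistics to estimate lambda from")
    return float(np.median(z2) / CHI2_1DF_MEDIAN)


def genomic_control(stats_df: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Apply genomic-control correction to a summary-statistics table.

    Inflation factors are estimated for the interaction test, the genetic
    main effect, and the marginal test.  Where lambda > 1, the corresponding
    SEs are inflated by sqrt(lambda) and p-values recomputed; lambda < 1
    leaves statistics unchanged (no deflation).  The 2df joint chi-square is
    rebuilt from the corrected main/interaction estimates with covariance
    scaled by sqrt(lambda_g * lambda_int).
    """
    if len(stats_df) == 0:
        raise ValueError("empty summary statistics")
    df = stats_df.copy()

    z2_int = (df["beta_int"] / df["se_int"]) ** 2
    z2_g = (df["beta_g"] / df["se_g"]) ** 2
    z2_marg = (df["beta_marg"] / df["se_marg"]) ** 2
    lam_int = _lambda_from_z2(z2_int.to_numpy(dtype=float))
    lam_g = _lambda_from_z2(z2_g.to_numpy(dtype=float))
    lam_marg = _lambda_from_z2(z2_marg.to_numpy(dtype=float))

    c_int = max(lam_int, 1.0)
    c_g = max(lam_g, 1.0)
    c_marg = max(lam_marg, 1.0)

    df["se_int"] = df["se_int"] * np.sqrt(c_int)
    df["se_g"] = df["se_g"] * np.sqrt(c_g)
    df["se_marg"] = df["se_marg"] * np.sqrt(c_marg)
    df["cov_g_int"] = df["cov_g_int"] * np.sqrt(c_g * c_int)

    df["p_int"] = stats.chi2.sf((df["beta_int"] / df["se_int"]) ** 2, 1)
    df["p_marg"] = stats.chi2.sf((df["beta_marg"] / df["se_marg"]) ** 2, 1)

    chi2_2df = _wald_2df(
        df["beta_g"].to_numpy(dtype=float),
        df["beta_int"].to_numpy(dtype=float),
        df["se_g"].to_numpy(dtype=float),
        df["se_int"].to_numpy(dtype=float),
        df["cov_g_int"].to_numpy(dtype=float),
    )
    df["p_2df"] = stats.chi2.sf(chi2_2df, 2)

    report = QCReport(
        n_input=len(df), n_output=len(df),
        lambda_int=lam_int, lambda_g=lam_g, lambda_marg=lam_marg,
    )
    return df, report


def _wald_2df(bg, bi, se_g, se_int, cov) -> np.ndarray:
    """2df Wald chi-square from (beta_g, beta_int) and their 2x2 covariance."""
    det = se_g**2 * se_int**2 - cov**2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (bg**2 * se_int**2 - 2 * bg * bi * cov + bi**2 * se_g**2) / det
    return chi2


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonize_alleles(
    dfs: list[pd.DataFrame], log: list | None = None
) -> list[pd.DataFrame]:
    """Align effect alleles across cohort tables to the first cohort.

    On an allele swap the effect/other alleles are exchanged, effect sizes
    are negated, and the effect-allele frequency becomes 1 - EAF; the
    main/interaction covariance is unchanged (both components flip sign).
    Variants whose alleles cannot be reconciled are dropped from the
    offending cohort.  Strand-ambiguous (A/T, C/G) variants are kept but
    logged.
    """
    if not dfs:
        return dfs
    ref = dfs[0].set_index("variant_id")
    out = [dfs[0].copy()]
    if log is not None:
        for vid, ea, oa in zip(ref.index, ref["effect_allele"], ref["other_allele"]):
            if (str(ea), str(oa)) in _AMBIGUOUS:
                log.append({"variant_id": vid, "event": "strand_ambiguous"})
    for df in dfs[1:]:
        df = df.copy()
        keep = np.ones(len(df), dtype=bool)
        ea = df["effect_allele"].astype(str).to_numpy()
        oa = df["other_allele"].astype(str).to_numpy()
        vids = df["variant_id"].to_numpy()
        flip = np.zeros(len(df), dtype=bool)
        for i, vid in enumerate(vids):
            if vid not in ref.index:
                continue
            rea, roa = str(ref.at[vid, "effect_allele"]), str(ref.at[vid, "other_allele"])
            if ea[i] == rea and oa[i] == roa:
                continue
            if ea[i] == roa and oa[i] == rea:
                flip[i] = True
            else:
                keep[i] = False
                if log is not None:
                    log.append({"variant_id": vid, "event": "allele_mismatch_dropped"})
        if flip.any():
            for col in ("beta_g", "beta_int", "beta_marg"):
                df.loc[flip, col] = -df.loc[flip, col]
            df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
            df.loc[flip, ["effect_allele", "other_allele"]] = df.loc[
                flip, ["other_allele", "effect_allele"]
            ].to_numpy()
        out.append(df.loc[keep].copy())
    return out
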