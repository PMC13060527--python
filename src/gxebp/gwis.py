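"""Per-cohort, per-variant interaction regression.

Model 1 regresses the BP trait on the genotype dosage, the binary alcohol
exposure, their product, and covariates by ordinary least squares with
model-based (homoscedastic) covariance:

    E(Y) = b0 + bAlc*Alc + bG*G + bGxAlc*(G x Alc) + bC*C

and reports the genetic main effect, the interaction effect, their standard
errors and covariance, a 1df Wald test of the interaction, and a 2df Wald
chi-square of the (main, interaction) pair.  Model 2 is the marginal
(main-effect-only) GWAS regression E(Y) = b0 + bG*G + bC*C.

Fitting across many variants reuses the Frisch-Waugh-Lovell decomposition:
the fixed design (intercept, exposure, covariates) is residualized out of Y,
G, and G x Alc once per slice, after which each variant needs only a 2x2
(Model 1) or scalar (Model 2) solve.  Coefficients, standard errors, and the
covariance are exactly those of the full OLS fit; Wald p-values use the
normal/chi-square approximation, the large-sample GWAS convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from gxebp.harmonize import AnalysisSlice

__all__ = [
    "STATS_COLUMNS",
    "fit_variants",
    "fit_model1",
    "fit_model2",
    "run_cohort",
]

#: column order of the per-variant summary-statistics interchange table
STATS_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "n",
    "n_exposed",
    "n_unexposed",
    "beta_g",
    "se_g",
    "beta_int",
    "se_int",
    "cov_g_int",
    "p_int",
    "p_2df",
    "beta_marg",
    "se_marg",
    "p_marg",
    "impq",
    "mac_exposed",
    "mac_unexposed",
    "mac_total",
]

_RCOND = 1e-10


def _fixed_design(table: pd.DataFrame, covariates: list[str], with_alc: bool) -> np.ndarray:
    cols = [np.ones(len(table))]
    if with_alc:
        cols.append(table["Alc"].to_numpy(dtype=float))
    for c in covariates:
        cols.append(table[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _residualizer(F: np.ndarray):
    """Return a function projecting out the column space of F."""
    q, r = np.linalg.qr(F)
    diag = np.abs(np.diag(r))
    if diag.size and np.any(diag <= _RCOND * diag.max()):
        raise np.linalg.LinAlgError("collinear fixed covariates")

    def resid(x: np.ndarray) -> np.ndarray:
        return x - q @ (q.T @ x)

    return resid


def _align_dosages(slice_: AnalysisSlice, dosages: np.ndarray) -> np.ndarray:
    """Subset a cohort dosage matrix to slice rows unless already aligned."""
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d.reshape(-1, 1)
    n = len(slice_.table)
    idx = slice_.row_index
    if idx is not None and not (d.shape[0] == n and np.array_equal(idx, np.arange(n))):
        if idx.size and idx.max() >= d.shape[0]:
            raise ValueError("dosage matrix does not cover slice row_index")
        d = d[idx, :]
    if d.shape[0] != n:
        raise ValueError("dosage rows do not match slice table")
    return d


def fit_variants(
    slice_: AnalysisSlice,
    dosages: np.ndarray,
    variant_meta: pd.DataFrame | None = None,
    chunk_size: int = 1024,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit Model 1 and Model 2 for every variant of a slice.

    Parameters
    ----------
    slice_:
        Harmonized analysis slice; its ``row_index`` selects the rows of the
        cohort dosage matrix.
    dosages:
        Cohort-level dosage matrix (individuals x variants); a matrix already
        aligned to the slice rows is accepted when ``row_index`` is trivial.
    variant_meta:
        Optional variant metadata (variant_id, chromosome, position, alleles,
        impq) copied onto the output, indexed like the dosage columns.

    Returns
    -------
    (stats, skipped):
        ``stats`` has one row per successfully fitted variant in
        ``STATS_COLUMNS`` order (plus ``variant_index``); ``skipped`` lists
        variant indices with the reason they could not be fitted.
    """
    table = slice_.table
    d_all = _align_dosages(slice_, dosages)
    n, v = d_all.shape

    y = table["Y"].to_numpy(dtype=float)
    alc = table["Alc"].to_numpy(dtype=float)
    exposed = alc == 1.0
    n_exp = int(exposed.sum())
    n_unexp = n - n_exp

    F1 = _fixed_design(table, slice_.covariates, with_alc=True)
    F2 = _fixed_design(table, slice_.covariates, with_alc=False)
    resid1 = _residualizer(F1)
    resid2 = _residualizer(F2)
    ry1 = resid1(y)
    ry2 = resid2(y)
    ryy1 = ry1 @ ry1
    ryy2 = ry2 @ ry2
    df1 = n - (F1.shape[1] + 2)
    df2 = n - (F2.shape[1] + 1)
    if df1 <= 0:
        raise ValueError("slice too small for Model 1")

    rows: list[dict] = []
    skipped: list[tuple[int, str]] = []
    for start in range(0, v, chunk_size):
        stop = min(start + chunk_size, v)
        G = d_all[:, start:stop]
        GA = G * alc[:, None]
        RG1 = resid1(G)
        RGA = resid1(GA)
        RG2 = resid2(G)

        a11 = np.einsum("ij,ij->j", RG1, RG1)
        a12 = np.einsum("ij,ij->j", RG1, RGA)
        a22 = np.einsum("ij,ij->j", RGA, RGA)
        b1 = RG1.T @ ry1
        b2 = RGA.T @ ry1
        det = a11 * a22 - a12 * a12

        s22 = np.einsum("ij,ij->j", RG2, RG2)
        sb = RG2.T @ ry2

        mac_total = np.minimum(G, 2.0 - G).sum(axis=0)
        mac_exposed = np.minimum(G[exposed], 2.0 - G[exposed]).sum(axis=0)
        mac_unexposed = np.minimum(G[~exposed], 2.0 - G[~exposed]).sum(axis=0)
        eaf = G.mean(axis=0) / 2.0

        for j in range(stop - start):
            idx = start + j
            if G[:, j].std() < 1e-12:
                skipped.append((idx, "monomorphic_dosage"))
                continue
            if n_exp == 0 or G[exposed, j].std() < 1e-12:
                skipped.append((idx, "no_exposed_variation"))
                continue
            if n_unexp == 0 or G[~exposed, j].std() < 1e-12:
                skipped.append((idx, "no_unexposed_variation"))
                continue
            if det[j] <= _RCOND * max(a11[j] * a22[j], 1e-300):
                skipped.append((idx, "singular_design"))
                continue

            bg = (a22[j] * b1[j] - a12[j] * b2[j]) / det[j]
            bi = (a11[j] * b2[j] - a12[j] * b1[j]) / det[j]
            rss1 = ryy1 - (bg * b1[j] + bi * b2[j])
            sigma2 = max(rss1, 0.0) / df1
            inv11 = a22[j] / det[j]
            inv22 = a11[j] / det[j]
            inv12 = -a12[j] / det[j]
            se_g = np.sqrt(sigma2 * inv11)
            se_int = np.sqrt(sigma2 * inv22)
            cov_gi = sigma2 * inv12
            with np.errstate(divide="ignore", invalid="ignore"):
                p_int = stats.chi2.sf(bi**2 / (sigma2 * inv22), 1)
                chi2_2df = (a11[j] * bg**2 + 2 * a12[j] * bg * bi + a22[j] * bi**2) / sigma2
                p_2df = stats.chi2.sf(chi2_2df, 2)

                bm = sb[j] / s22[j]
                sigma2_m = max(ryy2 - bm * sb[j], 0.0) / df2
                se_m = np.sqrt(sigma2_m / s22[j])
                p_marg = stats.chi2.sf(bm**2 / (sigma2_m / s22[j]), 1)

            rows.append(
                {
                    "variant_index": idx,
                    "eaf": eaf[j],
                    "n": n,
                    "n_exposed": n_exp,
                    "n_unexposed": n_unexp,
                    "beta_g": bg,
                    "se_g": se_g,
                    "beta_int": bi,
                    "se_int": se_int,
                    "cov_g_int": cov_gi,
                    "p_int": p_int,
                    "p_2df": p_2df,
                    "beta_marg": bm,
                    "se_marg": se_m,
                    "p_marg": p_marg,
                    "mac_exposed": mac_exposed[j],
                    "mac_unexposed": mac_unexposed[j],
                    "mac_total": mac_total[j],
                }
            )

    stats_df = pd.DataFrame(rows)
    skipped_df = pd.DataFrame(skipped, columns=["variant_index", "reason"])
    stats_df = _attach_meta(stats_df, skipped_df, variant_meta, v)
    return stats_df, skipped_df


def _attach_meta(
    stats_df: pd.DataFrame,
    skipped_df: pd.DataFrame,
    variant_meta: pd.DataFrame | None,
    n_variants: int,
) -> pd.DataFrame:
    defaults = {
        "variant_id": np.array([f"var{i + 1}" for i in range(n_variants)]),
        "chromosome": np.zeros(n_variants, dtype=int),
        "position": np.zeros(n_variants, dtype=int),
        "effect_allele": np.full(n_variants, "A"),
        "other_allele": np.full(n_variants, "G"),
        "impq": np.ones(n_variants),
    }
    if variant_meta is not None:
        meta = variant_meta.reset_index(drop=True)
        for col in defaults:
            if col in meta.columns:
                defaults[col] = meta[col].to_numpy()
    if len(stats_df) == 0:
        return pd.DataFrame(columns=STATS_COLUMNS + ["variant_index"])
    pos = stats_df["variant_index"].to_numpy()
    for col, values in defaults.items():
        stats_df[col] = values[pos]
    if len(skipped_df):
        skipped_df["variant_id"] = defaults["variant_id"][skipped_df["variant_index"].to_numpy()]
    return stats_df[STATS_COLUMNS + ["variant_index"]]


def fit_model1(slice_: AnalysisSlice, dosage: np.ndarray) -> dict:
    """Fit Model 1 (and the marginal model) for a single dosage vector.

    Raises ``ValueError`` if the variant cannot be fitted (monomorphic
    dosage, no dosage variation among exposed or unexposed, singular design).
    """
    stats_df, skipped = fit_variants(slice_, np.asarray(dosage, dtype=float).reshape(-1, 1))
    if len(stats_df) == 0:
        reason = skipped["reason"].iloc[0] if len(skipped) else "unknown"
        raise ValueError(f"variant could not be fitted: {reason}")
    row = stats_df.iloc[0].to_dict()
    row.pop("variant_index", None)
    return row


def fit_model2(slice_: AnalysisSlice, dosage: np.ndarray) -> dict:
    """Fit the marginal Model 2 alone: E(Y) = b0 + bG*G + bC*C."""
    table = slice_.table
    d = _align_dosages(slice_, dosage)[:, 0]
    y = table["Y"].to_numpy(dtype=float)
    F2 = _fixed_design(table, slice_.covariates, with_alc=False)
    resid2 = _residualizer(F2)
    ry = resid2(y)
    rg = resid2(d)
    s22 = rg @ rg
    if s22 < 1e-12:
        raise ValueError("variant could not be fitted: monomorphic_dosage")
    bm = (rg @ ry) / s22
    df2 = len(y) - (F2.shape[1] + 1)
    sigma2 = max(ry @ ry - bm * (rg @ ry), 0.0) / df2
    se_m = float(np.sqrt(sigma2 / s22))
    with np.errstate(divide="ignore", invalid="ignore"):
        p_marg = float(stats.chi2.sf(bm**2 / (sigma2 / s22), 1))
    return {"beta_marg": float(bm), "se_marg": se_m, "p_marg": p_marg}


def run_cohort(
    cohort,
    slices: list[AnalysisSlice],
    out_dir: str | Path | None = None,
    cohort_name: str = "cohort",
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Fit every non-flagged slice of a cohort; optionally write TSVs.

    Returns a mapping from slice name to ``(stats, skipped)``.  Output files
    are named ``{cohort}.{trait}.{contrast}.{sexgroup}.tsv``.
    """
    from gxebp import io as gio

    results: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for sl in slices:
        if sl.flagged:
            continue
        stats_df, skipped = fit_variants(sl, cohort.genotypes, cohort.variant_meta)
        results[sl.name] = (stats_df, skipped)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            gio.write_summary_stats(
                stats_df.drop(columns=["variant_index"], errors="ignore"),
                out / f"{cohort_name}.{sl.name}.tsv",
            )
    return results
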