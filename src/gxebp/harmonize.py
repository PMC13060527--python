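"""Phenotype and exposure harmonization.

Turns raw cohort measurements into the analysis variables of the interaction
study: antihypertensive-medication adjustment (+15 mmHg SBP / +10 mmHg DBP),
pulse pressure, 6-SD winsorization, US standard-drink conversion, the four
binary alcohol-exposure contrasts, very-heavy-drinker exclusion, and the
construction of per-(trait, contrast, sex group) analysis slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "CONTRASTS",
    "SEX_GROUPS",
    "AnalysisSlice",
    "adjust_medication",
    "compute_pp",
    "winsorize",
    "standard_drinks",
    "classify_exposure",
    "exclude_very_heavy",
    "build_slices",
]

TRAITS = ("SBP", "DBP", "PP")
CONTRASTS = ("CURDRINK", "LIGHTvsNEVER", "HEAVYvsNEVER", "HEAVYvsLIGHT")
SEX_GROUPS = ("combined", "M", "F")

#: mmHg added to observed BP of treated individuals to approximate the
#: untreated value (systolic, diastolic)
MEDICATION_OFFSET_SBP = 15.0
MEDICATION_OFFSET_DBP = 10.0

#: one US standard drink in grams of pure ethanol
GRAMS_PER_STANDARD_DRINK = 14.0
#: ethanol density in g/ml (in 100 ml of solution at 20 degrees C)
ETHANOL_DENSITY_G_PER_ML = 0.78945
ML_PER_FL_OZ = 29.5735

#: weekly drinks defining heavy consumption (risky use), by sex
HEAVY_DPW_FEMALE = 7.0
HEAVY_DPW_MALE = 14.0
#: below this weekly intake an individual counts as a never drinker
NEVER_DPW = 1.0


def adjust_medication(sbp_raw, dbp_raw, medicated):
    """Add +15 mmHg SBP / +10 mmHg DBP to treated individuals.

    Missing BP values propagate as missing.
    """
    sbp_raw = np.asarray(sbp_raw, dtype=float)
    dbp_raw = np.asarray(dbp_raw, dtype=float)
    med = np.asarray(medicated, dtype=float)
    return sbp_raw + MEDICATION_OFFSET_SBP * med, dbp_raw + MEDICATION_OFFSET_DBP * med


def compute_pp(sbp_adj, dbp_adj):
    """Pulse pressure, computed after the medication adjustment."""
    return np.asarray(sbp_adj, dtype=float) - np.asarray(dbp_adj, dtype=float)


def winsorize(values, k: float = 6.0) -> np.ndarray:
    """Cap values beyond mean +/- k*SD at exactly that bound.

    Mean and SD (ddof=1) are estimated from the input values themselves,
    ignoring missing entries.  Zero variance returns the input unchanged.
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.sum() < 2:
        return x
    mean = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0.0:
        return x
    lo, hi = mean - k * sd, mean + k * sd
    x[finite] = np.clip(x[finite], lo, hi)
    return x


_DRINK_MODES = ("volume_floz", "grams_country", "ml_abv")


def standard_drinks(volume, abv: float | None = None, mode: str = "ml_abv"):
    """Convert a beverage quantity to US standard drinks (14 g ethanol each).

    Parameters
    ----------
    volume:
        Beverage volume in fl oz (``mode='volume_floz'``), grams of pure
        ethanol (``mode='grams_country'``), or ml (``mode='ml_abv'``).
    abv:
        Alcohol by volume as a fraction in [0, 1]; required except in
        ``grams_country`` mode.
    mode:
        One of ``volume_floz``, ``grams_country``, ``ml_abv``.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError("volume must be non-negative")
    if mode not in _DRINK_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_DRINK_MODES}")
    if mode == "grams_country":
        out = volume / GRAMS_PER_STANDARD_DRINK
        return float(out) if out.ndim == 0 else out
    if abv is None:
        raise ValueError(f"abv is required for mode {mode!r}")
    abv = float(abv)
    if not 0.0 <= abv <= 1.0:
        raise ValueError("abv must lie in [0, 1]")
    volume_ml = volume * ML_PER_FL_OZ if mode == "volume_floz" else volume
    out = volume_ml * abv * ETHANOL_DENSITY_G_PER_ML / GRAMS_PER_STANDARD_DRINK
    return float(out) if out.ndim == 0 else out


def drinking_category(dpw, sex) -> np.ndarray:
    """Label each individual never / light / heavy from weekly drinks.

    Never: <1 drink per week.  Light: 1-7 (females) or 1-14 (males),
    boundaries inclusive.  Heavy: above the light range.
    """
    dpw = np.asarray(dpw, dtype=float)
    sex = np.asarray(sex)
    if np.any(dpw < 0):
        raise ValueError("dpw must be non-negative")
    heavy_cut = np.where(sex == "M", HEAVY_DPW_MALE, HEAVY_DPW_FEMALE)
    out = np.where(dpw < NEVER_DPW, "never", np.where(dpw <= heavy_cut, "light", "heavy"))
    return out


def classify_exposure(dpw, sex, contrast: str) -> np.ndarray:
    """Binary exposure for one contrast; NaN marks excluded individuals.

    CURDRINK codes current drinkers (>=1 drink/week) as 1 and everyone else
    as 0; the remaining contrasts compare two drinking categories and exclude
    the third (e.g. heavy drinkers are absent from LIGHTvsNEVER).
    """
    cat = drinking_category(dpw, sex)
    if contrast == "CURDRINK":
        return (cat != "never").astype(float)
    if contrast == "LIGHTvsNEVER":
        one, zero = "light", "never"
    elif contrast == "HEAVYvsNEVER":
        one, zero = "heavy", "never"
    elif contrast == "HEAVYvsLIGHT":
        one, zero = "heavy", "light"
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    out = np.full(cat.shape, np.nan)
    out[cat == one] = 1.0
    out[cat == zero] = 0.0
    return out


def exclude_very_heavy(
    dpw, sex, k: float = 6.0, among_drinkers: bool = True
) -> np.ndarray:
    """Flag very heavy drinkers: dpw >= mean + k*SD, sex-specific or combined.

    Moments are estimated once, on the pre-exclusion sample; by default among
    current drinkers (dpw >= 1), since the point mass of non-drinkers at zero
    would otherwise inflate the SD and make the rule vacuous.  Returns a
    boolean keep mask.  Zero variance in a stratum yields no exclusions there.
    """
    dpw = np.asarray(dpw, dtype=float)
    sex = np.asarray(sex)
    base = dpw >= NEVER_DPW if among_drinkers else np.ones(dpw.shape, dtype=bool)
    drop = np.zeros(dpw.shape, dtype=bool)

    def _cut(mask: np.ndarray) -> float | None:
        vals = dpw[mask]
        if len(vals) < 2:
            return None
        sd = vals.std(ddof=1)
        if sd == 0.0:
            return None
        return vals.mean() + k * sd

    combined_cut = _cut(base)
    if combined_cut is not None:
        drop |= dpw >= combined_cut
    for s in np.unique(sex):
        cut = _cut(base & (sex == s))
        if cut is not None:
            drop |= (sex == s) & (dpw >= cut)
    return ~drop


@dataclass
class AnalysisSlice:
    """One (trait, contrast, sex group) analysis dataset after harmonization.

    ``table`` holds id, Y (adjusted + winsorized mmHg), Alc (0/1), and the
    covariates entering the regression (age, age2, sex_male in the combined
    group, optional PCs).  ``row_index`` maps table rows back to cohort rows
    so the dosage matrix can be subset consistently.
    """

    trait: str
    contrast: str
    sex_group: str
    table: pd.DataFrame
    row_index: np.ndarray
    covariates: list[str] = field(default_factory=list)
    flagged: bool = False
    flag_reason: str = ""

    @property
    def name(self) -> str:
        return f"{self.trait}.{self.contrast}.{self.sex_group}"

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_exposed(self) -> int:
        return int((self.table["Alc"] == 1).sum())

    @property
    def n_unexposed(self) -> int:
        return int((self.table["Alc"] == 0).sum())


def harmonize_phenotypes(
    individuals: pd.DataFrame, winsor_k: float = 6.0, very_heavy_k: float = 6.0
) -> pd.DataFrame:
    """Medication adjustment, PP, very-heavy exclusion, winsorization.

    Returns a copy of the individual table restricted to retained rows with
    adjusted/winsorized SBP, DBP, PP columns appended.  Winsorization is done
    per trait on sex-combined moments, after the very-heavy exclusion.
    """
    df = individuals.copy()
    sbp_adj, dbp_adj = adjust_medication(df["sbp_raw"], df["dbp_raw"], df["medicated"])
    df["SBP"] = sbp_adj
    df["DBP"] = dbp_adj
    df["PP"] = compute_pp(sbp_adj, dbp_adj)
    keep = exclude_very_heavy(df["dpw"], df["sex"], k=very_heavy_k)
    df = df.loc[keep].copy()
    for trait in TRAITS:
        df[trait] = winsorize(df[trait].to_numpy(), k=winsor_k)
    return df


def build_slices(
    cohort,
    winsor_k: float = 6.0,
    very_heavy_k: float = 6.0,
    traits=TRAITS,
    contrasts=CONTRASTS,
    sex_groups=SEX_GROUPS,
    pc_columns: list[str] | None = None,
) -> list[AnalysisSlice]:
    """Build every (trait, contrast, sex group) analysis slice of a cohort.

    A slice with an empty exposure arm is emitted flagged rather than
    dropped; the cohort-level QC filter consumes the flag.
    """
    harmonized = harmonize_phenotypes(
        cohort.individuals, winsor_k=winsor_k, very_heavy_k=very_heavy_k
    )
    row_positions = cohort.individuals.index.get_indexer(harmonized.index)
    pcs = pc_columns or [c for c in harmonized.columns if c.startswith("PC")]

    slices: list[AnalysisSlice] = []
    for contrast in contrasts:
        alc = classify_exposure(harmonized["dpw"], harmonized["sex"], contrast)
        for sex_group in sex_groups:
            in_group = (
                np.ones(len(harmonized), dtype=bool)
                if sex_group == "combined"
                else (harmonized["sex"] == sex_group).to_numpy()
            )
            member = in_group & np.isfinite(alc)
            sub = harmonized.loc[member]
            for trait in traits:
                covs = ["age", "age2"] + (["sex_male"] if sex_group == "combined" else []) + pcs
                table = pd.DataFrame(
                    {
                        "id": sub["id"].to_numpy(),
                        "Y": sub[trait].to_numpy(),
                        "Alc": alc[member],
                        "age": sub["age"].to_numpy(),
                        "age2": sub["age"].to_numpy() ** 2,
                    }
                )
                if sex_group == "combined":
                    table["sex_male"] = (sub["sex"] == "M").astype(float).to_numpy()
                for pc in pcs:
                    table[pc] = sub[pc].to_numpy()
                sl = AnalysisSlice(
                    trait=trait,
                    contrast=contrast,
                    sex_group=sex_group,
                    table=table,
                    row_index=row_positions[member],
                    covariates=covs,
                )
                if sl.n == 0 or sl.n_exposed == 0 or sl.n_unexposed == 0:
                    sl.flagged = True
                    sl.flag_reason = "empty_exposure_arm" if sl.n else "empty_slice"
                slices.append(sl)
    return slices
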