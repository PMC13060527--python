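"""Tiered discovery framework for interaction loci.

Four significance tiers over meta-analysed records:

* A - genome-wide significant interaction (P_int < 5e-8) with FDR < 5%;
* B - two-step screen: variants marginally associated at P < 1e-5 are
  tested for interaction at a Bonferroni level 0.05/Meff, where Meff is the
  effective number of independent tests among the filtered variants
  (simpleM-style PCA of their dosage correlation matrix);
* C - secondary interactions among genome-wide significant 2df loci at
  0.05/M_2df, where M_2df counts clumped 2df-significant loci;
* D - 2df-significant loci without interaction evidence.

Plus LD-based clumping into loci (r2 >= 0.1 with the lead, >500 kb fallback
for panel-missing variants), novelty classification against a known-loci
catalog, sex and population heterogeneity screens, decomposition of the
genetic effect into unexposed (b0) and exposed (b1 = b0 + interaction)
strata, and a one-sided exact binomial enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Locus",
    "LDPanel",
    "bh_fdr",
    "meff_pca",
    "clump_loci",
    "classify_novelty",
    "sex_het_test",
    "decompose_effects",
    "enrichment_test",
    "approach_a",
    "approach_b",
    "approach_c",
    "approach_d",
    "GENOME_WIDE_P",
    "MARGINAL_SCREEN_P",
]

GENOME_WIDE_P = 5e-8
MARGINAL_SCREEN_P = 1e-5
LOCUS_DISTANCE_BP = 500_000
LOCUS_R2 = 0.1


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


class LDPanel:
    """Pairwise r-squared lookups from a reference dosage panel.

    Wraps a dosage matrix (individuals x variants); ``r2`` returns the
    squared Pearson correlation between two variants' dosages, or ``nan``
    if either variant is absent from the panel.
    """

    def __init__(self, dosages: np.ndarray, variant_ids) -> None:
        self.dosages = np.asarray(dosages, dtype=float)
        self.index = {vid: i for i, vid in enumerate(variant_ids)}

    def __contains__(self, variant_id) -> bool:
        return variant_id in self.index

    def r2(self, a, b) -> float:
        ia = self.index.get(a)
        ib = self.index.get(b)
        if ia is None or ib is None:
            return float("nan")
        x = self.dosages[:, ia]
        y = self.dosages[:, ib]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            return float("nan")
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)

    def submatrix(self, variant_ids) -> np.ndarray:
        cols = [self.index[v] for v in variant_ids if v in self.index]
        return self.dosages[:, cols]


def meff_pca(dosages: np.ndarray, var_explained: float = 0.995) -> int:
    """Effective number of independent tests (simpleM convention).

    Eigen-decomposes the correlation matrix of the variants' dosages and
    returns the smallest number of leading eigenvalues whose sum reaches
    ``var_explained`` of the total variance.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] == 0:
        return 0
    m = d.shape[1]
    if m == 1:
        return 1
    sd = d.std(axis=0)
    if np.any(sd == 0):
        keep = sd > 0
        d = d[:, keep]
        m_zero = int((~keep).sum())
        if d.shape[1] == 0:
            return 0
    else:
        m_zero = 0
    corr = np.corrcoef(d, rowvar=False)
    corr = np.atleast_2d(corr)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    cum = np.cumsum(eigvals) / total
    meff = int(np.searchsorted(cum, var_explained - 1e-12) + 1)
    return meff + m_zero


@dataclass
class Locus:
    """A clumped locus: lead variant plus correlated/nearby members."""

    lead: str
    members: list = field(default_factory=list)
    chromosome: int = 0
    span: tuple = (0, 0)
    lead_p: float = float("nan")
    tiers: list = field(default_factory=list)
    novel: bool | None = None
    context: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lead": self.lead,
            "members": list(self.members),
            "chromosome": int(self.chromosome),
            "span": [int(self.span[0]), int(self.span[1])],
            "lead_p": self.lead_p,
            "tiers": list(self.tiers),
            "novel": self.novel,
            "context": dict(self.context),
        }


def _sort_for_clumping(records: pd.DataFrame, p_col: str) -> pd.DataFrame:
    cols = {"p": records[p_col], "pos": records["position"]}
    if "effect_allele" in records.columns:
        cols["ea"] = records["effect_allele"].astype(str)
    else:
        cols["ea"] = ""
    order = pd.DataFrame(cols, index=records.index).sort_values(
        ["p", "pos", "ea"], kind="mergesort"
    )
    return records.loc[order.index]


def clump_loci(
    records: pd.DataFrame,
    panel: LDPanel | None,
    p_col: str = "p_int",
    r2_threshold: float = LOCUS_R2,
    distance_bp: int = LOCUS_DISTANCE_BP,
) -> list[Locus]:
    """Greedy LD clumping of significant variants into loci.

    Variants are visited in order of ascending p-value (ties broken by
    position, then effect allele); each unclaimed variant joins the first
    existing locus whose lead it is correlated with (r2 >= 0.1), otherwise a
    variant with no usable r2 joins a locus whose lead lies within 500 kb on
    the same chromosome, otherwise it founds a new locus.
    """
    loci: list[Locus] = []
    if len(records) == 0:
        return loci
    ordered = _sort_for_clumping(records, p_col)
    for _, row in ordered.iterrows():
        vid = row["variant_id"]
        chrom = row["chromosome"]
        pos = int(row["position"])
        assigned = False
        for locus in loci:
            r2 = panel.r2(vid, locus.lead) if panel is not None else float("nan")
            if np.isfinite(r2):
                if r2 >= r2_threshold:
                    locus.members.append(vid)
                    locus.span = (min(locus.span[0], pos), max(locus.span[1], pos))
                    assigned = True
                    break
            else:
                lead_pos = locus.context["lead_pos"]
                if locus.chromosome == chrom and abs(pos - lead_pos) <= distance_bp:
                    locus.members.append(vid)
                    locus.span = (min(locus.span[0], pos), max(locus.span[1], pos))
                    assigned = True
                    break
        if not assigned:
            loci.append(
                Locus(
                    lead=vid,
                    members=[vid],
                    chromosome=int(chrom),
                    span=(pos, pos),
                    lead_p=float(row[p_col]),
                    context={"lead_pos": pos, "lead_row": row.to_dict()},
                )
            )
    return loci


def classify_novelty(
    loci: list[Locus],
    known: pd.DataFrame,
    panel: LDPanel | None = None,
    positions: dict | None = None,
    distance_bp: int = LOCUS_DISTANCE_BP,
    r2_threshold: float = LOCUS_R2,
) -> list[Locus]:
    """Flag each locus as novel or known against a catalog of known variants.

    A locus is novel iff every member is more than 500 kb (inclusive bound:
    exactly 500 kb counts as near) from every known variant, or is in
    linkage equilibrium (r2 < 0.1) with every known variant within 500 kb.
    A member near a known variant with no available r2 renders the locus
    known.  An empty catalog marks every locus novel.
    """
    positions = positions or {}
    for locus in loci:
        if len(known) == 0:
            locus.novel = True
            continue
        novel = True
        for member in locus.members:
            mpos = positions.get(member)
            if mpos is None:
                mpos = locus.context.get("lead_pos") if member == locus.lead else None
            for _, krow in known.iterrows():
                if int(krow["chrom"]) != int(locus.chromosome):
                    continue
                if mpos is not None and abs(int(krow["pos"]) - int(mpos)) > distance_bp:
                    continue
                # member within +/-500kb of a known variant: needs r2 < 0.1
                r2 = (
                    panel.r2(member, krow.get("rsid"))
                    if panel is not None
                    else float("nan")
                )
                if not (np.isfinite(r2) and r2 < r2_threshold):
                    novel = False
                    break
            if not novel:
                break
        locus.novel = novel
    return loci


def sex_het_test(beta_m, se_m, beta_f, se_f, n_tests: int = 1):
    """Two-sample Z-test of interaction-effect heterogeneity between sexes.

    Assumes independence between male and female strata (conservative).
    Returns ``(z, p, significant)`` where significance is Bonferroni at
    0.05/n_tests.
    """
    beta_m = np.asarray(beta_m, dtype=float)
    se_m = np.asarray(se_m, dtype=float)
    beta_f = np.asarray(beta_f, dtype=float)
    se_f = np.asarray(se_f, dtype=float)
    z = (beta_m - beta_f) / np.sqrt(se_m**2 + se_f**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    sig = p < 0.05 / n_tests
    if z.ndim == 0:
        return float(z), float(p), bool(sig)
    return z, p, sig


def decompose_effects(beta_g, beta_int, se_g, se_int, cov) -> dict:
    """Stratum-specific genetic effects from main and interaction estimates.

    The unexposed effect is b0 = beta_g; the exposed effect is
    b1 = beta_g + beta_int with Var(b1) = se_g^2 + se_int^2 + 2*cov.
    ``fold`` = b1/b0 is the fold-change of the genetic effect under
    exposure (nan when b0 is numerically zero).
    """
    beta_g = float(beta_g)
    beta_int = float(beta_int)
    var_b1 = float(se_g) ** 2 + float(se_int) ** 2 + 2.0 * float(cov)
    if var_b1 < 0:
        raise ValueError("inconsistent inputs: Var(b1) < 0")
    b0 = beta_g
    b1 = beta_g + beta_int
    fold = b1 / b0 if abs(b0) >= 1e-12 else float("nan")
    return {
        "b0": b0,
        "b1": b1,
        "se_b0": float(se_g),
        "se_b1": float(np.sqrt(var_b1)),
        "fold": fold,
    }


def enrichment_test(k_hits: int, n_loci: int, p0: float = 0.05) -> float:
    """One-sided exact binomial tail P(X >= k), X ~ Binomial(n, p0).

    Evaluated through the regularized incomplete beta function, which is
    stable in the far tail.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k_hits <= n_loci:
        raise ValueError("k_hits must lie in [0, n_loci]")
    if k_hits == 0:
        return 1.0
    return float(stats.binom.sf(k_hits - 1, n_loci, p0))


def approach_a(records: pd.DataFrame, q: float = 0.05) -> pd.Series:
    """Tier A: genome-wide significant interaction with FDR < 5%.

    BH is computed within the scan (the supplied record set).
    """
    if len(records) == 0:
        return pd.Series(np.zeros(0, dtype=bool), name="tier_a")
    p = records["p_int"].to_numpy(dtype=float)
    flags = (p < GENOME_WIDE_P) & bh_fdr(p, q)
    return pd.Series(flags, index=records.index, name="tier_a")


def approach_b(
    records: pd.DataFrame,
    panel: LDPanel,
    q: float = 0.05,
    marginal_p: float = MARGINAL_SCREEN_P,
    var_explained: float = 0.995,
) -> tuple[pd.Series, int]:
    """Tier B: two-step screen through the marginal test.

    Step 1 keeps variants with marginal P < 1e-5; step 2 tests those for
    interaction at 0.05/Meff (Meff from PCA of the filtered variants'
    dosage correlation matrix in the reference panel) together with BH
    FDR < 5% among the filtered set.  Returns ``(flags, meff)``.
    """
    flags = pd.Series(np.zeros(len(records), dtype=bool), index=records.index, name="tier_b")
    if len(records) == 0:
        return flags, 0
    step1 = records["p_marg"].to_numpy(dtype=float) < marginal_p
    if not step1.any():
        return flags, 0
    filtered = records.loc[step1]
    in_panel = [v for v in filtered["variant_id"] if v in panel]
    meff = meff_pca(panel.submatrix(in_panel), var_explained) if in_panel else 0
    # variants absent from the panel count as independent tests
    meff += int(len(filtered) - len(in_panel))
    if meff == 0:
        return flags, 0
    p_int = filtered["p_int"].to_numpy(dtype=float)
    hits = (p_int < 0.05 / meff) & bh_fdr(p_int, q)
    flags.loc[filtered.index] = hits
    return flags, meff


def loci_2df(
    records: pd.DataFrame, panel: LDPanel | None, q: float = 0.05
) -> list[Locus]:
    """Clumped loci with genome-wide significant 2df joint effects."""
    if len(records) == 0:
        return []
    p = records["p_2df"].to_numpy(dtype=float)
    sig = (p < GENOME_WIDE_P) & bh_fdr(p, q)
    return clump_loci(records.loc[sig], panel, p_col="p_2df")


def approach_c(
    records: pd.DataFrame, panel: LDPanel | None, q: float = 0.05
) -> tuple[list[Locus], int]:
    """Tier C: secondary interactions among 2df-significant loci.

    M_2df is the number of clumped 2df loci in the scan; a lead qualifies if
    its interaction p-value is below 0.05/M_2df.  Returns the flagged loci
    and M_2df.
    """
    loci = loci_2df(records, panel, q)
    m_2df = len(loci)
    hits = []
    if m_2df == 0:
        return hits, 0
    by_id = records.set_index("variant_id")
    for locus in loci:
        p_int = float(by_id.at[locus.lead, "p_int"])
        if p_int < 0.05 / m_2df:
            locus.tiers.append("C")
            locus.context["p_int"] = p_int
            hits.append(locus)
    return hits, m_2df


def approach_d(
    records: pd.DataFrame,
    panel: LDPanel | None,
    q: float = 0.05,
    cutoff: str = "nominal",
) -> list[Locus]:
    """Tier D: 2df-significant loci without interaction evidence.

    ``cutoff='nominal'`` requires the lead's interaction p > 0.05;
    ``cutoff='bonferroni'`` uses p > 0.05/M_2df instead.
    """
    loci = loci_2df(records, panel, q)
    m_2df = len(loci)
    if m_2df == 0:
        return []
    threshold = 0.05 if cutoff == "nominal" else 0.05 / m_2df
    by_id = records.set_index("variant_id")
    out = []
    for locus in loci:
        p_int = float(by_id.at[locus.lead, "p_int"])
        if p_int > threshold:
            locus.tiers.append("D")
            locus.context["p_int"] = p_int
            out.append(locus)
    return out
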