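"""Discovery layer: FDR, Meff, clumping, novelty, heterogeneity, enrichment."""

import numpy as np
import pandas as pd
import pytest

from gxebp.discovery import (
    LDPanel,
    approach_a,
    approach_b,
    approach_c,
    approach_d,
    bh_fdr,
    classify_novelty,
    clump_loci,
    decompose_effects,
    enrichment_test,
    meff_pca,
    sex_het_test,
)


class TestBHFDR:
    def test_all_equal_pass_at_step_up(self):
        flags = bh_fdr([0.04, 0.04, 0.04, 0.04], q=0.05)
        assert flags.all()

    def test_single_p(self):
        assert bh_fdr([0.049], q=0.05)[0]
        assert not bh_fdr([0.051], q=0.05)[0]

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        base = bh_fdr(p)
        p2 = p.copy()
        p2[5] = p2[5] / 10
        again = bh_fdr(p2)
        assert (again | ~base).all()  # no discovery lost by lowering a p

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestMeff:
    def test_independent_variants_full_count(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(3000, 8)).astype(float)
        assert meff_pca(d) == 8

    def test_perfect_correlation_single_test(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.5, 500).astype(float)
        assert meff_pca(np.column_stack([x, x, x])) == 1

    def test_block_structure_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(3)
        n = 2000
        latent = rng.normal(size=n)
        block = np.column_stack(
            [latent + rng.normal(scale=0.22, size=n) for _ in range(10)]
        )
        indep = rng.normal(size=(n, 5))
        d = np.column_stack([block, indep])
        # oracle: explicit eigen-decomposition of the correlation matrix
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(d, rowvar=False)))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        expected = int(np.searchsorted(cum, 0.995 - 1e-12) + 1)
        assert meff_pca(d) == expected
        assert expected < 15  # the correlated block collapses


def _records(rows):
    df = pd.DataFrame(rows)
    defaults = {
        "chromosome": 1, "effect_allele": "A", "other_allele": "G",
        "p_int": 0.5, "p_2df": 0.5, "p_marg": 0.5,
        "beta_g": 0.1, "beta_int": 0.1, "se_g": 0.1, "se_int": 0.1, "cov_g_int": 0.0,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return df


def _panel_from_corr(n, specs, seed=0):
    """Panel with dosages of prescribed pairwise correlation blocks."""
    rng = np.random.default_rng(seed)
    cols, ids = [], []
    for vid, parent, rho in specs:
        if parent is None:
            x = rng.normal(size=n)
        else:
            base = cols[ids.index(parent)]
            noise = rng.normal(size=n)
            x = rho * base + np.sqrt(1 - rho**2) * noise
        cols.append(x)
        ids.append(vid)
    return LDPanel(np.column_stack(cols), ids)


class TestClumping:
    def test_correlated_pair_merges_with_smaller_p_lead(self):
        panel = _panel_from_corr(4000, [("a", None, 0), ("b", "a", 0.8)])
        rec = _records(
            [
                {"variant_id": "a", "position": 1000, "p_int": 1e-10},
                {"variant_id": "b", "position": 2000, "p_int": 1e-8},
            ]
        )
        loci = clump_loci(rec, panel)
        assert len(loci) == 1
        assert loci[0].lead == "a"
        assert set(loci[0].members) == {"a", "b"}

    def test_distant_uncorrelated_pair_stays_separate(self):
        # neither variant in the panel, 600 kb apart -> two loci
        panel = LDPanel(np.zeros((10, 0)), [])
        rec = _records(
            [
                {"variant_id": "a", "position": 1_000_000, "p_int": 1e-10},
                {"variant_id": "b", "position": 1_600_000, "p_int": 1e-9},
            ]
        )
        assert len(clump_loci(rec, panel)) == 2

    def test_panel_missing_nearby_joins_locus(self):
        panel = _panel_from_corr(4000, [("a", None, 0)])
        rec = _records(
            [
                {"variant_id": "a", "position": 1_000_000, "p_int": 1e-10},
                {"variant_id": "x", "position": 1_300_000, "p_int": 1e-9},
            ]
        )
        loci = clump_loci(rec, panel)
        assert len(loci) == 1 and set(loci[0].members) == {"a", "x"}

    def test_equal_p_tie_broken_by_position(self):
        panel = LDPanel(np.zeros((10, 0)), [])
        rec = _records(
            [
                {"variant_id": "b", "position": 5000, "p_int": 1e-9},
                {"variant_id": "a", "position": 1000, "p_int": 1e-9},
            ]
        )
        loci = clump_loci(rec, panel)
        assert loci[0].lead == "a"

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(4)
        specs = [("v0", None, 0)]
        for i in range(1, 12):
            parent = "v0" if i < 6 else None
            specs.append((f"v{i}", parent, 0.9 if parent else 0))
        panel = _panel_from_corr(3000, specs)
        rec = _records(
            [
                {"variant_id": f"v{i}", "position": 1000 + 2_000_000 * i,
                 "p_int": float(rng.uniform(1e-12, 1e-8))}
                for i in range(12)
            ]
        )
        loci = clump_loci(rec, panel)
        members = [m for l in loci for m in l.members]
        assert sorted(members) == sorted(rec["variant_id"])  # partition
        leads = rec[rec["variant_id"].isin([l.lead for l in loci])]
        again = clump_loci(leads, panel)
        assert {l.lead for l in again} == {l.lead for l in loci}


class TestNovelty:
    def _locus(self, lead="a", pos=1_000_000, chrom=1):
        from gxebp.discovery import Locus

        return Locus(lead=lead, members=[lead], chromosome=chrom, span=(pos, pos),
                     context={"lead_pos": pos})

    def test_nearby_but_uncorrelated_is_novel(self):
        panel = _panel_from_corr(4000, [("a", None, 0), ("k", None, 0)])
        known = pd.DataFrame({"chrom": [1], "pos": [1_300_000], "rsid": ["k"]})
        loci = classify_novelty([self._locus()], known, panel, {"a": 1_000_000})
        assert loci[0].novel

    def test_nearby_and_correlated_is_known(self):
        panel = _panel_from_corr(4000, [("a", None, 0), ("k", "a", 0.8)])
        known = pd.DataFrame({"chrom": [1], "pos": [1_300_000], "rsid": ["k"]})
        loci = classify_novelty([self._locus()], known, panel, {"a": 1_000_000})
        assert not loci[0].novel

    def test_exactly_500kb_without_r2_is_known(self):
        panel = LDPanel(np.zeros((10, 0)), [])
        known = pd.DataFrame({"chrom": [1], "pos": [1_500_000], "rsid": ["k"]})
        loci = classify_novelty([self._locus()], known, panel, {"a": 1_000_000})
        assert not loci[0].novel

    def test_beyond_500kb_is_novel(self):
        panel = LDPanel(np.zeros((10, 0)), [])
        known = pd.DataFrame({"chrom": [1], "pos": [1_500_001], "rsid": ["k"]})
        loci = classify_novelty([self._locus()], known, panel, {"a": 1_000_000})
        assert loci[0].novel

    def test_empty_catalog_all_novel(self):
        known = pd.DataFrame(columns=["chrom", "pos", "rsid"])
        loci = classify_novelty([self._locus()], known)
        assert loci[0].novel


class TestSexHeterogeneity:
    def test_equal_effects(self):
        z, p, sig = sex_het_test(0.5, 0.1, 0.5, 0.1)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_value(self):
        z, p, _ = sex_het_test(3.0, 1.0, 0.0, 1.0)
        assert z == pytest.approx(2.1213, abs=1e-4)
        assert p == pytest.approx(0.0339, abs=1e-4)

    def test_scale_invariance(self):
        z1, _, _ = sex_het_test(3.0, 1.0, 1.0, 2.0)
        z2, _, _ = sex_het_test(30.0, 10.0, 10.0, 20.0)
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_bonferroni_flag(self):
        _, p, sig = sex_het_test(3.0, 1.0, 0.0, 1.0, n_tests=1)
        assert sig
        _, _, sig21 = sex_het_test(3.0, 1.0, 0.0, 1.0, n_tests=21)
        assert not sig21  # 0.0339 > 0.05/21


class TestDecomposition:
    def test_sixfold_structure(self):
        out = decompose_effects(0.1, 0.5, 0.05, 0.08, 0.0)
        assert out["b0"] == pytest.approx(0.1)
        assert out["b1"] == pytest.approx(0.6)
        assert out["fold"] == pytest.approx(6.0)

    def test_no_interaction_fold_one(self):
        out = decompose_effects(0.4, 0.0, 0.05, 0.08, -0.001)
        assert out["b1"] == out["b0"] and out["fold"] == pytest.approx(1.0)

    def test_variance_formula(self):
        out = decompose_effects(0.1, 0.2, 1.0, 1.0, 0.0)
        assert out["se_b1"] == pytest.approx(np.sqrt(2.0))

    def test_zero_b0_fold_missing(self):
        assert np.isnan(decompose_effects(0.0, 0.5, 0.1, 0.1, 0.0)["fold"])

    def test_inconsistent_variance_rejected(self):
        with pytest.raises(ValueError):
            decompose_effects(0.1, 0.2, 0.1, 0.1, -1.0)


class TestEnrichment:
    def test_novel_loci_tail(self):
        p = enrichment_test(13, 36)
        assert p == pytest.approx(9.5e-9, rel=0.05)

    def test_known_loci_tail(self):
        p = enrichment_test(258, 2070)
        assert p == pytest.approx(4.7e-40, rel=0.05)

    def test_zero_hits(self):
        assert enrichment_test(0, 100) == 1.0

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            enrichment_test(1, 10, p0=1.5)


class TestApproaches:
    def test_tier_a_threshold(self):
        rec = _records(
            [
                {"variant_id": "a", "position": 1, "p_int": 4e-8},
                {"variant_id": "b", "position": 2, "p_int": 6e-8},
            ]
        )
        flags = approach_a(rec)
        assert flags.tolist() == [True, False]

    def test_tier_a_empty(self):
        assert approach_a(pd.DataFrame()).sum() == 0

    def test_two_step_uncorrelated_meff_equals_count(self):
        rng = np.random.default_rng(5)
        ids = [f"v{i}" for i in range(6)]
        panel = LDPanel(rng.binomial(2, 0.4, size=(3000, 6)).astype(float), ids)
        rec = _records(
            [
                {"variant_id": f"v{i}", "position": i + 1,
                 "p_marg": 1e-6, "p_int": 1e-4}
                for i in range(6)
            ]
        )
        flags, meff = approach_b(rec, panel)
        assert meff == 6
        # 1e-4 < 0.05/6 and FDR passes -> all hits
        assert flags.all()

    def test_power_ordering_b_detects_what_a_misses(self):
        """A marginally-screened variant with p_int between 0.05/Meff and
        5e-8 is a tier-B discovery but not tier-A."""
        rng = np.random.default_rng(6)
        ids = [f"v{i}" for i in range(4)]
        panel = LDPanel(rng.binomial(2, 0.4, size=(3000, 4)).astype(float), ids)
        rows = [{"variant_id": "v0", "position": 1, "p_marg": 1e-7, "p_int": 1e-4}]
        rows += [
            {"variant_id": f"v{i}", "position": i + 1, "p_marg": 0.5, "p_int": 0.5}
            for i in range(1, 4)
        ]
        rec = _records(rows)
        a_flags = approach_a(rec)
        b_flags, meff = approach_b(rec, panel)
        assert not a_flags.any()
        assert b_flags.tolist() == [True, False, False, False]
        assert meff == 1  # only the screened variant enters step 2

    def test_tier_c_and_d_disjoint(self):
        panel = LDPanel(np.zeros((10, 0)), [])
        rows = []
        for i in range(4):
            rows.append(
                {
                    "variant_id": f"v{i}",
                    "position": 1 + 2_000_000 * i,
                    "p_2df": 1e-10,
                    "p_int": 1e-4 if i == 0 else 0.5,
                }
            )
        rec = _records(rows)
        c_loci, m_2df = approach_c(rec, panel)
        d_loci = approach_d(rec, panel)
        assert m_2df == 4
        assert [l.lead for l in c_loci] == ["v0"]  # 1e-4 < 0.05/4
        assert {l.lead for l in d_loci} == {"v1", "v2", "v3"}
        assert not ({l.lead for l in c_loci} & {l.lead for l in d_loci})

    def test_tier_c_empty_when_no_2df_loci(self):
        rec = _records([{"variant_id": "a", "position": 1, "p_2df": 0.5}])
        c_loci, m_2df = approach_c(rec, LDPanel(np.zeros((10, 0)), []))
        assert c_loci == [] and m_2df == 0
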