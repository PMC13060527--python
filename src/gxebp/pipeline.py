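"""End-to-end pipeline orchestration with stage caching.

Stages: simulate -> harmonize -> gwis -> qc -> meta -> discover.  Each stage
writes its outputs plus a stamp file recording the configuration hash; a
stage whose stamp matches the current configuration is skipped, so deleting
one stage's outputs re-runs only that stage and those downstream.  Every
filter count and inflation factor is recorded in a JSON-lines log.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gxebp import io as gio
from gxebp.discovery import (
    LDPanel,
    approach_a,
    approach_b,
    approach_c,
    approach_d,
    classify_novelty,
    clump_loci,
    decompose_effects,
    sex_het_test,
)
from gxebp.gwis import run_cohort
from gxebp.harmonize import build_slices
from gxebp.meta import cross_population, meta_cohorts, reporting_filter
from gxebp.qc import filter_cohorts, filter_variants, genomic_control
from gxebp.simulate import SimulationConfig, SimulatedCohort, simulate_cohort

__all__ = ["run_pipeline", "discover_scan", "load_config", "default_demo_config"]

logger = logging.getLogger("gxebp")

_SIM_FIELDS = set(SimulationConfig.__dataclass_fields__)


class _JsonlLogger:
    def __init__(self, path: Path) -> None:
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self.fh = open(path, "a")

    def log(self, stage: str, **fields) -> None:
        record = {"stage": stage, **fields}
        self.fh.write(json.dumps(record, default=str) + "\n")
        self.fh.flush()
        logger.info("%s: %s", stage, fields)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_demo_config(seed: int = 1) -> dict:
    """A two-population, six-cohort demo with one exaggerated causal variant.

    The first variant carries a deliberately large main and interaction
    effect so the demo surfaces a discovery at desk-scale sample sizes;
    the remaining 1,999 variants are null.
    """
    n_variants = 2000
    return {
        "seed": seed,
        "simulation": {
            "n_variants": n_variants,
            "allele_freqs": 0.3,
            "beta_g": [2.0] + [0.0] * (n_variants - 1),
            "beta_gxalc": [6.0] + [0.0] * (n_variants - 1),
        },
        "cohorts": {
            "eur_a": {"population": "EUR", "n_individuals": 800},
            "eur_b": {"population": "EUR", "n_individuals": 800},
            "eur_c": {"population": "EUR", "n_individuals": 800},
            "eas_a": {"population": "EAS", "n_individuals": 600},
            "eas_b": {"population": "EAS", "n_individuals": 600},
            "eas_c": {"population": "EAS", "n_individuals": 600},
        },
        "analysis": {
            "traits": ["SBP"],
            "contrasts": ["CURDRINK"],
            "sex_groups": ["combined"],
        },
        "discovery": {"fdr_q": 0.05, "approach_d_cutoff": "nominal"},
        "reporting": {"thresholds": {"EUR": 1000, "EAS": 1000, "CPMA": 1000}},
    }


def _stamp_path(out: Path, stage: str) -> Path:
    return out / f".{stage}.stamp.json"


def _stage_cached(out: Path, stage: str, chash: str) -> bool:
    sp = _stamp_path(out, stage)
    if not sp.exists():
        return False
    try:
        return json.loads(sp.read_text()).get("config_hash") == chash
    except json.JSONDecodeError:
        return False


def _write_stamp(out: Path, stage: str, chash: str, seed: int) -> None:
    from gxebp import __version__

    _stamp_path(out, stage).write_text(
        json.dumps({"config_hash": chash, "seed": seed, "version": __version__})
    )


def _cohort_seed(base_seed: int, index: int) -> int:
    # distinct, reproducible, and below 2**31
    return int((base_seed * 100003 + index * 7919 + 17) % (2**31 - 1))


def _sim_config(config: dict, cohort_attrs: dict, seed: int) -> SimulationConfig:
    params = {k: v for k, v in config.get("simulation", {}).items() if k in _SIM_FIELDS}
    params.update({k: v for k, v in cohort_attrs.items() if k in _SIM_FIELDS})
    params["seed"] = seed
    return SimulationConfig(**params)


def discover_scan(
    records: pd.DataFrame,
    panel: LDPanel,
    known: pd.DataFrame,
    positions: dict,
    population: str,
    trait: str = "",
    contrast: str = "",
    sex_group: str = "",
    q: float = 0.05,
    d_cutoff: str = "nominal",
    thresholds: dict | None = None,
) -> dict:
    """Run the four-tier discovery framework on one meta-analysis scan."""
    records = records.reset_index(drop=True)
    reportable = reporting_filter(records, thresholds)
    scan = {
        "population": population,
        "trait": trait,
        "contrast": contrast,
        "sex_group": sex_group,
        "n_variants": len(records),
        "n_reportable": int(reportable.sum()),
    }
    sub = records.loc[reportable].reset_index(drop=True)
    if len(sub):
        a_flags = approach_a(sub, q)
        b_flags, meff = approach_b(sub, panel, q)
        c_loci, m_2df = approach_c(sub, panel, q)
        d_loci = approach_d(sub, panel, q, cutoff=d_cutoff)
        int_hits = sub.loc[a_flags | b_flags]
        loci_1df = clump_loci(int_hits, panel, p_col="p_int")
        for locus in loci_1df:
            row = locus.context["lead_row"]
            locus.tiers.append("A" if row["p_int"] < 5e-8 else "B")
            locus.context["decomposition"] = decompose_effects(
                row["beta_g"], row["beta_int"], row["se_g"], row["se_int"], row["cov_g_int"]
            )
        classify_novelty(loci_1df, known, panel, positions)
        classify_novelty(c_loci, known, panel, positions)
        classify_novelty(d_loci, known, panel, positions)
        scan.update(
            meff=meff,
            m_2df=m_2df,
            tier_a=int(a_flags.sum()),
            tier_b=int((b_flags & ~a_flags).sum()),
            loci_1df=[l.to_dict() for l in loci_1df],
            loci_c=[l.to_dict() for l in c_loci],
            loci_d=[l.to_dict() for l in d_loci],
        )
    return scan


def run_pipeline(config: dict, out_dir: str | Path, force: bool = False) -> dict:
    """Run simulate -> harmonize -> gwis -> qc -> meta -> discover.

    Returns the discovery report as a dict (also written to
    ``discovery/report.json`` under ``out_dir``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = gio.config_hash(config)
    stamp = gio.version_stamp(config, seed)
    jlog = _JsonlLogger(out / "log.jsonl")

    analysis = config.get("analysis", {})
    traits = analysis.get("traits", ["SBP", "DBP", "PP"])
    contrasts = analysis.get("contrasts", ["CURDRINK", "LIGHTvsNEVER", "HEAVYvsNEVER", "HEAVYvsLIGHT"])
    sex_groups = analysis.get("sex_groups", ["combined", "M", "F"])
    cohorts_cfg = config.get("cohorts", {})
    if not cohorts_cfg:
        raise ValueError("pipeline config must define at least one cohort")

    # ---- simulate ------------------------------------------------------
    sim_dir = out / "sim"
    if force or not _stage_cached(out, "simulate", chash):
        if sim_dir.exists():
            shutil.rmtree(sim_dir)
        for i, (name, attrs) in enumerate(cohorts_cfg.items()):
            cseed = _cohort_seed(seed, i)
            cohort = simulate_cohort(_sim_config(config, attrs, cseed))
            cohort.write(sim_dir / name)
            jlog.log("simulate", cohort=name, seed=cseed, n=cohort.individuals.shape[0],
                     n_variants=cohort.genotypes.shape[1])
        _write_stamp(out, "simulate", chash, seed)
    else:
        jlog.log("simulate", cached=True)

    cohorts = {name: SimulatedCohort.read(sim_dir / name) for name in cohorts_cfg}

    # ---- harmonize + gwis ---------------------------------------------
    gwis_dir = out / "gwis"
    slice_meta: dict[str, dict] = {}
    for name, cohort in cohorts.items():
        slices = build_slices(
            cohort, traits=traits, contrasts=contrasts, sex_groups=sex_groups
        )
        slice_meta[name] = {
            sl.name: {"n": sl.n, "n_exposed": sl.n_exposed, "n_unexposed": sl.n_unexposed}
            for sl in slices
        }
        if force or not _stage_cached(out, f"gwis.{name}", chash):
            results = run_cohort(cohort, slices, out_dir=gwis_dir, cohort_name=name)
            for sname, (stats_df, skipped) in results.items():
                jlog.log("gwis", cohort=name, slice=sname, fitted=len(stats_df),
                         skipped=len(skipped))
            _write_stamp(out, f"gwis.{name}", chash, seed)
        else:
            jlog.log("gwis", cohort=name, cached=True)

    # ---- qc ------------------------------------------------------------
    qc_dir = out / "qc"
    qc_reports: dict[str, dict] = {}
    for name in cohorts_cfg:
        for f in sorted(gwis_dir.glob(f"{name}.*.tsv")):
            sname = f.name[len(name) + 1 : -4]
            meta = slice_meta[name].get(sname, {})
            ok, reason = filter_cohorts(
                meta.get("n", 0), meta.get("n_exposed", 0), meta.get("n_unexposed", 0)
            )
            key = f"{name}.{sname}"
            if not ok:
                qc_reports[key] = {"included": False, "reason": reason}
                jlog.log("qc", file=key, excluded=reason)
                continue
            if force or not _stage_cached(out, f"qc.{key}", chash):
                stats_df = gio.read_summary_stats(f)
                filtered, vrep = filter_variants(stats_df)
                if len(filtered) == 0:
                    qc_reports[key] = {"included": False, "reason": "no_variants_after_filter"}
                    jlog.log("qc", file=key, excluded="no_variants_after_filter")
                    continue
                corrected, grep_ = genomic_control(filtered)
                gio.write_summary_stats(corrected, qc_dir / f.name, stamp=stamp)
                qc_reports[key] = {
                    "included": True,
                    **vrep.to_dict(),
                    "lambda_int": grep_.lambda_int,
                    "lambda_g": grep_.lambda_g,
                    "lambda_marg": grep_.lambda_marg,
                }
                jlog.log("qc", file=key, removed=vrep.removed,
                         lambda_int=grep_.lambda_int, lambda_marg=grep_.lambda_marg)
                _write_stamp(out, f"qc.{key}", chash, seed)
            else:
                stamp_file = qc_dir / f.name
                qc_reports[key] = {"included": stamp_file.exists()}
                jlog.log("qc", file=key, cached=True)
    (out / "qc_report.json").write_text(json.dumps(qc_reports, indent=2, default=str))

    # ---- meta ----------------------------------------------------------
    meta_dir = out / "meta"
    meta_dir.mkdir(parents=True, exist_ok=True)
    populations = sorted({attrs["population"] for attrs in cohorts_cfg.values()})
    meta_tables: dict[tuple, pd.DataFrame] = {}
    for trait in traits:
        for contrast in contrasts:
            for sex_group in sex_groups:
                sname = f"{trait}.{contrast}.{sex_group}"
                pop_tables: dict[str, pd.DataFrame] = {}
                for pop in populations:
                    tables = []
                    for name, attrs in cohorts_cfg.items():
                        if attrs["population"] != pop:
                            continue
                        f = qc_dir / f"{name}.{sname}.tsv"
                        if f.exists() and qc_reports.get(f"{name}.{sname}", {}).get("included"):
                            tables.append(gio.read_summary_stats(f))
                    if len(tables) == 0:
                        continue
                    pooled = meta_cohorts(tables, population=pop)
                    if len(pooled):
                        pop_tables[pop] = pooled
                        meta_tables[(pop, trait, contrast, sex_group)] = pooled
                        pooled.to_csv(meta_dir / f"{pop}.{sname}.tsv", sep="\t", index=False)
                if pop_tables:
                    cpma = cross_population(pop_tables)
                    if len(cpma):
                        meta_tables[("CPMA", trait, contrast, sex_group)] = cpma
                        cpma.to_csv(meta_dir / f"CPMA.{sname}.tsv", sep="\t", index=False)
                jlog.log("meta", slice=sname, populations=list(pop_tables),
                         cpma=("CPMA", trait, contrast, sex_group) in meta_tables)

    # ---- discover ------------------------------------------------------
    disc_cfg = config.get("discovery", {})
    q = float(disc_cfg.get("fdr_q", 0.05))
    d_cutoff = disc_cfg.get("approach_d_cutoff", "nominal")
    known_path = disc_cfg.get("known_loci")
    known = (
        pd.read_csv(known_path, sep="\t")
        if known_path
        else pd.DataFrame(columns=["chrom", "pos", "rsid", "trait"])
    )
    # LD reference panel: dosages of the largest simulated cohort
    panel_cohort = max(cohorts.values(), key=lambda c: len(c.individuals))
    panel = LDPanel(panel_cohort.genotypes, panel_cohort.variant_meta["variant_id"])
    positions = dict(
        zip(panel_cohort.variant_meta["variant_id"], panel_cohort.variant_meta["position"])
    )

    report: dict = {"scans": [], "config_hash": chash, "seed": seed}
    thresholds = config.get("reporting", {}).get("thresholds")
    for key, records in meta_tables.items():
        pop, trait, contrast, sex_group = key
        scan = discover_scan(
            records, panel, known, positions,
            population=pop, trait=trait, contrast=contrast, sex_group=sex_group,
            q=q, d_cutoff=d_cutoff, thresholds=thresholds,
        )
        report["scans"].append(scan)
        jlog.log("discover", population=pop, trait=trait, contrast=contrast,
                 sex_group=sex_group, hits=scan.get("tier_a", 0) + scan.get("tier_b", 0))

    # sex heterogeneity of lead interaction effects (combined-scan leads)
    het = []
    for key, records in meta_tables.items():
        pop, trait, contrast, sex_group = key
        if sex_group != "combined":
            continue
        males = meta_tables.get((pop, trait, contrast, "M"))
        females = meta_tables.get((pop, trait, contrast, "F"))
        if males is None or females is None:
            continue
        m_idx = males.set_index("variant_id")
        f_idx = females.set_index("variant_id")
        shared = [v for v in records["variant_id"] if v in m_idx.index and v in f_idx.index]
        if not shared:
            continue
        z, p, sig = sex_het_test(
            m_idx.loc[shared, "beta_int"].to_numpy(),
            m_idx.loc[shared, "se_int"].to_numpy(),
            f_idx.loc[shared, "beta_int"].to_numpy(),
            f_idx.loc[shared, "se_int"].to_numpy(),
            n_tests=len(shared),
        )
        het.append(
            {
                "population": pop,
                "trait": trait,
                "contrast": contrast,
                "n_tests": len(shared),
                "n_significant": int(np.sum(sig)),
            }
        )
    report["sex_heterogeneity"] = het

    disc_dir = out / "discovery"
    disc_dir.mkdir(parents=True, exist_ok=True)
    (disc_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    _write_stamp(out, "discover", chash, seed)
    jlog.log("done", report=str(disc_dir / "report.json"))
    return report
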