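"""File formats: summary-statistics TSV dialect, manifest, provenance stamps.

The interchange format is a tab-separated table with a mandatory header in
``gxebp.gwis.STATS_COLUMNS`` order, ``.`` for missing values, and optional
``#key=value`` provenance comment lines before the header.  Round-trips are
lossless to better than 1e-12 relative on floating-point columns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gxebp.gwis import STATS_COLUMNS

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_manifest",
    "version_stamp",
    "parse_stamp",
    "config_hash",
]

POPULATIONS = ("AFR", "BRA", "EAS", "EUR", "HIS", "SAS")

_FLOAT_COLUMNS = [
    "eaf",
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


class SummaryStatsError(ValueError):
    """Malformed summary-statistics file."""


def write_summary_stats(df: pd.DataFrame, path: str | Path, stamp: list[str] | None = None) -> None:
    """Write a summary-statistics table in the interchange TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in STATS_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[STATS_COLUMNS]
    with open(path, "w") as fh:
        for line in stamp or []:
            fh.write(line.rstrip("\n") + "\n")
        out.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.17g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read the interchange TSV; raises with a line number on malformed rows."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
    else:
        raise SummaryStatsError(f"{path}: no header row found")
    header = lines[body_start].rstrip("\n").split("\t")
    missing = [c for c in STATS_COLUMNS if c not in header]
    if missing:
        raise SummaryStatsError(f"{path}: missing required columns {missing}")
    n_fields = len(header)
    for offset, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
            raise SummaryStatsError(f"{path}: malformed row at line {offset}")
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values=["."], keep_default_na=False,
        dtype={"variant_id": str, "effect_allele": str, "other_allele": str},
    )
    for col in _FLOAT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[STATS_COLUMNS]


def read_manifest(path: str | Path) -> dict:
    """Read and validate a cohort manifest YAML.

    Maps cohort id to ``{population, n, ...}``; population labels must come
    from the fixed vocabulary.
    """
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError("manifest must be a mapping of cohort id to attributes")
    for cohort, attrs in manifest.items():
        pop = attrs.get("population")
        if pop not in POPULATIONS:
            raise ValueError(
                f"cohort {cohort!r}: population {pop!r} not in {POPULATIONS}"
            )
    return manifest


def config_hash(config: dict) -> str:
    """Deterministic short hash of a configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def version_stamp(config: dict, seed: int) -> list[str]:
    """Provenance comment lines for output files."""
    from gxebp import __version__

    return [
        f"#gxebp_version={__version__}",
        f"#config_hash={config_hash(config)}",
        f"#seed={seed}",
    ]


def parse_stamp(path: str | Path) -> dict:
    """Parse ``#key=value`` provenance lines from a file header."""
    stamp: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, value = line[1:].rstrip("\n").split("=", 1)
                stamp[key] = value
    return stamp
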