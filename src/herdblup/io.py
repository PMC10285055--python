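"""Readers/writers for the pipeline's external file formats and run manifests.

Inputs are CSV (pedigree: `animal_id,sire_id,dam_id`; performance:
`animal_id,country,herd,calving_date,age_months,my305,afc,ci1`, missing values
empty); analytical outputs are TSV.  Every pipeline run writes a manifest with a
config digest, the seed, input checksums and the decisions in effect.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .hys import make_hys

__all__ = ["read_performance", "attach_hys", "write_results", "file_digest",
           "write_manifest"]

PERFORMANCE_COLUMNS = ("animal_id", "country", "herd", "calving_date",
                       "age_months", "my305", "afc", "ci1")


def read_performance(path, season_rule: str = "quarter",
                     trait_names=("my305", "afc", "ci1")) -> pd.DataFrame:
    """Read a performance CSV and attach the `hys` contemporary-group column."""
    df = pd.read_csv(path, dtype={"animal_id": str, "country": str, "herd": str,
                                  "calving_date": str})
    required = {"animal_id", "herd", "calving_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"performance file {path} lacks columns {sorted(missing)}")
    for t in trait_names:
        if t in df.columns:
            df[t] = pd.to_numeric(df[t], errors="coerce")
    return attach_hys(df, season_rule)


def attach_hys(df: pd.DataFrame, season_rule: str = "quarter") -> pd.DataFrame:
    df = df.copy()
    labels = []
    for row_number, (herd, date) in enumerate(zip(df["herd"], df["calving_date"]), 1):
        try:
            labels.append(make_hys(herd, date, season_rule))
        except ValueError as exc:
            raise ValueError(f"row {row_number}: {exc}") from exc
    df["hys"] = labels
    return df


def write_results(result, path) -> None:
    """Results TSV: `animal_id,trait,ebv,pev,reliability,accuracy,model_tag`."""
    result.table().to_csv(path, sep="\t", index=False)


def write_fixed_effects(result, path) -> None:
    result.fixed_effects.to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, *, seed: int, config_digest: str, inputs: dict,
                   decisions: dict, timings: dict | None = None,
                   extra: dict | None = None) -> dict:
    from . import __version__

    manifest = {
        "tool": "herdblup",
        "version": __version__,
        "seed": seed,
        "config_digest": config_digest,
        "input_checksums": inputs,
        "decisions": decisions,
        "stage_timings_s": timings or {},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
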