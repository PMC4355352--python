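"""Typed table readers/writers: TSV adapters, FCS ingestion, GMT sets.

TSV (tab-delimited, UTF-8, header row) is the canonical on-disk format.
Readers validate schemas strictly: missing columns raise, extra columns
warn and are passed through.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from follistage.fcs import read_fcs, write_fcs, FcsParseError

EVENT_SCHEMA = ("fsc", "ssc", "peak_fluor", "integrated_fluor")
ARRAY_SCHEMA = ("array_id", "contrast", "dye", "sample_id", "probe_id", "fg", "bg")
QPCR_SCHEMA = ("gene", "sample", "Cq", "is_standard", "input_ng")
PROFILE_SCHEMA = ("sample_id", "p_subG1", "p_G1", "p_S", "p_G2", "normalized")
REGULON_SCHEMA = ("regulator", "gene", "direction")


class SchemaError(ValueError):
    pass


def _check_schema(df: pd.DataFrame, required, label: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table is missing columns {missing}; found {list(df.columns)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{label} table has extra columns {extra}; preserved in passthrough", stacklevel=3)
    return df


def read_tsv(path, required, label: str = "input") -> pd.DataFrame:
    return _check_schema(pd.read_csv(path, sep="\t"), required, label)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read an event table from TSV or FCS 3.x (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        df = read_fcs(path)
        return _check_schema(df, EVENT_SCHEMA, "event")
    return read_tsv(path, EVENT_SCHEMA, "event")


def write_events(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        write_fcs(path, df[list(EVENT_SCHEMA)])
    else:
        write_tsv(df, path)


def read_array_long(path) -> pd.DataFrame:
    return read_tsv(path, ARRAY_SCHEMA, "array")


def read_qpcr(path) -> pd.DataFrame:
    return read_tsv(path, QPCR_SCHEMA, "qPCR")


def read_profiles(path) -> pd.DataFrame:
    return read_tsv(path, PROFILE_SCHEMA, "phase-profile")


def read_gmt(path) -> dict:
    """Read gene sets from GMT: name <tab> description <tab> genes..."""
    sets = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"GMT line {lineno} has fewer than 3 fields")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_regulons(path) -> list:
    """Read signed regulons from TSV (regulator, gene, direction)."""
    from follistage.enrichment import Regulon

    df = read_tsv(path, REGULON_SCHEMA, "regulon")
    out = []
    for reg, grp in df.groupby("regulator"):
        members = {g: int(d) for g, d in zip(grp["gene"], grp["direction"])}
        out.append(Regulon(regulator_id=str(reg), members=members))
    return out


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
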