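"""Readers and writers for the table formats the pipeline consumes and emits.

SEG segment tables (tab-delimited sample/chrom/start/end/seg.mean), per-sample
purity CSVs, GMT gene sets, guide count matrices with guide maps, and clinical
tables.  Chromosome labels are normalized on read (``chr1`` and ``1`` agree);
every writer produces plain CSV/TSV so round trips are value-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from .genome import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "read_seg",
    "write_seg",
    "read_gmt",
    "write_gmt",
    "read_purity",
    "read_counts",
    "read_clinical",
    "write_provenance",
]

_SEG_COLS = ["sample", "chrom", "start_bp", "end_bp", "log2_ratio"]


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file: tab-delimited sample, chrom, start, end, seg.mean.

    A header line is tolerated (detected by a non-numeric start field).
    Extra columns beyond the first five are ignored.  Rows with end < start
    or malformed numeric fields are rejected with their line number.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] < 5:
        raise ValueError(f"{path}: SEG needs >= 5 columns, found {raw.shape[1]}")
    start_line = 1
    try:
        float(raw.iloc[0, 2])
    except (ValueError, TypeError):
        raw = raw.iloc[1:].reset_index(drop=True)
        start_line = 2
    rows = []
    for i, rec in raw.iterrows():
        line_no = start_line + i
        try:
            start = int(float(rec.iloc[2]))
            end = int(float(rec.iloc[3]))
            log2r = float(rec.iloc[4])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed numeric field on line {line_no}") from exc
        if end < start:
            raise ValueError(f"{path}: end < start on line {line_no}")
        rows.append((str(rec.iloc[0]), normalize_chrom(rec.iloc[1]), start, end, log2r))
    return pd.DataFrame(rows, columns=_SEG_COLS)


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write a segment table as SEG (tab-delimited with header)."""
    out = segments[_SEG_COLS].copy()
    out.columns = ["ID", "chrom", "loc.start", "loc.end", "seg.mean"]
    out.to_csv(path, sep="\t", index=False)


def read_purity(path) -> pd.Series:
    """Read per-sample purity: CSV with columns sample, purity."""
    df = pd.read_csv(path)
    if not {"sample", "purity"} <= set(df.columns):
        raise ValueError(f"{path}: purity CSV needs columns sample, purity")
    s = df.set_index("sample")["purity"].astype(float)
    if ((s <= 0) | (s > 1)).any():
        raise ValueError(f"{path}: purity values must be in (0, 1]")
    return s


def read_gmt(path) -> dict[str, set]:
    """Read GMT gene sets: name, description, members, tab-delimited.

    Duplicate members within a set are deduplicated with a warning; lines
    with fewer than three fields are rejected with their line number.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        logger.warning("%s: empty GMT file", path)
        return sets
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line {i} has fewer than 3 fields")
        name = fields[0]
        members = [g for g in fields[2:] if g]
        uniq = set(members)
        if len(uniq) < len(members):
            logger.warning("%s: set %s has %d duplicate member(s); deduplicated",
                           path, name, len(members) - len(uniq))
        sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_counts(counts_path, map_path) -> pd.DataFrame:
    """Join a guide count matrix (guide x samples CSV/TSV) with its guide map.

    The map is TSV with columns guide, gene, chrom, pos.  Every count-matrix
    guide must appear in the map exactly once.
    """
    sep = "\t" if str(counts_path).endswith((".tsv", ".txt")) else ","
    counts = pd.read_csv(counts_path, sep=sep)
    gmap = pd.read_csv(map_path, sep="\t")
    need = {"guide", "gene", "chrom", "pos"}
    if not need <= set(gmap.columns):
        raise ValueError(f"{map_path}: guide map needs columns {sorted(need)}")
    if gmap["guide"].duplicated().any():
        raise ValueError(f"{map_path}: guides must map to exactly one gene")
    if "guide" not in counts.columns:
        counts = counts.rename(columns={counts.columns[0]: "guide"})
    missing = set(counts["guide"]) - set(gmap["guide"])
    if missing:
        raise ValueError(f"{len(missing)} guide(s) in counts absent from map")
    gmap["chrom"] = gmap["chrom"].map(normalize_chrom)
    merged = gmap.merge(counts, on="guide", how="inner")
    count_cols = [c for c in merged.columns if c not in ("guide", "gene", "chrom", "pos")]
    if (merged[count_cols].to_numpy() < 0).any():
        raise ValueError("negative counts in matrix")
    return merged


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV: patient, time, event, drugs (';'-separated), optional classes."""
    df = pd.read_csv(path)
    need = {"patient", "time", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: clinical CSV needs columns {sorted(need)}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 or 1")
    if "drugs" in df.columns:
        df["drugs"] = df["drugs"].fillna("")
    return df


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_provenance(path, config: dict, seed: int | None = None) -> None:
    """JSON sidecar recording the config hash and seed next to an output table."""
    payload = {
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
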