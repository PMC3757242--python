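"""Readers and writers for the plain-text formats used across the pipeline.

Conventions: expression matrices are tab-delimited, features as rows with a
header row of sample IDs; ortholog maps are two-column TSVs; segments are
SEG-like TSVs (sample, chrom, start, end, call) with 1-based inclusive
coordinates converted to 0-based half-open on read and back on write; BED
is 0-based half-open as always; gene sets are GMT.  Parse errors report
file and line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .agdex import OrthologPairSet
from .cnv import Segment, SegmentSet


class ParseError(ValueError):
    pass


# -- expression matrices ----------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Tab-delimited features x samples matrix with sample-ID header row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse matrix ({exc})") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: matrix contains missing values")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


# -- ortholog maps ----------------------------------------------------------

def read_ortholog_map(path: str | Path) -> OrthologPairSet:
    """Two-column TSV (species1 feature, species2 feature); no header."""
    path = Path(path)
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated IDs")
            pairs.append((parts[0], parts[1]))
    return OrthologPairSet(pairs)


def write_ortholog_map(pairs: OrthologPairSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b in pairs.pairs:
            fh.write(f"{a}\t{b}\n")


# -- segments (SEG-like) ----------------------------------------------------

def read_segments(path: str | Path) -> list[SegmentSet]:
    """SEG-like TSV with header sample/chrom/start/end/call.

    Input coordinates are 1-based inclusive (SEG convention) and converted
    to 0-based half-open.
    """
    path = Path(path)
    sets: dict[str, list[Segment]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample", "chrom", "start", "end", "call"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            sample, chrom, start, end, call = parts
            try:
                seg = Segment(chrom, int(start) - 1, int(end), call)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            sets.setdefault(sample, []).append(seg)
    return [SegmentSet(s, segs) for s, segs in sets.items()]


def write_segments(sets: Iterable[SegmentSet], path: str | Path) -> None:
    """Write SEG-like TSV, converting back to 1-based inclusive."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tcall\n")
        for s in sets:
            for seg in s.segments:
                fh.write(f"{s.sample}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t{seg.call}\n")


# -- BED --------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Minimal BED reader: chrom/start/end[/name], 0-based half-open."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# -- GMT gene sets ----------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: set name, description, then member IDs, tab-separated."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 member"
                )
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# -- generic ----------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# -- intensity traces/profiles ----------------------------------------------

def read_traces(path: str | Path) -> pd.DataFrame:
    """TSV with metadata columns then intensity columns, one trace per row.

    Expected columns: sample, label, then v0..vN intensities.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ParseError(f"{path}: trace table needs a 'sample' column")
    return df


def write_traces(rows: list[tuple[str, str, Iterable[float]]], path: str | Path) -> None:
    """Write (sample, label, values) rows to a trace/profile TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    materialized = [(s, lab, list(v)) for s, lab, v in rows]
    n = max((len(v) for _, _, v in materialized), default=0)
    with open(path, "w") as fh:
        fh.write("sample\tlabel\t" + "\t".join(f"v{i}" for i in range(n)) + "\n")
        for sample, label, vals in materialized:
            vals = vals + [0.0] * (n - len(vals))
            fh.write(sample + "\t" + label + "\t" + "\t".join(f"{v:.6g}" for v in vals) + "\n")
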