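"""File-format dialects: TSV matrices, BED/bedGraph/BEDPE, FASTA, JSON.

Report coordinates are 1-based inclusive; BED-family files are written in
their native 0-based half-open convention.  Conversion happens here and
only here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, from_bed_fields, to_bed_fields
from .pools import MatePairSet


class FormatError(ValueError):
    pass


# --- marker x sample matrices (markers as rows: id, chrom, pos, then samples)

def write_matrix_tsv(path: str | Path, markers: pd.DataFrame, data: pd.DataFrame) -> None:
    if not markers.index.equals(data.index):
        raise FormatError("marker table and data matrix indices differ")
    out = pd.concat([markers[["chrom", "pos"]], data], axis=1)
    out.to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="id")
    markers = df[["chrom", "pos"]].copy()
    data = df.drop(columns=["chrom", "pos"])
    return markers, data


def write_samples_tsv(path: str | Path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


# --- BED / bedGraph

def write_bed(path: str | Path, intervals: list[GenomicInterval], names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            chrom, s, e = to_bed_fields(iv)
            name = names[k] if names else f"region{k + 1}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: malformed BED record: {line!r}")
        try:
            out.append(from_bed_fields(parts[0], int(parts[1]), int(parts[2])))
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: {err}") from err
    return out


def write_bedgraph(path: str | Path, chrom: str, start: int, window: int, values: np.ndarray) -> None:
    """``start`` is 1-based; records are emitted 0-based half-open."""
    with open(path, "w") as fh:
        for w, v in enumerate(values):
            s = start - 1 + w * window
            fh.write(f"{chrom}\t{s}\t{s + window}\t{v:.6g}\n")


# --- BEDPE mate pairs

def write_bedpe(path: str | Path, pairs: MatePairSet, max_records: int | None = None) -> None:
    n = len(pairs) if max_records is None else min(len(pairs), max_records)
    r = pairs.read_length
    with open(path, "w") as fh:
        for k in range(n):
            s1, s2 = pairs.pos1[k] - 1, pairs.pos2[k] - 1
            st1 = "+" if pairs.strand1[k] > 0 else "-"
            st2 = "+" if pairs.strand2[k] > 0 else "-"
            fh.write(
                f"{pairs.chrom}\t{s1}\t{s1 + r}\t{pairs.chrom}\t{s2}\t{s2 + r}\tpair{k}\t0\t{st1}\t{st2}\n"
            )


def read_bedpe(path: str | Path, library_total_reads: int | None = None) -> MatePairSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["c1", "s1", "e1", "c2", "s2", "e2", "name", "score", "st1", "st2"],
    )
    if df.isna().any().any():
        raise FormatError(f"{path}: malformed BEDPE (missing fields)")
    read_len = int(df["e1"][0] - df["s1"][0])
    return MatePairSet(
        pos1=df["s1"].to_numpy(dtype=np.int64) + 1,
        strand1=np.where(df["st1"] == "+", 1, -1),
        pos2=df["s2"].to_numpy(dtype=np.int64) + 1,
        strand2=np.where(df["st2"] == "+", 1, -1),
        read_length=read_len,
        chrom=str(df["c1"][0]),
        library_total_reads=library_total_reads if library_total_reads is not None else 2 * len(df),
    )


# --- FASTA

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- JSON

def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, GenomicInterval):
        return {"chrom": obj.chrom, "start": obj.start, "end": obj.end}
    raise TypeError(f"not JSON-serializable: {type(obj)}")
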