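"""Readers and writers for the on-disk formats the pipeline touches.

Formats: ENCODE narrowPeak (10 columns), BED6, bedGraph, fixed-step wiggle
(read-only), and tab-separated tables with a header row.  Everything is
converted to 0-based half-open coordinates at this boundary and chromosome
names are matched by exact string equality (no "chr" aliasing).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    FormatError,
    GeneRecord,
    GenomicInterval,
    ParameterError,
    PeakSummit,
    ReadTagSet,
    SignalTrack,
    ValidationError,
)

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "expr_imm", "expr_mat", "fdr"]
TAG_COLUMNS = ["chrom", "pos5", "strand"]


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path, tf_name: str = "") -> list[PeakSummit]:
    """Read an ENCODE 10-column narrowPeak file into summit records.

    The summit is chromStart plus the column-10 offset.  Records with the
    conventional "unset" offset of -1 get the interval midpoint instead, so
    downstream distance arithmetic stays total.
    """
    summits: list[PeakSummit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start, end = int(start), int(end)
                score = float(score)
                offset = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            interval = GenomicInterval(chrom, start, end, strand if strand in "+-." else ".")
            summit = interval.midpoint if offset == -1 else start + offset
            if not (start <= summit < end):
                raise ValidationError(
                    f"{path}:{lineno}: summit {summit} outside [{start}, {end})"
                )
            summits.append(
                PeakSummit(interval=interval, summit=summit, score=max(score, 0.0),
                           tf_name=tf_name, name=name)
            )
    return summits


def write_narrowpeak(summits: Iterable[PeakSummit], path: str | Path) -> int:
    """Write summit records as narrowPeak; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for s in summits:
            iv = s.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        s.name or f"{s.tf_name or 'peak'}_{n + 1}",
                        str(int(round(s.score))),
                        iv.strand,
                        f"{s.score:.4g}",
                        "-1",
                        "-1",
                        str(s.summit - iv.start),
                    ]
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the tab-separated gene table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                expr_imm=float(row.expr_imm),
                expr_mat=float(row.expr_mat),
                fdr=float(row.fdr),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> int:
    df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.strand, g.tss, g.expr_imm, g.expr_mat, g.fdr)
            for g in genes
        ],
        columns=GENE_COLUMNS,
    )
    # full float repr so the table round-trips exactly
    df.to_csv(path, sep="\t", index=False)
    return len(df)


# ---------------------------------------------------------------------------
# bedGraph and wiggle
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, bin_size: int = 10) -> SignalTrack:
    """Rasterize a strict bedGraph into a binned SignalTrack.

    Records must be sorted and non-overlapping within each chromosome.
    Partially covered bins take the coverage-weighted mean of overlapping
    record values, which conserves total value mass under re-binning;
    untouched bins are zero.
    """
    if bin_size < 1:
        raise ParameterError("bin_size must be >= 1")
    # accumulate value mass and covered bases per bin, then divide
    mass: dict[str, np.ndarray] = {}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            if start < last_end.get(chrom, 0):
                raise FormatError(
                    f"{path}:{lineno}: records on {chrom} overlap or are unsorted"
                )
            last_end[chrom] = end
            arr = mass.get(chrom)
            needed = (end - 1) // bin_size + 1
            if arr is None:
                arr = np.zeros(needed, dtype=float)
                mass[chrom] = arr
            elif needed > arr.size:
                arr = np.concatenate([arr, np.zeros(needed - arr.size)])
                mass[chrom] = arr
            first_bin = start // bin_size
            last_bin = (end - 1) // bin_size
            for b in range(first_bin, last_bin + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                arr[b] += value * (hi - lo)
    values = {chrom: arr / bin_size for chrom, arr in mass.items()}
    return SignalTrack(values=values, bin_size=bin_size, normalization="raw")


def write_bedgraph(track: SignalTrack, path: str | Path) -> int:
    """Write a SignalTrack as bedGraph, merging equal-valued adjacent bins.

    Zero bins are omitted (bedGraph convention: uncovered means zero).
    """
    n = 0
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            run_start = 0
            for i in range(1, arr.size + 1):
                if i == arr.size or arr[i] != arr[run_start]:
                    v = arr[run_start]
                    if v != 0:
                        fh.write(
                            f"{chrom}\t{run_start * track.bin_size}"
                            f"\t{i * track.bin_size}\t{v:.6g}\n"
                        )
                        n += 1
                    run_start = i
    return n


def read_wiggle_fixedstep(path: str | Path, bin_size: int = 10) -> SignalTrack:
    """Read a fixed-step wiggle file (1-based starts per UCSC convention)."""
    segments: list[tuple[str, int, int, list[float]]] = []  # chrom, start0, step, vals
    current: list[float] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(item.split("=") for item in line.split()[1:])
                try:
                    chrom = kv["chrom"]
                    start0 = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", step))
                except (KeyError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad fixedStep header") from exc
                if span != step:
                    raise FormatError(f"{path}:{lineno}: span != step unsupported")
                current = []
                segments.append((chrom, start0, step, current))
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: value before fixedStep header")
                try:
                    current.append(float(line))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
    mass: dict[str, np.ndarray] = {}
    for chrom, start0, step, vals in segments:
        if not vals:
            continue
        end = start0 + step * len(vals)
        needed = (end - 1) // bin_size + 1
        arr = mass.get(chrom)
        if arr is None:
            arr = np.zeros(needed)
            mass[chrom] = arr
        elif needed > arr.size:
            arr = np.concatenate([arr, np.zeros(needed - arr.size)])
            mass[chrom] = arr
        for i, v in enumerate(vals):
            s = start0 + i * step
            e = s + step
            for b in range(s // bin_size, (e - 1) // bin_size + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                arr[b] += v * (hi - lo)
    values = {chrom: arr / bin_size for chrom, arr in mass.items()}
    return SignalTrack(values=values, bin_size=bin_size, normalization="raw")


# ---------------------------------------------------------------------------
# tag tables and BED
# ---------------------------------------------------------------------------

def read_tag_table(path: str | Path, fragment_length_mean: float = 300.0) -> ReadTagSet:
    """Read a tag table TSV with columns chrom, pos5, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["pos5"] = df["pos5"].astype(np.int64)
    if len(df) and (df["pos5"] < 0).any():
        raise ValidationError(f"{path}: negative pos5")
    return ReadTagSet(tags=df[TAG_COLUMNS], fragment_length_mean=fragment_length_mean)


def write_tag_table(tags: ReadTagSet, path: str | Path) -> int:
    tags.tags.to_csv(path, sep="\t", index=False)
    return len(tags.tags)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> int:
    n = 0
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            n += 1
    return n


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> int:
    """Write a DataFrame as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g",
              quoting=csv.QUOTE_NONE)
    return len(df)
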