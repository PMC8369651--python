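"""Readers/writers for the external text formats plus genome-track utilities.

Formats: TSV quantification tables, bin-pair triplet contact matrices, BED3+,
BEDPE, bedGraph and FASTA (via pyfaidx). BED/BEDPE/bedGraph keep their native
0-based half-open convention, which matches the internal one.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import BinTrack, ContactMatrix, GenomeBinning, QuantTable

__all__ = [
    "load_quant_table",
    "write_quant_table",
    "load_contacts",
    "write_contacts",
    "load_intervals",
    "write_intervals",
    "read_bedgraph",
    "write_bedgraph",
    "motif_density_track",
    "aggregate_track_at_intervals",
]

_NA_VALUES = ["", "NA", "NaN", "nan"]

BED_COLUMNS = ["chrom", "start", "end", "name", "score"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


# ---------------------------------------------------------------------------
# quantification tables


def _coerce_metadata(metadata) -> pd.DataFrame:
    """Accept a DataFrame (sample-indexed), a mapping sample -> (condition, batch),
    or a path to a TSV with columns sample/condition/batch."""
    if isinstance(metadata, (str, os.PathLike)):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str).set_index("sample")
    if isinstance(metadata, dict):
        metadata = pd.DataFrame(
            {s: {"condition": c, "batch": b} for s, (c, b) in metadata.items()}
        ).T
    if not {"condition", "batch"}.issubset(metadata.columns):
        raise ValueError("metadata needs 'condition' and 'batch' columns")
    return metadata


def load_quant_table(path, metadata) -> QuantTable:
    """Read a protein x sample iBAQ table (first column = protein id).

    Blank/unparseable cells become missing. Raises on duplicate protein ids and
    on samples absent from ``metadata``.
    """
    meta = _coerce_metadata(metadata)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate protein id {dup!r} in {path}")
    unknown = df.columns.difference(meta.index)
    if len(unknown):
        raise ValueError(f"samples missing from metadata: {list(unknown)}")
    df = df.apply(pd.to_numeric, errors="coerce")
    return QuantTable(df, meta["condition"], meta["batch"], kind="iBAQ")


def write_quant_table(table: QuantTable, path) -> None:
    out = table.data.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# contact matrices


def load_contacts(path, binning: GenomeBinning, chrom: str) -> ContactMatrix:
    """Read triplet text: ``bin_i bin_j count`` or ``chrom1 pos1 chrom2 pos2 count``.

    Counts at (j, i) are folded into (i, j); duplicate pixels accumulate.
    """
    n = binning.n_bins(chrom)
    b1, b2, cnt = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 3:
                i, j = int(fields[0]), int(fields[1])
                c = float(fields[2])
            elif len(fields) == 5:
                if fields[0] != chrom or fields[2] != chrom:
                    raise ValueError(
                        f"line {lineno}: chromosome mismatch (expected {chrom})"
                    )
                i = binning.bin_of(chrom, int(fields[1]))
                j = binning.bin_of(chrom, int(fields[3]))
                c = float(fields[4])
            else:
                raise ValueError(f"line {lineno}: expected 3 or 5 fields")
            if c < 0:
                raise ValueError(f"line {lineno}: negative count")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"line {lineno}: bin index out of range for {chrom}")
            if i > j:
                i, j = j, i
            b1.append(i)
            b2.append(j)
            cnt.append(c)
    if b1:
        df = pd.DataFrame({"b1": b1, "b2": b2, "c": cnt})
        df = df.groupby(["b1", "b2"], as_index=False)["c"].sum()
        return ContactMatrix(chrom, binning, df["b1"], df["b2"], df["c"])
    return ContactMatrix(chrom, binning, [], [], [])


def write_contacts(matrix: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, j, c in zip(matrix.bin1, matrix.bin2, matrix.count):
            c = int(c) if float(c).is_integer() else c
            fh.write(f"{i}\t{j}\t{c}\n")


# ---------------------------------------------------------------------------
# intervals


def load_intervals(path, kind: str = "BED") -> pd.DataFrame:
    """Read BED3+ (-> IntervalSet frame) or BEDPE (-> LoopSet frame).

    Cis BEDPE records with anchors out of genomic order are stored reordered so
    anchor1 <= anchor2.
    """
    if kind not in ("BED", "BEDPE"):
        raise ValueError("kind must be 'BED' or 'BEDPE'")
    rows = []
    ncols_min = 3 if kind == "BED" else 6
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < ncols_min:
                raise ValueError(f"line {lineno}: need >= {ncols_min} columns")
            if kind == "BED":
                start, end = int(f[1]), int(f[2])
                if start >= end:
                    raise ValueError(f"line {lineno}: start >= end")
                rows.append(
                    {
                        "chrom": f[0],
                        "start": start,
                        "end": end,
                        "name": f[3] if len(f) > 3 else ".",
                        "score": f[4] if len(f) > 4 else ".",
                    }
                )
            else:
                rec = {
                    "chrom1": f[0],
                    "start1": int(f[1]),
                    "end1": int(f[2]),
                    "chrom2": f[3],
                    "start2": int(f[4]),
                    "end2": int(f[5]),
                }
                if rec["start1"] >= rec["end1"] or rec["start2"] >= rec["end2"]:
                    raise ValueError(f"line {lineno}: start >= end")
                if rec["chrom1"] == rec["chrom2"] and rec["start1"] > rec["start2"]:
                    rec = {
                        "chrom1": rec["chrom2"],
                        "start1": rec["start2"],
                        "end1": rec["end2"],
                        "chrom2": rec["chrom1"],
                        "start2": rec["start1"],
                        "end2": rec["end1"],
                    }
                for k, extra in enumerate(f[6:]):
                    rec[f"attr{k + 1}"] = extra
                rows.append(rec)
    columns = BED_COLUMNS if kind == "BED" else BEDPE_COLUMNS
    return _frame(rows, columns)


def _frame(rows, columns):
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    ordered = columns + [c for c in df.columns if c not in columns]
    return df[ordered]


def write_intervals(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph tracks


def write_bedgraph(track: BinTrack, path) -> None:
    """Write defined bins as 4-column bedGraph; missing bins are omitted."""
    res = track.binning.resolution
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if np.isnan(v):
                continue
            end = track.binning.bin_end(track.chrom, i)
            fh.write(f"{track.chrom}\t{i * res}\t{end}\t{float(v)!r}\n")


def read_bedgraph(path, binning: GenomeBinning, chrom: str) -> BinTrack:
    """Read a bedGraph whose intervals are exactly this binning's bins."""
    res = binning.resolution
    values = np.full(binning.n_bins(chrom), np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, start, end, v = line.split()[:4]
            if c != chrom:
                continue
            start, end = int(start), int(end)
            if start % res or end != min(start + res, binning.chrom_sizes[chrom]):
                raise ValueError(f"line {lineno}: interval not aligned to binning")
            values[start // res] = float(v)
    return BinTrack(chrom, binning, values)


# ---------------------------------------------------------------------------
# genome tracks from sequence / signal aggregation


def _sequences(source):
    """Yield (name, sequence) from a pyfaidx-readable FASTA path or a dict."""
    if isinstance(source, dict):
        return source.items()
    from pyfaidx import Fasta

    fa = Fasta(str(source))
    return ((name, str(fa[name][:])) for name in fa.keys())


def count_motif(sequence: str, motif: str) -> list:
    """Start positions of (possibly overlapping) motif matches, case-insensitive."""
    seq = sequence.upper()
    motif = motif.upper()
    hits, pos = [], seq.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(motif, pos + 1)
    return hits


def motif_density_track(sequence_source, motif: str, binsize: int = 500) -> dict:
    """Per-bin motif occurrence counts (occurrences per ``binsize`` bp).

    An occurrence is assigned to the bin containing its start; overlapping
    occurrences all count; no reverse-complement scan (GGCC is its own reverse
    complement). Returns {chrom: BinTrack}.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError("motif must be a non-empty string over A/C/G/T")
    if len(motif) > binsize:
        raise ValueError("motif longer than bin size")
    seqs = {name: seq for name, seq in _sequences(sequence_source)}
    binning = GenomeBinning({n: len(s) for n, s in seqs.items()}, binsize)
    tracks = {}
    for name, seq in seqs.items():
        counts = np.zeros(binning.n_bins(name))
        for pos in count_motif(seq, motif):
            counts[pos // binsize] += 1
        tracks[name] = BinTrack(name, binning, counts)
    return tracks


def aggregate_track_at_intervals(
    track: BinTrack, intervals: pd.DataFrame, flank: int
) -> np.ndarray:
    """Mean signal profile over +/-``flank`` bp windows at interval midpoints.

    Midpoint = floor((start+end)/2). Windows truncated by a chromosome edge are
    dropped; missing values are excluded position-wise from the mean.
    """
    res = track.binning.resolution
    if flank % res:
        raise ValueError("flank must be a multiple of the track resolution")
    here = intervals[intervals["chrom"] == track.chrom]
    if not len(here):
        raise ValueError(f"no intervals on {track.chrom}")
    w = flank // res
    n = track.n_bins
    windows = []
    for start, end in zip(here["start"], here["end"]):
        mid_bin = ((int(start) + int(end)) // 2) // res
        if mid_bin - w < 0 or mid_bin + w >= n:
            continue
        windows.append(track.values[mid_bin - w : mid_bin + w + 1])
    if not windows:
        raise ValueError("all windows truncated at chromosome edges")
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(windows), axis=0)
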