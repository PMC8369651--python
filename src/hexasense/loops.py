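"""Loop- and stripe-level sensitivity: per-loop signal change, aggregate peak
analysis (APA), differential loops with anchor slop, stripe aggregation and
loop classification by stripe-anchor overlap.

Loop pixels come from BEDPE anchor pairs; an anchor maps to the bin containing
its midpoint. APA averages O/E windows centered on loop pixels so distance
decay cancels; center enrichment is the center pixel over the mean of the
far-from-diagonal corner block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic import BalancedView, observed_over_expected

__all__ = [
    "APAResult",
    "loop_bins",
    "loop_signal_change",
    "apa",
    "differential_loops",
    "stripe_aggregate",
    "classify_loops_by_stripe",
]


@dataclass
class APAResult:
    matrix: np.ndarray  # (2h+1) x (2h+1) mean O/E window
    n_loops: int
    center_enrichment: float


def loop_bins(loops: pd.DataFrame, binning, chrom: str) -> np.ndarray:
    """Map each cis loop on ``chrom`` to a (bin_i <= bin_j) pixel via anchor
    midpoints. Returns an (n, 2) int array."""
    here = loops[(loops["chrom1"] == chrom) & (loops["chrom2"] == chrom)]
    res = binning.resolution
    n = binning.n_bins(chrom)
    out = []
    for s1, e1, s2, e2 in zip(here["start1"], here["end1"], here["start2"], here["end2"]):
        i = ((int(s1) + int(e1)) // 2) // res
        j = ((int(s2) + int(e2)) // 2) // res
        if i > j:
            i, j = j, i
        if 0 <= i and j < n:
            out.append((i, j))
    return np.array(out, dtype=int).reshape(-1, 2)


def loop_signal_change(
    before: BalancedView, after: BalancedView, loops: pd.DataFrame
) -> pd.DataFrame:
    """Per-loop after/before contact-probability ratio at the loop pixel.

    Contact probability = balanced value / total balanced signal, so the ratio
    is depth-independent. Loops at masked bins or with zero before-probability
    are flagged undefined and excluded from the summary mean.
    """
    binning = before.matrix.binning
    chrom = before.matrix.chrom
    pix = loop_bins(loops, binning, chrom)
    db, da = before.dense(), after.dense()
    tb, ta = before.total(), after.total()
    rows = []
    for i, j in pix:
        vb, va = db[i, j] / tb, da[i, j] / ta
        if np.isnan(vb) or np.isnan(va) or vb == 0:
            rows.append({"bin1": i, "bin2": j, "ratio": np.nan, "defined": False})
        else:
            rows.append({"bin1": i, "bin2": j, "ratio": va / vb, "defined": True})
    df = pd.DataFrame(rows, columns=["bin1", "bin2", "ratio", "defined"])
    df.attrs["mean_ratio"] = float(df.loc[df["defined"], "ratio"].mean())
    return df


def apa(
    b: BalancedView,
    loops: pd.DataFrame,
    half_window: int = 10,
    group_col: str = None,
) -> "APAResult | dict":
    """Aggregate peak analysis on O/E windows centered at loop pixels.

    Loops whose (2h+1)-window leaves the matrix or crosses the diagonal are
    dropped. With ``group_col`` set (a column of ``loops``), one APAResult per
    group is returned, each divided by its own loop count.
    """
    if group_col is not None:
        return {
            key: apa(b, sub, half_window)
            for key, sub in loops.groupby(group_col, sort=True)
        }
    h = half_window
    chrom = b.matrix.chrom
    pix = loop_bins(loops, b.matrix.binning, chrom)
    oe = observed_over_expected(b)
    n = b.n_bins
    windows = []
    for i, j in pix:
        if i - h < 0 or j + h >= n or (j - h) - (i + h) < 1:
            continue  # off-matrix or diagonal-crossing window
        windows.append(oe[i - h : i + h + 1, j - h : j + h + 1])
    if not windows:
        raise ValueError("no usable loops for APA")
    agg = np.nanmean(np.stack(windows), axis=0)
    corner = agg[0:h, h + 1 :]  # far-from-diagonal corner block (h x h)
    center = agg[h, h]
    enrichment = float(center / np.nanmean(corner))
    return APAResult(agg, len(windows), enrichment)


def _anchors_overlap(s1, e1, s2, e2, slop) -> bool:
    """Half-open intervals, each expanded by +/-slop, intersect."""
    return (s1 - slop) < (e2 + slop) and (s2 - slop) < (e1 + slop)


def differential_loops(before: pd.DataFrame, after: pd.DataFrame, slop: int = 10_000):
    """Kept / lost / gained loops by slopped both-anchor overlap.

    A before-loop is kept iff some after-loop on the same chromosome pair has
    anchor1 overlapping anchor1 and anchor2 overlapping anchor2 once both are
    expanded by +/-``slop`` bp; unmatched before-loops are lost, unmatched
    after-loops gained.
    """

    def _matches(row, other) -> bool:
        cand = other[
            (other["chrom1"] == row["chrom1"]) & (other["chrom2"] == row["chrom2"])
        ]
        for _, o in cand.iterrows():
            if _anchors_overlap(row["start1"], row["end1"], o["start1"], o["end1"], slop) and _anchors_overlap(
                row["start2"], row["end2"], o["start2"], o["end2"], slop
            ):
                return True
        return False

    kept_idx = [idx for idx, row in before.iterrows() if _matches(row, after)]
    lost_idx = [idx for idx in before.index if idx not in set(kept_idx)]
    gained_idx = [idx for idx, row in after.iterrows() if not _matches(row, before)]
    return {
        "kept": before.loc[kept_idx],
        "lost": before.loc[lost_idx],
        "gained": after.loc[gained_idx],
        "lost_fraction": len(lost_idx) / len(before) if len(before) else 0.0,
    }


def stripe_aggregate(
    b: BalancedView,
    stripes: pd.DataFrame,
    extent: int,
    background_offset: int = 5,
) -> dict:
    """Mean O/E profile along stripes plus a perpendicular-offset background.

    ``stripes`` needs columns ``anchor_bin`` and ``orientation`` ("left": the
    stripe runs along (a, a+k); "right": along (a-k, a)). The background takes
    the same profiles with the anchor shifted perpendicular to the stripe by
    +/-``background_offset`` bins. Profiles truncated at the matrix edge are
    NaN-padded; stripes fully off-matrix are dropped.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    oe = observed_over_expected(b)
    n = b.n_bins
    profiles, backgrounds = [], []
    for _, s in stripes.iterrows():
        a = int(s["anchor_bin"])
        if not 0 <= a < n:
            continue
        sign = 1 if s["orientation"] == "left" else -1
        prof = np.full(extent, np.nan)
        bg = np.full(extent, np.nan)
        for k in range(1, extent + 1):
            other = a + sign * k
            if not 0 <= other < n:
                continue
            prof[k - 1] = oe[min(a, other), max(a, other)]
            vals = []
            for off in (-background_offset, background_offset):
                aa = a + off
                if 0 <= aa < n and aa != other:
                    vals.append(oe[min(aa, other), max(aa, other)])
            bg[k - 1] = np.nanmean(vals) if vals else np.nan
        if np.all(np.isnan(prof)):
            continue
        profiles.append(prof)
        backgrounds.append(bg)
    if not profiles:
        raise ValueError("no usable stripes")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tail positions
        mean_prof = np.nanmean(np.vstack(profiles), axis=0)
        mean_bg = np.nanmean(np.vstack(backgrounds), axis=0)
    return {
        "profile": mean_prof,
        "background": mean_bg,
        "ratio": float(np.nanmean(mean_prof) / np.nanmean(mean_bg)),
        "n_stripes": len(profiles),
    }


def classify_loops_by_stripe(loops: pd.DataFrame, stripe_anchors: pd.DataFrame):
    """Count loop anchors overlapping any stripe-anchor interval: both/one/none."""

    def _hits(chrom, start, end) -> bool:
        here = stripe_anchors[stripe_anchors["chrom"] == chrom]
        return bool(((here["start"] < end) & (start < here["end"])).any())

    classes = []
    for _, row in loops.iterrows():
        k = _hits(row["chrom1"], row["start1"], row["end1"]) + _hits(
            row["chrom2"], row["start2"], row["end2"]
        )
        classes.append({2: "both", 1: "one", 0: "none"}[k])
    return pd.Series(classes, index=loops.index, name="stripe_class")
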