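"""Insulation-score TAD boundary calling, cross-condition boundary matching,
and intra/inter-TAD interaction-change ratios stratified by subcompartment.

The insulation score of bin i is the mean balanced signal in a square window
upstream x downstream of i sliding along the diagonal (1 Mb x 1 Mb at 40 kb
resolution in the source protocol), log2-normalized to the chromosome mean.
Boundaries are negative-to-positive zero crossings of the delta vector (right
minus left flanking mean of the insulation score) whose flanking delta
amplitude ("boundary strength") reaches 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic import BalancedView

__all__ = [
    "InsulationProfile",
    "insulation_profile",
    "call_boundaries",
    "match_boundaries",
    "tad_interaction_change",
    "DEFAULT_SUBCOMP_GROUPS",
]

DEFAULT_SUBCOMP_GROUPS = {
    "A1": ("A1",),
    "A2B1": ("A2", "B1"),
    "B2B3": ("B2", "B3"),
}


@dataclass
class InsulationProfile:
    """Normalized insulation scores, delta vector and called boundaries."""

    chrom: str
    resolution: int
    score: np.ndarray  # log2(raw IS / chrom mean raw IS), NaN near edges
    delta: np.ndarray = None
    boundaries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["bin", "strength"])
    )


def insulation_profile(b: BalancedView, window: int = 1_000_000) -> InsulationProfile:
    """Sliding-square insulation score from a balanced matrix.

    ``window`` (bp) must be a multiple of the resolution and >= 2 bins; bins
    within one window of an edge, or whose square touches a masked bin, are
    missing.
    """
    res = b.matrix.binning.resolution
    if window % res:
        raise ValueError("window must be a multiple of the resolution")
    w = window // res
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    d = b.dense()
    n = b.n_bins
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        square = d[i - w : i, i + 1 : i + w + 1]
        if np.any(np.isnan(square)):
            continue
        raw[i] = square.mean()
    mean = np.nanmean(raw)
    score = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = np.isfinite(raw) & (raw > 0)
        score[ok] = np.log2(raw[ok] / mean)
    return InsulationProfile(b.matrix.chrom, res, score)


def call_boundaries(
    ins: InsulationProfile, delta_window: int = 200_000, min_strength: float = 0.1
) -> InsulationProfile:
    """Boundaries at negative->positive zero crossings of the delta vector.

    delta(i) = mean(IS[i+1..i+d]) - mean(IS[i-d..i-1]); at each crossing the
    candidate bin is the lower-IS bin of the crossing pair, its strength the
    delta amplitude max(delta[i..i+d]) - min(delta[i-d..i]); candidates under
    ``min_strength`` are filtered.
    """
    d = delta_window // ins.resolution
    if d < 1:
        raise ValueError("delta window must span at least 1 bin")
    s = ins.score
    n = s.size
    delta = np.full(n, np.nan)
    for i in range(n):
        right = s[i + 1 : min(i + d + 1, n)]
        left = s[max(i - d, 0) : i]
        if right.size and left.size and not (
            np.all(np.isnan(right)) or np.all(np.isnan(left))
        ):
            delta[i] = np.nanmean(right) - np.nanmean(left)
    boundaries = []
    for i in range(n - 1):
        if np.isnan(delta[i]) or np.isnan(delta[i + 1]):
            continue
        if delta[i] < 0 <= delta[i + 1]:
            pair = [i, i + 1]
            vals = [s[j] if np.isfinite(s[j]) else np.inf for j in pair]
            bin_i = pair[int(np.argmin(vals))]
            lo = delta[max(bin_i - d, 0) : bin_i + 1]
            hi = delta[bin_i : min(bin_i + d + 1, n)]
            strength = np.nanmax(hi) - np.nanmin(lo)
            if strength >= min_strength:
                boundaries.append({"bin": bin_i, "strength": float(strength)})
    bdf = pd.DataFrame(boundaries, columns=["bin", "strength"])
    return InsulationProfile(ins.chrom, ins.resolution, s, delta, bdf)


def match_boundaries(before, after, slop: int = 80_000, resolution: int = None):
    """Greedy closest-pair matching of boundary lists within +/-``slop`` bp.

    ``before``/``after`` are bin-index sequences or boundary DataFrames (with
    resolution taken from an InsulationProfile when given). Returns a dict with
    stable pairs, lost (before-only), gained (after-only) and the lost
    fraction among before-boundaries.
    """

    def _bins(x):
        if isinstance(x, InsulationProfile):
            return list(x.boundaries["bin"]), x.resolution
        if isinstance(x, pd.DataFrame):
            return list(x["bin"]), None
        return list(x), None

    bb, res_b = _bins(before)
    ab, res_a = _bins(after)
    res = resolution or res_b or res_a
    if res is None:
        raise ValueError("resolution required when passing plain bin lists")
    pairs = sorted(
        (abs(i - j) * res, i, j)
        for i in bb
        for j in ab
        if abs(i - j) * res <= slop
    )
    used_b, used_a, stable = set(), set(), []
    for _, i, j in pairs:  # closest first; ties to leftmost via sort order
        if i in used_b or j in used_a:
            continue
        used_b.add(i)
        used_a.add(j)
        stable.append((i, j))
    lost = [i for i in bb if i not in used_b]
    gained = [j for j in ab if j not in used_a]
    return {
        "stable": stable,
        "lost": lost,
        "gained": gained,
        "lost_fraction": len(lost) / len(bb) if bb else 0.0,
    }


def _bins_to_tads(binning, chrom, tads: pd.DataFrame) -> np.ndarray:
    """Per-bin TAD id by majority overlap (-1 = outside all TADs)."""
    res = binning.resolution
    n = binning.n_bins(chrom)
    tad_of = np.full(n, -1)
    best = np.zeros(n)
    here = tads[tads["chrom"] == chrom].reset_index(drop=True)
    for t, (start, end) in enumerate(zip(here["start"], here["end"])):
        for i in range(int(start) // res, min(-(-int(end) // res), n)):
            ov = min(int(end), binning.bin_end(chrom, i)) - max(int(start), i * res)
            if ov > best[i]:
                best[i] = ov
                tad_of[i] = t
    return tad_of


def tad_interaction_change(
    before: BalancedView,
    after: BalancedView,
    tads: pd.DataFrame,
    subcomp: pd.DataFrame,
    groups: dict = None,
    max_separation: int = 10_000_000,
) -> pd.DataFrame:
    """After/before contact-probability ratios within and between TADs, by
    subcompartment group.

    Each TAD takes the subcompartment of the majority of its bins; pixels
    joining TADs of *different* groups are skipped. Inter-TAD pixels beyond
    ``max_separation`` bp are excluded to keep the ratio distance-comparable.
    """
    groups = groups or DEFAULT_SUBCOMP_GROUPS
    binning = before.matrix.binning
    chrom = before.matrix.chrom
    res = binning.resolution
    tad_of = _bins_to_tads(binning, chrom, tads)
    from .hic import assign_bin_states

    bin_state = assign_bin_states(binning, chrom, subcomp)
    # majority subcompartment per TAD
    tad_state = {}
    for t in np.unique(tad_of[tad_of >= 0]):
        states, cnt = np.unique(bin_state[tad_of == t], return_counts=True)
        keep = states != ""
        if keep.any():
            tad_state[t] = states[keep][np.argmax(cnt[keep])]
    group_of_state = {s: g for g, members in groups.items() for s in members}
    db, da = before.dense(), after.dense()
    tb, ta = before.total(), after.total()
    n = before.n_bins
    sums = {g: {"intra": [0.0, 0.0], "inter": [0.0, 0.0]} for g in groups}
    max_bins = max_separation // res
    for i in range(n):
        ti = tad_of[i]
        if ti < 0 or ti not in tad_state:
            continue
        gi = group_of_state.get(tad_state[ti])
        if gi is None:
            continue
        for j in range(i, min(i + max_bins + 1, n)):
            tj = tad_of[j]
            if tj < 0 or tj not in tad_state:
                continue
            gj = group_of_state.get(tad_state[tj])
            if gj != gi:
                continue  # interactions between different groups are skipped
            kind = "intra" if ti == tj else "inter"
            vb, va = db[i, j], da[i, j]
            if np.isnan(vb) or np.isnan(va):
                continue
            sums[gi][kind][0] += vb / tb
            sums[gi][kind][1] += va / ta
    rows = []
    for g in groups:
        for kind in ("intra", "inter"):
            sb, sa = sums[g][kind]
            rows.append(
                {
                    "group": g,
                    "kind": kind,
                    "ratio": sa / sb if sb > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
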