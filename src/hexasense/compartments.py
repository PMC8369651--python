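"""A/B compartment calling and the four-way compartment change classification.

Compartments come from the sign of the leading eigenvector (PC1) of the
Pearson correlation matrix of the balanced O/E map, oriented so PC1 correlates
positively with a gene-density (activity) reference; A = PC1 > 0, B = PC1 < 0.

Across conditions the per-bin ratio PC1_after / PC1_before classifies bins as
strengthened (> 1.2), stable (within +/-20%, inclusive), weakened (< 0.8) or
flipped (opposite signs). Eigenvectors are defined only up to scale, so both
profiles are rescaled to unit standard deviation over shared bins before
ratios are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentProfile",
    "CompartmentChange",
    "call_compartments",
    "classify_compartment_change",
    "neighbor_context",
]

CHANGE_TYPES = ("strengthened", "stable", "weakened", "flipped", "undefined")


@dataclass
class CompartmentProfile:
    """PC1 values (unit norm, NaN at masked bins) and per-bin A/B labels."""

    pc1: np.ndarray
    labels: np.ndarray  # "A", "B" or ""


@dataclass
class CompartmentChange:
    ratio: np.ndarray  # PC1_after / PC1_before on rescaled vectors
    change_type: np.ndarray
    fractions: pd.DataFrame  # change-type fractions among defined bins, per A/B


def call_compartments(pearson: np.ndarray, reference) -> CompartmentProfile:
    """Leading eigenvector of the Pearson matrix, sign-anchored to a reference.

    ``reference`` is a per-bin activity proxy (gene density) on the same
    binning; the eigenvector is negated if it correlates negatively with it.
    """
    ref = np.asarray(getattr(reference, "values", reference), dtype=float)
    n = pearson.shape[0]
    if ref.shape != (n,):
        raise ValueError("reference track does not match the matrix binning")
    defined = ~np.all(np.isnan(pearson), axis=0)
    idx = np.where(defined)[0]
    if idx.size < 3:
        raise ValueError("too few defined bins for eigendecomposition")
    sub = pearson[np.ix_(idx, idx)]
    sub = np.where(np.isnan(sub), 0.0, sub)  # residual NaN (constant rows) -> 0
    evals, evecs = np.linalg.eigh(sub)
    v = evecs[:, -1]  # eigenvector of the largest eigenvalue, unit norm
    pc1 = np.full(n, np.nan)
    pc1[idx] = v
    both = defined & ~np.isnan(ref)
    if both.sum() >= 2 and np.nanstd(ref[both]) > 0:
        r = np.corrcoef(pc1[both], ref[both])[0, 1]
        if r < 0:
            pc1 = -pc1
    labels = np.array([""] * n, dtype=object)
    labels[(pc1 > 0) & defined] = "A"
    labels[(pc1 < 0) & defined] = "B"
    return CompartmentProfile(pc1, labels)


def classify_compartment_change(
    before: CompartmentProfile, after: CompartmentProfile, threshold: float = 0.2
) -> CompartmentChange:
    """Apply the +/-20% strengthened/stable/weakened/flipped rule per bin.

    Both PC1 vectors are rescaled to unit standard deviation over the bins
    defined in both profiles; boundary ratios 1-threshold and 1+threshold are
    classed stable (the "within" reading, inclusive).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    b, a = np.asarray(before.pc1, float).copy(), np.asarray(after.pc1, float).copy()
    if b.shape != a.shape:
        raise ValueError("profiles must share a binning")
    shared = ~np.isnan(b) & ~np.isnan(a)
    for v in (b, a):
        sd = np.nanstd(v[shared])
        if sd > 0:
            v[:] = v / sd
    n = b.size
    ratio = np.full(n, np.nan)
    ctype = np.array(["undefined"] * n, dtype=object)
    for i in range(n):
        if not shared[i] or b[i] == 0 or a[i] == 0:
            continue
        if np.sign(a[i]) != np.sign(b[i]):
            ctype[i] = "flipped"
            continue
        r = a[i] / b[i]
        ratio[i] = r
        if r > 1 + threshold:
            ctype[i] = "strengthened"
        elif r < 1 - threshold:
            ctype[i] = "weakened"
        else:
            ctype[i] = "stable"

    rows = []
    for comp in ("A", "B"):
        sel = (np.asarray(before.labels) == comp) & (ctype != "undefined")
        tot = sel.sum()
        for t in CHANGE_TYPES[:4]:
            rows.append(
                {
                    "compartment": comp,
                    "change_type": t,
                    "fraction": (np.sum(ctype[sel] == t) / tot) if tot else np.nan,
                    "n_bins": int(np.sum(ctype[sel] == t)),
                }
            )
    return CompartmentChange(ratio, ctype, pd.DataFrame(rows))


def _segments(labels) -> list:
    """Merge consecutive equal non-empty labels into (start, end, label) runs."""
    segs = []
    start = None
    for i, lab in enumerate(list(labels) + [None]):
        if start is not None and (lab != labels[start]):
            segs.append((start, i, labels[start]))
            start = None
        if start is None and lab not in ("", None):
            start = i
    return segs


def neighbor_context(change: CompartmentChange, labels) -> pd.DataFrame:
    """Contingency of segment-level change type x flanking-label congruence.

    Consecutive bins with the same A/B label form segments; each segment gets
    its majority change type and is scored "same" if both flanking segments
    share its label, "different" if at least one defined flank differs, "edge"
    if it touches the chromosome end (or a gap) on either side.
    """
    labels = np.asarray(labels, dtype=object)
    segs = _segments(labels)
    counts = {}
    for k, (s, e, lab) in enumerate(segs):
        types, cnt = np.unique(change.change_type[s:e], return_counts=True)
        dominant = types[np.argmax(cnt)]
        left = segs[k - 1] if k > 0 else None
        right = segs[k + 1] if k + 1 < len(segs) else None
        if left is None or right is None:
            congruence = "edge"
        elif left[2] == lab and right[2] == lab:
            congruence = "same"
        else:
            congruence = "different"
        counts[(dominant, congruence)] = counts.get((dominant, congruence), 0) + 1
    return pd.DataFrame(
        [
            {"change_type": t, "neighbors": c, "n_segments": n}
            for (t, c), n in sorted(counts.items())
        ]
    )
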