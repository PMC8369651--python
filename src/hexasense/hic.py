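"""Matrix-level Hi-C primitives: KR balancing, observed/expected, Pearson
correlation transform, contact-probability curves and region-set interaction
change between conditions.

Balancing targets row sums of 1 on the unmasked submatrix (a doubly stochastic
scaling of the symmetric contact map), the convention behind "KR-balanced"
maps. Cross-condition comparisons use contact probability — balanced values
divided by the matrix's total balanced signal — so libraries of different
depth are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContactMatrix

__all__ = [
    "BalancedView",
    "kr_balance",
    "observed_over_expected",
    "pearson_matrix",
    "contact_probability_curve",
    "region_state_interaction_change",
    "assign_bin_states",
]


@dataclass
class BalancedView:
    """A contact matrix together with balancing weights and a bin mask.

    Balanced value at (i, j) = ``weights[i] * raw_ij * weights[j]``; masked
    bins (low coverage) have NaN weights and NaN balanced rows/columns.
    """

    matrix: ContactMatrix
    weights: np.ndarray
    mask: np.ndarray  # True = excluded

    def dense(self) -> np.ndarray:
        m = self.matrix.to_dense()
        b = self.weights[:, None] * m * self.weights[None, :]
        b[self.mask, :] = np.nan
        b[:, self.mask] = np.nan
        return b

    @property
    def n_bins(self) -> int:
        return self.matrix.n_bins

    def total(self) -> float:
        """Total balanced signal over the upper triangle (incl. diagonal)."""
        d = self.dense()
        iu = np.triu_indices(self.n_bins)
        return float(np.nansum(d[iu]))


def _sinkhorn(a: np.ndarray, tol: float, max_iter: int):
    """Symmetric Sinkhorn scaling: x <- x / sqrt(rowsum). Oracle-simple."""
    x = np.ones(a.shape[0])
    for _ in range(max_iter):
        r = x * (a @ x)
        if np.max(np.abs(r - 1)) <= tol:
            return x, True
        x = x / np.sqrt(r)
    r = x * (a @ x)
    return x, bool(np.max(np.abs(r - 1)) <= tol)


def _knight_ruiz(a: np.ndarray, tol: float, max_iter: int):
    """Knight-Ruiz balancing of a symmetric non-negative matrix.

    Inner-outer Newton iteration with conjugate-gradient inner solves; returns
    x with diag(x) A diag(x) doubly stochastic.
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol**2
    v = x * (a @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    total_iter = 0
    while rout > rt and total_iter < max_iter:
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            total_iter += 1
            if total_iter >= max_iter:
                break
        x = x * y
        v = x * (a @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        total_iter += 1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        if g * eta**2 > 0.1:
            eta = max(eta, g * eta**2)
        eta = max(min(eta, etamax), 0.5 * tol / res_norm)
    r = x * (a @ x)
    return x, bool(np.max(np.abs(r - 1)) <= tol)


def kr_balance(
    m: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000, min_nnz: int = 10
) -> BalancedView:
    """Balance a contact matrix so unmasked row sums equal 1.

    Bins with fewer than ``min_nnz`` non-zero pixels are masked first. Knight-
    Ruiz iteration is tried, with a plain Sinkhorn fallback; non-convergence of
    both raises, naming the chromosome.
    """
    n = m.n_bins
    if m.n_pixels == 0:
        raise ValueError(f"{m.chrom}: empty contact matrix")
    dense = m.to_dense()
    nnz = (dense > 0).sum(axis=1)
    mask = nnz < min_nnz
    if mask.all():
        raise ValueError(f"{m.chrom}: all bins masked (min_nnz={min_nnz})")
    keep = ~mask
    sub = dense[np.ix_(keep, keep)]
    x, ok = _knight_ruiz(sub, tol, max_iter)
    if not ok or np.any(~np.isfinite(x)) or np.any(x <= 0):
        x, ok = _sinkhorn(sub, tol, max_iter)
    if not ok:
        raise RuntimeError(f"{m.chrom}: balancing did not converge in {max_iter} iterations")
    weights = np.full(n, np.nan)
    weights[keep] = x
    return BalancedView(m, weights, mask)


def observed_over_expected(b: BalancedView) -> np.ndarray:
    """O/E matrix: balanced value / mean balanced value at its bin distance.

    The expected value at distance s is the mean over all unmasked pixels at
    that distance (zeros included). Distances with zero expected value yield
    NaN, as do masked bins.
    """
    d = b.dense()
    n = b.n_bins
    oe = np.full((n, n), np.nan)
    keep = np.where(~b.mask)[0]
    for s in range(n):
        i = keep[keep + s < n]
        i = i[~b.mask[i + s]] if s else i
        if not i.size:
            continue
        vals = d[i, i + s]
        exp = np.nanmean(vals)
        if not np.isfinite(exp) or exp == 0:
            continue
        oe[i, i + s] = vals / exp
        oe[i + s, i] = vals / exp
    return oe


def pearson_matrix(oe: np.ndarray) -> np.ndarray:
    """Row-row Pearson correlation of the O/E matrix (pairwise-complete).

    Diagonal is 1 for bins with any defined off-diagonal value; constant rows
    give NaN correlations.
    """
    df = pd.DataFrame(oe)
    if df.notna().any(axis=1).sum() < 3:
        raise ValueError("need at least 3 unmasked bins")
    p = df.corr(min_periods=3).to_numpy()
    defined = ~np.all(np.isnan(oe), axis=0)
    idx = np.where(defined)[0]
    p[idx, idx] = 1.0
    return p


def contact_probability_curve(
    b: BalancedView, labels=None, log_ratio: float = 1.15
) -> dict:
    """Distance-stratified contact probability P(s), log-binned.

    Returns {stratum: DataFrame(distance_bp, prob, n_pairs)} for strata "all"
    and, when per-bin A/B ``labels`` are given, "A-A" and "B-B". Each curve is
    normalized so sum(P(s) * n_pairs(s)) = 1.
    """
    d = b.dense()
    n = b.n_bins
    res = b.matrix.binning.resolution
    strata = {"all": np.ones(n, dtype=bool)}
    if labels is not None:
        labels = np.asarray(labels)
        strata["A-A"] = labels == "A"
        strata["B-B"] = labels == "B"

    # geometric distance-bin edges (in bins)
    edges = [1]
    while edges[-1] < n:
        edges.append(max(int(np.ceil(edges[-1] * log_ratio)), edges[-1] + 1))
    edges = np.array(edges)

    out = {}
    for name, sel in strata.items():
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1)
        idx = np.where(sel & ~b.mask)[0]
        idxset = np.zeros(n, dtype=bool)
        idxset[idx] = True
        for s in range(1, n):
            k = np.searchsorted(edges, s, side="right") - 1
            if k >= len(sums):
                continue
            i = np.arange(n - s)
            ok = idxset[i] & idxset[i + s]
            if not ok.any():
                continue
            vals = d[i[ok], i[ok] + s]
            sums[k] += np.nansum(vals)
            counts[k] += np.sum(~np.isnan(vals))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = sums / counts
        tot = np.nansum(p * counts)
        if tot > 0:
            p = p / tot
        mids = np.sqrt(edges[:-1] * edges[1:]) * res
        keep = counts > 0
        out[name] = pd.DataFrame(
            {"distance_bp": mids[keep], "prob": p[keep], "n_pairs": counts[keep]}
        )
    return out


def assign_bin_states(binning, chrom: str, states: pd.DataFrame) -> np.ndarray:
    """Per-bin state label by majority overlap; ties -> first state in file order.

    Bins with no overlapping state get the empty string.
    """
    res = binning.resolution
    n = binning.n_bins(chrom)
    # overlap accumulated per (bin, state), preserving file order of first sight
    order = {}
    overlap = {}
    here = states[states["chrom"] == chrom]
    for pos, (start, end, name) in enumerate(zip(here["start"], here["end"], here["name"])):
        if name not in order:
            order[name] = pos
        for i in range(int(start) // res, min(-(-int(end) // res), n)):
            bs, be = i * res, binning.bin_end(chrom, i)
            ov = min(int(end), be) - max(int(start), bs)
            if ov > 0:
                overlap[(i, name)] = overlap.get((i, name), 0) + ov
    labels = np.array([""] * n, dtype=object)
    per_bin = {}
    for (i, name), ov in overlap.items():
        per_bin.setdefault(i, []).append((ov, -order[name], name))
    for i, cand in per_bin.items():
        cand.sort(reverse=True)  # max overlap, then earliest file order
        labels[i] = cand[0][2]
    return labels


def region_state_interaction_change(
    before: BalancedView, after: BalancedView, states: pd.DataFrame
) -> pd.DataFrame:
    """Per-state after/before ratio of summed intra-state contact probability.

    A pixel belongs to a state when *both* its bins are assigned that state by
    majority overlap. Contact probability = balanced value / total balanced
    signal, so the ratio is depth-independent. States covering no bins are NaN.
    """
    if before.n_bins != after.n_bins:
        raise ValueError("matrices must share a binning")
    chrom = before.matrix.chrom
    labels = assign_bin_states(before.matrix.binning, chrom, states)
    db, da = before.dense(), after.dense()
    tb, ta = before.total(), after.total()
    rows = []
    for state in dict.fromkeys(states["name"]):
        sel = np.where(labels == state)[0]
        if not sel.size:
            rows.append({"state": state, "ratio": np.nan, "n_bins": 0})
            continue
        ii, jj = np.meshgrid(sel, sel, indexing="ij")
        up = ii <= jj
        sb = np.nansum(db[ii[up], jj[up]]) / tb
        sa = np.nansum(da[ii[up], jj[up]]) / ta
        rows.append(
            {
                "state": state,
                "ratio": sa / sb if sb > 0 else np.nan,
                "n_bins": int(sel.size),
            }
        )
    return pd.DataFrame(rows)
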