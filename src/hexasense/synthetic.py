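"""Synthetic study data with planted ground truth.

Three generators emulate the study's inputs so every downstream stage is
testable without the deposited datasets:

* :func:`simulate_quant_experiment` — label-free MS tables (iBAQ) for paired
  control/treated conditions with planted per-protein depletion factors
  (the true AICAP), log-normal replicate noise and abundance-dependent
  (left-censoring, MNAR) missingness.
* :func:`simulate_hic_pair` — paired before/after intra-chromosomal contact
  maps with power-law distance decay, checkerboard compartments, TAD blocks,
  loop peaks with Gaussian spill, stripe lines, per-bin biases and Poisson
  counts; treatment perturbs compartment strength, loops and stripes.
* :func:`simulate_frap_trace` — recovery traces from the single-exponential
  model A(1 - e^(-t/tau)) + y0 with Gaussian noise.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BinTrack, ContactMatrix, FRAPTrace, GenomeBinning, QuantTable

__all__ = [
    "QuantTruth",
    "simulate_quant_experiment",
    "HiCTruth",
    "make_hic_truth",
    "simulate_hic_pair",
    "simulate_frap_trace",
    "gene_density_reference",
    "simulate_sequence_panel",
]


# ---------------------------------------------------------------------------
# proteomics


@dataclass
class QuantTruth:
    """Planted ground truth behind a simulated quantification experiment.

    Arrays cover every simulated protein, including ones censored out of the
    table entirely (``detected`` False).
    """

    protein_ids: list
    abundance: np.ndarray  # true per-protein abundance (iBAQ scale)
    depletion: np.ndarray  # d > 0: treated abundance = d * control abundance
    detected: np.ndarray  # protein appears in at least one sample
    noise_cv: float
    missing_mu: float  # sigmoid location on the log-abundance axis
    missing_scale: float
    seed: int

    def detected_depletion(self) -> pd.Series:
        return pd.Series(
            self.depletion[self.detected],
            index=[p for p, ok in zip(self.protein_ids, self.detected) if ok],
        )


def _solve_missing_mu(log_abundance, scale, target):
    """Location of the logistic censoring curve giving the target missing rate."""
    lo, hi = log_abundance.min() - 20, log_abundance.max() + 20
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = np.mean(1.0 / (1.0 + np.exp((log_abundance - mid) / scale)))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_quant_experiment(
    n_proteins: int = 500,
    n_replicates: int = 3,
    noise_cv: float = 0.2,
    missing_rate: float = 0.2,
    frac_unchanged: float = 0.25,
    depletion_sdlog: float = 1.0,
    abundance_meanlog: float = np.log(1e6),
    abundance_sdlog: float = 2.5,
    missing_scale: float = 0.3,
    seed: int = 0,
):
    """Simulate paired control/treated iBAQ tables with planted depletion.

    A ``frac_unchanged`` fraction of proteins keeps d = 1 exactly (the
    histone-like bulk anchoring the chromatin fraction). The rest model the
    treatment as a balanced redistribution — condensate proteins are released
    from chromatin (d < 1) while cytoplasmic proteins gain access (d > 1):
    log-depletion factors are drawn antithetically (each factor paired with
    its reciprocal on an abundance-adjacent protein), so the planted field has
    median exactly 1 at every abundance stratum. This balanced design keeps
    the rank-based quantile-normalized index centred: unchanged proteins keep
    their within-sample quantile, so their measured AICAP stays near 1.

    Missingness is left-censoring at the detection limit: a cell goes missing
    with probability sigmoid(-(log expected abundance - mu)/s), with mu solved
    so the overall missing rate matches ``missing_rate``. Proteins detected in
    no sample at all are dropped from the table — as in a real search-engine
    output — but kept in the truth (``detected`` False).

    Returns ``(QuantTable kind=iBAQ, QuantTruth)``.
    """
    if n_proteins <= 0 or n_replicates < 2:
        raise ValueError("need n_proteins > 0 and n_replicates >= 2")
    rng = np.random.default_rng(seed)
    abundance = np.exp(rng.normal(abundance_meanlog, abundance_sdlog, n_proteins))
    n_unchanged = int(round(frac_unchanged * n_proteins))
    perm = rng.permutation(n_proteins)
    cont = perm[n_unchanged:]
    d = np.ones(n_proteins)
    if cont.size:
        cont = cont[np.argsort(abundance[cont])]  # abundance-adjacent pairing
        d_cont = np.ones(cont.size)
        for k in range(0, cont.size - 1, 2):
            x = rng.normal(0.0, depletion_sdlog)
            if rng.random() < 0.5:
                x = -x
            d_cont[k], d_cont[k + 1] = np.exp(x), np.exp(-x)
        if cont.size % 2:
            d_cont[-1] = np.exp(rng.normal(0.0, depletion_sdlog))
        d[cont] = d_cont

    sigma = np.sqrt(np.log1p(noise_cv**2))
    samples, conditions, batches, columns = [], [], [], []
    expected = []
    for cond, factor in (("control", np.ones(n_proteins)), ("treated", d)):
        for r in range(1, n_replicates + 1):
            lam = abundance * factor
            noise = np.exp(rng.normal(0.0, sigma, n_proteins)) if noise_cv > 0 else 1.0
            columns.append(lam * noise)
            expected.append(lam)
            samples.append(f"{'ctrl' if cond == 'control' else 'hex'}_{r}")
            conditions.append(cond)
            batches.append(f"b{r}")
    values = np.column_stack(columns)
    expected = np.column_stack(expected)
    if missing_rate > 0:
        log_exp = np.log(expected)
        mu = _solve_missing_mu(log_exp.ravel(), missing_scale, missing_rate)
        p_miss = 1.0 / (1.0 + np.exp((log_exp - mu) / missing_scale))
        values = np.where(rng.random(values.shape) < p_miss, np.nan, values)
    else:
        mu = -np.inf
    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    detected = ~np.all(np.isnan(values), axis=1)
    data = pd.DataFrame(
        values[detected],
        index=[p for p, ok in zip(protein_ids, detected) if ok],
        columns=samples,
    )
    table = QuantTable(
        data,
        pd.Series(conditions, index=samples),
        pd.Series(batches, index=samples),
        kind="iBAQ",
    )
    truth = QuantTruth(
        protein_ids, abundance, d, detected, noise_cv, mu, missing_scale, seed
    )
    return table, truth


# ---------------------------------------------------------------------------
# Hi-C


@dataclass
class HiCTruth:
    """Planted architecture of a simulated before/after Hi-C pair.

    ``delta_*`` are per-bin compartment strengths (0 <= delta < 1); the pair
    factor is 1 + c_i c_j sqrt(delta_i delta_j). Loops are (bin_i, bin_j,
    factor_before, factor_after); stripes are (anchor_bin, orientation,
    extent_bins, factor_before, factor_after).
    """

    compartment_sign: np.ndarray  # +1 (A) / -1 (B) per bin
    delta_before: np.ndarray
    delta_after: np.ndarray
    boundaries_before: list  # sorted internal TAD boundary bins
    boundaries_after: list
    tad_factor: float = 2.0
    loops: list = field(default_factory=list)
    stripes: list = field(default_factory=list)
    bias_sdlog: float = 0.2
    alpha: float = 1.0
    depth_before: float = 1e6
    depth_after: float = 1e6
    loop_sigma: float = 0.5  # Gaussian spill of loop enrichment, bins
    seed: int = 0

    def __post_init__(self):
        self.compartment_sign = np.asarray(self.compartment_sign, dtype=int)
        n = self.compartment_sign.size
        for name in ("delta_before", "delta_after"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 0:
                v = np.full(n, float(v))
            if np.any(v < 0) or np.any(v >= 1):
                raise ValueError("compartment strength must satisfy 0 <= delta < 1")
            setattr(self, name, v)
        for b in (self.boundaries_before, self.boundaries_after):
            if list(b) != sorted(b):
                raise ValueError("boundaries must be sorted")
        for lp in self.loops:
            if lp[2] < 1 or lp[3] < 0:
                raise ValueError("loop factors must be >= 1 before treatment")


def make_hic_truth(
    n_bins: int = 200,
    block_size: int = 20,
    delta: float = 0.3,
    weaken: str = "A",
    weaken_factor: float = 0.5,
    tad_size: int = 50,
    tad_factor: float = 2.0,
    n_loops: int = 0,
    loop_factor: float = 10.0,
    loop_after_factor: float = None,
    n_stripes: int = 0,
    stripe_factor: float = 3.0,
    stripe_extent: int = 15,
    alpha: float = 1.0,
    bias_sdlog: float = 0.2,
    depth: float = 1e6,
    seed: int = 0,
) -> HiCTruth:
    """Standard planted scenario: alternating A/B blocks, equal-size TADs,
    loops at random mid-range pixels, stripes at TAD boundaries; treatment
    multiplies the compartment strength of ``weaken`` bins by
    ``weaken_factor`` and loop/stripe enrichments likewise.
    """
    rng = np.random.default_rng(seed)
    sign = np.ones(n_bins, dtype=int)
    for start in range(0, n_bins, 2 * block_size):
        sign[start + block_size : start + 2 * block_size] = -1
    delta_before = np.full(n_bins, delta)
    delta_after = delta_before.copy()
    if weaken == "A":
        delta_after[sign > 0] *= weaken_factor
    elif weaken == "B":
        delta_after[sign < 0] *= weaken_factor
    elif weaken == "all":
        delta_after *= weaken_factor
    boundaries = list(range(tad_size, n_bins, tad_size))
    loop_after = loop_factor * weaken_factor if loop_after_factor is None else loop_after_factor
    loops = []
    attempts = 0
    while len(loops) < n_loops and attempts < 50 * max(n_loops, 1):
        attempts += 1
        i = int(rng.integers(12, n_bins - 12))
        s = int(rng.integers(25, min(120, n_bins - 24)))
        j = i + s
        if j >= n_bins - 12:
            continue
        if all(abs(i - li) + abs(j - lj) > 6 for li, lj, *_ in loops):
            loops.append((i, j, loop_factor, max(loop_after, 0.0)))
    stripes = []
    for k in range(n_stripes):
        a = boundaries[k % len(boundaries)] if boundaries else int(rng.integers(10, n_bins - 10))
        orientation = "left" if k % 2 == 0 else "right"
        stripes.append(
            (a, orientation, stripe_extent, stripe_factor, 1.0 + (stripe_factor - 1.0) * weaken_factor)
        )
    return HiCTruth(
        sign,
        delta_before,
        delta_after,
        boundaries,
        boundaries,
        tad_factor,
        loops,
        stripes,
        bias_sdlog,
        alpha,
        depth,
        depth,
        seed=seed,
    )


def _expected_matrix(truth: HiCTruth, when: str) -> np.ndarray:
    """Dense upper-triangle expectation lambda_ij (unnormalized)."""
    n = truth.compartment_sign.size
    delta = truth.delta_before if when == "before" else truth.delta_after
    bounds = truth.boundaries_before if when == "before" else truth.boundaries_after
    rng = np.random.default_rng(truth.seed + 987654)  # biases shared by both conditions
    bias = np.exp(rng.normal(0.0, truth.bias_sdlog, n)) if truth.bias_sdlog > 0 else np.ones(n)
    bias /= bias.mean()
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dist = np.abs(i - j)
    lam = (dist + 1.0) ** (-truth.alpha)
    c = truth.compartment_sign
    lam = lam * (1.0 + np.outer(c, c) * np.sqrt(np.outer(delta, delta)))
    tad_id = np.searchsorted(np.asarray(bounds), np.arange(n), side="right")
    lam = np.where(tad_id[:, None] == tad_id[None, :], lam * truth.tad_factor, lam)
    for li, lj, f_before, f_after in truth.loops:
        f = f_before if when == "before" else f_after
        if f == 1.0:
            continue
        rad = max(int(np.ceil(3 * truth.loop_sigma)), 1)
        for di in range(-rad, rad + 1):
            for dj in range(-rad, rad + 1):
                a, b = li + di, lj + dj
                if 0 <= a < n and 0 <= b < n:
                    g = np.exp(-(di**2 + dj**2) / (2 * truth.loop_sigma**2))
                    lam[a, b] *= 1.0 + (f - 1.0) * g
                    lam[b, a] = lam[a, b]
    for a, orientation, extent, f_before, f_after in truth.stripes:
        f = f_before if when == "before" else f_after
        sign = 1 if orientation == "left" else -1
        for k in range(1, extent + 1):
            b = a + sign * k
            if 0 <= b < n:
                lam[min(a, b), max(a, b)] *= f
                lam[max(a, b), min(a, b)] = lam[min(a, b), max(a, b)]
    lam = lam * np.outer(bias, bias)
    depth = truth.depth_before if when == "before" else truth.depth_after
    iu = np.triu_indices(n)
    lam = lam * (depth / lam[iu].sum())
    return lam


def simulate_hic_pair(binning: GenomeBinning, chrom: str, truth: HiCTruth):
    """Draw the paired before/after contact maps from the planted truth.

    Counts are Poisson around the expectation; both conditions use a fresh
    generator with the same seed (common random numbers), so identical truth
    yields identical matrices.
    """
    n = binning.n_bins(chrom)
    if truth.compartment_sign.size != n:
        raise ValueError("truth size does not match the binning")
    out = []
    for when in ("before", "after"):
        lam = _expected_matrix(truth, when)
        iu = np.triu_indices(n)
        rng = np.random.default_rng(truth.seed)
        counts = rng.poisson(lam[iu])
        nz = counts > 0
        out.append(
            ContactMatrix(chrom, binning, iu[0][nz], iu[1][nz], counts[nz])
        )
    return out[0], out[1], truth


def gene_density_reference(binning: GenomeBinning, chrom: str, truth: HiCTruth, seed: int = 1):
    """Noisy gene-density proxy track correlated with the planted A/B signs
    (A bins gene-dense), used to orient PC1."""
    rng = np.random.default_rng(seed)
    base = np.where(truth.compartment_sign > 0, 10.0, 2.0)
    return BinTrack(chrom, binning, rng.poisson(base).astype(float))


# ---------------------------------------------------------------------------
# FRAP


def simulate_frap_trace(
    A: float,
    tau: float,
    y0: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach: int = 3,
) -> FRAPTrace:
    """Normalized-scale recovery trace from the single-exponential model.

    ``times`` are post-bleach seconds starting at 0; three pre-bleach frames
    at intensity 1.0 are prepended (1 s apart). Gaussian noise is added to the
    post-bleach intensities only.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if A < 0:
        raise ValueError("A must be non-negative")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and increasing")
    rng = np.random.default_rng(seed)
    post = A * (1.0 - np.exp(-times / tau)) + y0
    if noise_sd > 0:
        post = post + rng.normal(0.0, noise_sd, post.size)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    pre_times = times[0] - dt * np.arange(n_prebleach, 0, -1)  # ends dt before t=0
    full_times = np.concatenate([pre_times, times])
    intensity = np.concatenate([np.ones(n_prebleach), post])
    return FRAPTrace(
        times=full_times,
        bleached=intensity,
        control=np.ones_like(intensity),
        background=np.zeros_like(intensity),
        n_prebleach=n_prebleach,
        normalized=intensity,
    )


# ---------------------------------------------------------------------------
# protein sequences (demonstration panel for residue-composition analysis)


def simulate_sequence_panel(aicap: pd.Series, length: int = 400, seed: int = 0):
    """Random protein sequences whose IDR hydrophobic content decreases with
    AICAP, with one IDR (and a PLD inside it) per protein.

    A demonstration generator for the residue-composition correlation; returns
    (sequences dict, regions DataFrame with protein/start/end/kind).
    """
    rng = np.random.default_rng(seed)
    hydrophobic = list("ILVFM")
    other = [aa for aa in "ACDEFGHIKLMNPQRSTVWY" if aa not in hydrophobic]
    seqs, rows = {}, []
    lo, hi = aicap.min(), aicap.max()
    for prot, a in aicap.items():
        frac = 0.45 - 0.35 * (a - lo) / max(hi - lo, 1e-9)  # low AICAP -> hydrophobic IDR
        idr_start, idr_end = length // 4, 3 * length // 4
        seq = []
        for pos in range(length):
            p = frac if idr_start <= pos < idr_end else 0.15
            if rng.random() < p:
                seq.append(hydrophobic[rng.integers(len(hydrophobic))])
            else:
                seq.append(other[rng.integers(len(other))])
        seqs[prot] = "".join(seq)
        rows.append({"protein": prot, "start": idr_start, "end": idr_end, "kind": "IDR"})
        rows.append(
            {
                "protein": prot,
                "start": idr_start,
                "end": idr_start + (idr_end - idr_start) // 2,
                "kind": "PLD",
            }
        )
    return seqs, pd.DataFrame(rows)
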