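"""Proteomics core: from iBAQ tables to the anti-1,6-HD index of
chromatin-associated proteins (AICAP), significance, grouping, preranked
enrichment and residue-composition correlation.

The pipeline is iBAQ -> FOT (fraction of total, x10^6) -> per-sample minimum
imputation -> quantile normalization -> AICAP = mean treated FOT / mean
control FOT with a two-sided Welch t-test per protein. Low AICAP means the
protein is stripped from chromatin by 1,6-hexanediol, i.e. its association
depends on hexanediol-sensitive hydrophobic interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import QuantTable

__all__ = [
    "ibaq_to_fot",
    "impute_missing",
    "quantile_normalize",
    "compute_aicap",
    "aicap_pipeline",
    "assign_aicap_group",
    "AICAP_GROUP_EDGES",
    "EnrichmentResult",
    "preranked_enrichment",
    "residue_composition_correlation",
    "RESIDUES",
]

FOT_SCALE = 1e6


def ibaq_to_fot(table: QuantTable) -> QuantTable:
    """FOT_p = iBAQ_p / sum of present iBAQ in the sample, x 10^6.

    Missing values stay missing; each sample's present FOTs sum to 10^6.
    """
    if table.kind != "iBAQ":
        raise ValueError(f"expected an iBAQ table, got {table.kind}")
    totals = table.data.sum(axis=0, skipna=True)
    bad = totals[(totals <= 0) | totals.isna()]
    if len(bad):
        raise ValueError(f"samples with no positive values: {list(bad.index)}")
    return table.replace_values(table.data / totals * FOT_SCALE, kind="FOT")


def impute_missing(table: QuantTable) -> QuantTable:
    """Replace each missing cell with the minimum present value of its sample."""
    mins = table.data.min(axis=0, skipna=True)
    if mins.isna().any():
        raise ValueError("sample with all values missing")
    return table.replace_values(table.data.fillna(mins), kind=table.kind)


def quantile_normalize(table: QuantTable) -> QuantTable:
    """Map every sample to the mean order-statistic distribution.

    Rank r of each column receives the mean of all columns' r-th order
    statistics; ties within a column receive the average of the target values
    at their tied ranks. Afterwards all column sorted vectors are identical
    (up to tie-induced averaging).
    """
    if table.data.isna().any().any():
        raise ValueError("quantile normalization requires a complete table")
    x = table.data.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        col = x[:, c]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(col.size)
        # average reference values over tied groups
        assigned = reference[ranks].astype(float)
        sorted_col = col[order]
        start = 0
        for i in range(1, col.size + 1):
            if i == col.size or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    assigned[order[start:i]] = reference[start:i].mean()
                start = i
        out[:, c] = assigned
    values = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return table.replace_values(values, kind="FOT_normalized")


def compute_aicap(
    table: QuantTable, control: str = "control", treated: str = "treated"
) -> pd.DataFrame:
    """Per-protein AICAP = mean treated / mean control normalized FOT.

    P-values are two-sided Welch two-sample t-tests on the normalized FOT
    replicates. Proteins with zero control mean are flagged undefined and are
    excluded from rankings downstream.
    """
    ctrl = table.samples_of(control)
    trt = table.samples_of(treated)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need at least 2 replicates per condition")
    xc = table.data[ctrl].to_numpy(dtype=float)
    xt = table.data[trt].to_numpy(dtype=float)
    mean_c = xc.mean(axis=1)
    mean_t = xt.mean(axis=1)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # identical imputed replicate groups trigger a benign precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    defined = mean_c > 0
    aicap = np.where(defined, mean_t / np.where(defined, mean_c, 1.0), np.nan)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    df = pd.DataFrame(
        {
            "protein": table.data.index,
            "aicap": aicap,
            "p_value": p,
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "n_control": len(ctrl),
            "n_treated": len(trt),
            "defined": defined,
        }
    ).set_index("protein")
    df["group"] = [
        assign_aicap_group(a) if d else ""
        for a, d in zip(df["aicap"], df["defined"])
    ]
    return df


def aicap_pipeline(
    table: QuantTable, control: str = "control", treated: str = "treated"
) -> pd.DataFrame:
    """iBAQ -> FOT -> impute -> quantile normalize -> AICAP, in one call."""
    return compute_aicap(
        quantile_normalize(impute_missing(ibaq_to_fot(table))), control, treated
    )


# left-closed bin edges; only the lowest bin label is printed in the source
# figure, the rest follow 0.2-wide steps to 1.1 then open-ended
AICAP_GROUP_EDGES = (0.0, 0.3, 0.5, 0.7, 0.9, 1.1, np.inf)
AICAP_GROUP_LABELS = ("0-0.3", "0.3-0.5", "0.5-0.7", "0.7-0.9", "0.9-1.1", "1.1+")


def assign_aicap_group(aicap: float) -> str:
    """Six AICAP groups on left-closed bins [0,0.3), ..., [1.1, inf)."""
    if not np.isfinite(aicap) or aicap < 0:
        raise ValueError("AICAP must be defined and non-negative")
    k = np.searchsorted(AICAP_GROUP_EDGES, aicap, side="right") - 1
    return AICAP_GROUP_LABELS[k]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    p_value: float
    n_permutations: int
    seed: int
    running_sum: np.ndarray = None


def _running_sum(metric: np.ndarray, is_hit: np.ndarray) -> np.ndarray:
    """Weighted Kolmogorov-Smirnov running sum over a ranked list."""
    n = metric.size
    nh = int(is_hit.sum())
    if nh == n:  # degenerate: every protein is a hit, no deviation possible
        return np.zeros(n)
    hit_total = metric[is_hit].sum()
    steps = np.where(
        is_hit,
        (metric / hit_total) if hit_total > 0 else (1.0 / nh if nh else 0.0),
        -1.0 / (n - nh),
    )
    return np.cumsum(steps)


def preranked_enrichment(
    ranking: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "set",
) -> EnrichmentResult:
    """Preranked enrichment of a protein set at the low-AICAP end.

    Proteins are ranked ascending by AICAP (most sensitive first); the hit
    increment is proportional to the metric max(1 - AICAP, 0), the miss
    decrement 1/(N - N_hits); ES is the signed maximum deviation of the
    running sum. The permutation p-value shuffles set membership labels:
    p = (1 + #{|ES_perm| > |ES|}) / (n_perm + 1); exact ties do not count as
    exceedances, so a maximal observed ES attains the minimal attainable p.
    """
    ranking = ranking.dropna().sort_values(kind="mergesort")
    hits = np.array([p in set(gene_set) for p in ranking.index])
    if not hits.any():
        raise ValueError("gene set does not intersect the ranking")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    metric = np.clip(1.0 - ranking.to_numpy(dtype=float), 0.0, None)
    rs = _running_sum(metric, hits)
    es = float(rs[np.argmax(np.abs(rs))])
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(hits)
        rp = _running_sum(metric, perm)
        if np.max(np.abs(rp)) > abs(es) + 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (n_perm + 1)
    return EnrichmentResult(set_name, es, p, n_perm, seed, rs)


RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
REGION_CLASSES = ("whole", "whole_minus_idr", "idr", "pld")


def _region_sequence(seq: str, regions: pd.DataFrame, cls: str) -> str:
    """Extract the sub-sequence of one region class from interval annotations."""
    if cls == "whole":
        return seq
    mask = np.zeros(len(seq), dtype=bool)
    kinds = {"idr": ("IDR",), "pld": ("PLD",), "whole_minus_idr": ("IDR",)}[cls]
    for _, r in regions.iterrows():
        if r["kind"] in kinds:
            mask[int(r["start"]) : int(r["end"])] = True
    if cls == "whole_minus_idr":
        mask = ~mask
    return "".join(np.array(list(seq))[mask]) if mask.any() else ""


def residue_composition_correlation(
    results: pd.DataFrame, sequences: dict, regions: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho of AICAP vs per-residue fraction, per region class.

    Restricted to proteins with defined AICAP < 1 that have a sequence (and
    region annotations for the IDR/PLD classes). Region classes: whole
    sequence, whole minus IDR, IDR, PLD. Residues absent from every protein
    (constant zero fraction) give NaN.
    """
    sub = results[(results["defined"]) & (results["aicap"] < 1)]
    proteins = [p for p in sub.index if p in sequences]
    if not proteins:
        raise ValueError("no proteins with AICAP < 1 and a sequence")
    rows = []
    for cls in REGION_CLASSES:
        fracs, aicaps = {aa: [] for aa in RESIDUES}, []
        for p in proteins:
            reg = regions[regions["protein"] == p]
            rseq = _region_sequence(sequences[p], reg, cls)
            if not rseq:
                continue  # empty region class for this protein
            aicaps.append(sub.loc[p, "aicap"])
            for aa in RESIDUES:
                fracs[aa].append(rseq.count(aa) / len(rseq))
        for aa in RESIDUES:
            if len(aicaps) >= 3 and len(set(fracs[aa])) > 1:
                rho, _ = stats.spearmanr(aicaps, fracs[aa])
            else:
                rho = np.nan
            rows.append(
                {"residue": aa, "region": cls, "rho": rho, "n_proteins": len(aicaps)}
            )
    return pd.DataFrame(rows)
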