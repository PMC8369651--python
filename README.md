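# hexasense

Quantifying 1,6-hexanediol sensitivity of chromatin-associated proteins and
of higher-order chromatin structure.

1,6-hexanediol (1,6-HD) dissolves biomolecular condensates that depend on
weak hydrophobic interactions, so comparing chromatin composition and
conformation before and after treatment reports which proteins and which
structural features rely on liquid-liquid phase separation. `hexasense`
implements the full desk-side analysis around such an experiment:

* **AICAP** — the *anti-1,6-HD index of chromatin-associated proteins*. From
  label-free quantification tables (iBAQ), each sample is normalized to
  fraction-of-total, FOT_p = iBAQ_p / Σ_p iBAQ_p × 10⁶; missing values are
  imputed with the per-sample minimum (left-censoring assumption) and
  quantile normalization aligns the replicate distributions. Then

      AICAP_p = mean FOT_p(treated) / mean FOT_p(control),

  with a two-sided Welch t-test per protein. AICAP ≪ 1 means the protein is
  stripped from chromatin by 1,6-HD — condensate-like behaviour; AICAP ≈ 1
  is the stable bulk (histone-like); AICAP > 1 typically marks cytoplasmic
  proteins gaining access. Downstream: six sensitivity groups, preranked
  enrichment (weighted Kolmogorov–Smirnov running sum with permutation p),
  and Spearman correlation of AICAP against residue composition in whole /
  ordered / IDR / PLD regions.
* **Hi-C differential structure** — from paired intra-chromosomal contact
  matrices: Knight–Ruiz balancing, observed/expected and Pearson transforms,
  A/B compartments from the leading eigenvector (PC1, sign anchored to gene
  density) with the ±20 % strengthened/stable/weakened/flipped rule on the
  PC1 ratio; insulation-score TAD boundaries (1 Mb sliding square, delta
  vector, strength ≥ 0.1) matched across conditions within ±80 kb; per-loop
  contact-probability change, aggregate peak analysis (APA), differential
  loops under 10 kb anchor slop, stripe aggregation and compartment- or
  chromatin-state-stratified contact statistics.
* **FRAP** — double normalization of recovery traces and nonlinear fitting of
  FRAP(t) = A·(1 − e^(−t/τ)) + y0, giving the mobile fraction A and
  t₁/₂ = τ·ln 2, plus the OLS regression of mobile fraction on AICAP.
* **Synthetic study data** — generators with planted ground truth for all of
  the above (depletion factors, compartment checkerboards, TADs, loops,
  stripes, FRAP parameters), so every stage is validated end-to-end without
  the original deposited datasets.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (about 10 s in total):

```sh
python analysis/01_simulate_study_data.py
python analysis/02_protein_sensitivity.py
python analysis/03_compartment_sensitivity.py
python analysis/04_tad_sensitivity.py
python analysis/05_loop_stripe_sensitivity.py
python analysis/06_frap_mobility.py
```

Output of `02_protein_sensitivity.py`:

```
AICAP computed for 448 proteins; Spearman vs planted depletion = 0.917
proteins per AICAP group: {'0-0.3': 36, '0.3-0.5': 44, '0.5-0.7': 44, '0.7-0.9': 63, '0.9-1.1': 66, '1.1+': 195}
enrichment of 77 strongly-depleted proteins at the low-AICAP end: ES = 0.930, p = 0.000999
hydrophobic residue correlation with AICAP: rho(L, IDR) = -0.78, rho(L, whole) = -0.68 over 220 proteins
```

448 of 500 simulated proteins survive detection; the measured AICAP ranks
the planted depletion factors with ρ = 0.92; strongly depleted
(condensate-like) proteins are enriched at the sensitive end of the ranking;
and hydrophobic residue content in disordered regions anticorrelates with
AICAP, as planted. The other drivers print the structural side: perfect A/B
label recovery at 100 kb, 3/3 planted TAD boundaries recovered within one
bin, a 54 % mean loop-signal decrease for loops planted with a ×0.4
depletion, and FRAP mobile fractions recovered to ±0.01 with a negative
mobile-fraction–AICAP slope.

A thin CLI mirrors the library for shell use, e.g.
`hexasense aicap --table ibaq.tsv --meta meta.tsv --out aicap.tsv` or
`hexasense track-motif --fasta genome.fa --motif GGCC --binsize 500
--out ggcc.bedGraph`; see `hexasense --help`.

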