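"""Generate the simulated study inputs used by the downstream analyses.

Writes, under results/simulated/:
  - a label-free iBAQ table (500 proteins, 3 control + 3 treated replicates,
    20% left-censored missingness) with sample metadata and the planted
    per-protein depletion truth;
  - paired before/after contact matrices for a 20 Mb compartment-scale
    chromosome (100 kb bins) and a TAD/loop-scale chromosome (5 kb bins);
  - a panel of FRAP traces spanning mobile fractions 0.1-0.7.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hexasense.core import GenomeBinning
from hexasense.io_formats import write_contacts, write_quant_table
from hexasense.synthetic import (
    make_hic_truth,
    simulate_frap_trace,
    simulate_hic_pair,
    simulate_quant_experiment,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 0


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # --- proteomics -------------------------------------------------------
    table, truth = simulate_quant_experiment(seed=SEED)
    write_quant_table(table, OUT / "ibaq.tsv")
    pd.DataFrame(
        {
            "sample": table.sample_ids,
            "condition": table.condition[table.sample_ids].to_numpy(),
            "batch": table.batch[table.sample_ids].to_numpy(),
        }
    ).to_csv(OUT / "meta.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "protein": truth.protein_ids,
            "abundance": truth.abundance,
            "depletion": truth.depletion,
            "detected": truth.detected,
        }
    ).to_csv(OUT / "quant_truth.tsv", sep="\t", index=False)
    print(
        f"proteomics: {len(table.protein_ids)} detected of {len(truth.protein_ids)} "
        f"simulated proteins, {table.data.isna().to_numpy().mean():.1%} missing cells"
    )

    # --- compartment-scale Hi-C (100 kb) ---------------------------------
    res = 100_000
    binning = GenomeBinning({"chrC": 200 * res}, res)
    truth_c = make_hic_truth(
        n_bins=200, delta=0.3, weaken="A", weaken_factor=0.5, depth=1e6, seed=SEED
    )
    before, after, truth_c = simulate_hic_pair(binning, "chrC", truth_c)
    write_contacts(before, OUT / "hic_compartment_before.txt")
    write_contacts(after, OUT / "hic_compartment_after.txt")
    (OUT / "hic_compartment_truth.json").write_text(
        json.dumps(
            {
                "resolution": res,
                "compartment_sign": truth_c.compartment_sign.tolist(),
                "boundaries": list(map(int, truth_c.boundaries_before)),
            }
        )
    )
    print(
        f"compartment Hi-C: 200 bins at 100 kb, depth {int(before.count.sum()):,} / "
        f"{int(after.count.sum()):,} contacts (A-compartment strength halved after treatment)"
    )

    # --- TAD/loop-scale Hi-C (5 kb) --------------------------------------
    res = 5000
    binning = GenomeBinning({"chrL": 300 * res}, res)
    truth_l = make_hic_truth(
        n_bins=300, block_size=300, delta=0.0, tad_size=75, tad_factor=2.5,
        n_loops=20, loop_factor=8.0, weaken_factor=0.4, depth=2e6, seed=SEED,
    )
    before_l, after_l, truth_l = simulate_hic_pair(binning, "chrL", truth_l)
    write_contacts(before_l, OUT / "hic_loop_before.txt")
    write_contacts(after_l, OUT / "hic_loop_after.txt")
    (OUT / "hic_loop_truth.json").write_text(
        json.dumps(
            {
                "resolution": res,
                "boundaries": list(map(int, truth_l.boundaries_before)),
                "loops": [[int(i), int(j), fb, fa] for i, j, fb, fa in truth_l.loops],
            }
        )
    )
    print(
        f"loop Hi-C: 300 bins at 5 kb, {len(truth_l.loops)} planted loops "
        f"(factor 8 before, depleted x0.4 after), TADs every 75 bins"
    )

    # --- FRAP traces ------------------------------------------------------
    panel = {
        "PSPC1_like": (0.70, 8.0, 0.15),
        "FUSN_like": (0.55, 12.0, 0.20),
        "RNAPII_CTD_like": (0.45, 15.0, 0.20),
        "WDR43_like": (0.20, 20.0, 0.15),
        "H2B_like": (0.10, 30.0, 0.10),
    }
    times = np.arange(0.0, 101.0)
    rows = []
    for k, (name, (A, tau, y0)) in enumerate(panel.items()):
        tr = simulate_frap_trace(A, tau, y0, times, noise_sd=0.02, seed=SEED + k)
        df = pd.DataFrame(
            {
                "time": tr.times,
                "bleached": tr.normalized * 100.0,  # arbitrary intensity units
                "control": np.full_like(tr.times, 100.0),
                "background": np.zeros_like(tr.times),
            }
        )
        df.to_csv(OUT / f"frap_{name}.tsv", sep="\t", index=False)
        rows.append({"construct": name, "A_true": A, "tau_true": tau, "y0_true": y0})
    pd.DataFrame(rows).to_csv(OUT / "frap_truth.tsv", sep="\t", index=False)
    print(f"FRAP: {len(panel)} traces, 3 pre-bleach + 101 post-bleach frames each")


if __name__ == "__main__":
    main()
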