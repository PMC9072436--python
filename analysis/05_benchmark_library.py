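#!/usr/bin/env python
"""Benchmark the simulated screen like a real library: essential vs
nonessential control separation (ROC-AUC, NNMD), positional balance between
the U6 and H1 expression positions, the promoter effect, and replicate
correlation.

Requires results/sim/ from 02_simulate_screen.py.
Writes results/benchmark/{benchmark.json,roc_curve.tsv}.
"""

import json
from pathlib import Path

import pandas as pd

from dualguide import benchmark as bm
from dualguide import stats as st
from dualguide.design import GuideLibrary

OUT = Path("results/benchmark")


def main():
    counts = pd.read_csv("results/sim/counts.tsv", sep="\t", index_col=0)
    library = GuideLibrary.from_csv("results/sim/library.csv")
    controls = [c.construct_id for c in library if c.category == "control"]
    lfc = st.center_lfc(st.lfc_from_counts(counts), controls)
    eff = st.gene_effects(lfc, library)

    ess = {g for g in eff.single.index if g.startswith("ESS")}
    non = {g for g in eff.single.index if g.startswith("NON")}
    labels = bm.ControlLabels(positives=ess, negatives=non)
    auc, curve = bm.roc_auc(eff.single, labels)
    nnmd_val = bm.nnmd(eff.single[list(ess)], eff.single[list(non)])
    pos = bm.positional_balance(lfc, library, ess, threshold=-1.0)
    prom = bm.promoter_effect(lfc, library)
    rep = bm.replicate_correlation(lfc)

    report = {
        "auc": round(auc, 4),
        "nnmd": round(nnmd_val, 3),
        "positional_r": round(pos.pearson_r, 3),
        "pct_essential_both_positions_below_-1": round(pos.pct_both_below, 1),
        "promoter_delta_median": round(prom.median, 4),
        "promoter_wilcoxon_p": prom.wilcoxon_p,
        "replicate_r_min": round(float(rep.min().min()), 3),
    }
    OUT.mkdir(parents=True, exist_ok=True)
    curve.to_csv(OUT / "roc_curve.tsv", sep="\t", index=False)
    with open(OUT / "benchmark.json", "w") as fh:
        json.dump(report, fh, indent=2)

    print(f"essential/nonessential separation: AUC = {report['auc']}, "
          f"NNMD = {report['nnmd']}")
    print(f"positional balance: r = {report['positional_r']}, "
          f"{report['pct_essential_both_positions_below_-1']}% of essential "
          "genes below -1 in both positions")
    print(f"promoter effect (U6 - H1): median delta = "
          f"{report['promoter_delta_median']} "
          f"(Wilcoxon p = {report['promoter_wilcoxon_p']:.2e}) — the U6 "
          "position depletes more, consistent with the simulated bias")
    print(f"minimum replicate correlation: {report['replicate_r_min']}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
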