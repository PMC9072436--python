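#!/usr/bin/env python
"""Select control genes and synthetic-lethal paralog pairs on a synthetic
dependency cohort (200 cell lines, 50 paralog pairs, 10 planted
synthetic-lethal).

Pipeline: pan-essential / nonessential gene thresholds on the CRISPR and
RNAi dependency matrices, loss-of-function matrix from copy number +
truncating mutations, directed KS/Fisher two-class tests with BH FDR and
top-decile percentile selection, and expression-silent nonessential pairs.

Writes results/controls/{controls.json,pair_tests.tsv}.
"""

import json
from pathlib import Path

from dualguide import controls as ctl
from dualguide.simulate import CohortConfig, simulate_depmap_cohort

OUT = Path("results/controls")
SEED = 0


def main():
    cohort = simulate_depmap_cohort(CohortConfig(n_lines=200, n_pairs=50,
                                                 n_sl_pairs=10, seed=SEED))
    ess = ctl.select_pan_essential(cohort.dep_crispr, cohort.dep_rnai)
    non = ctl.select_nonessential(cohort.dep_crispr, cohort.dep_rnai)
    lof = ctl.build_lof_matrix(cohort.cn_log2, cohort.mutations)
    tests = ctl.test_paralog_dependency(cohort.dep_crispr, lof, cohort.pairs)
    picked = ctl.selected_pairs(tests)
    ness_pairs = ctl.select_nonessential_pairs(cohort.expression, cohort.pairs)

    OUT.mkdir(parents=True, exist_ok=True)
    tests.to_csv(OUT / "pair_tests.tsv", sep="\t", index=False)
    with open(OUT / "controls.json", "w") as fh:
        json.dump({"pan_essential": sorted(ess), "nonessential": sorted(non),
                   "selected_sl_pairs": sorted(map(list, picked)),
                   "nonessential_pairs": sorted(map(list, ness_pairs))},
                  fh, indent=2)

    truth = cohort.true_sl_pairs
    print(f"pan-essential genes selected: {len(ess)}/"
          f"{len(cohort.essential_genes)} planted "
          f"(false: {len(ess - set(cohort.essential_genes))})")
    print(f"nonessential genes selected: {len(non)}/"
          f"{len(cohort.nonessential_genes)} planted "
          f"(false: {len(non - set(cohort.nonessential_genes))})")
    print(f"LOF matrix: {int(lof.to_numpy().sum())} loss-of-function calls")
    print(f"synthetic-lethal pairs: {len(picked & truth)}/{len(truth)} "
          f"recovered, {len(picked - truth)} false call(s)")
    print(f"expression-silent nonessential pairs: {len(ness_pairs)} "
          f"(planted: {len(cohort.silent_pairs)}, "
          f"recovered: {len(ness_pairs & cohort.silent_pairs)})")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
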