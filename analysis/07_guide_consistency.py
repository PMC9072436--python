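#!/usr/bin/env python
"""Train the guide-agreement classifier on a planted-signal guide x cell-line
LFC matrix and select consistent guide groups.

A quarter of guides are simulated inert (pure noise): they should fail the
agreement-score > 0.7 group selection, while the classifier separates
same-gene from random-gene pairs with high holdout AUC.

Writes results/consistency/{agreement_scores.tsv,selected_guides.tsv,
model_card.json}.
"""

import json
from pathlib import Path

import pandas as pd

from dualguide import consistency as cons
from dualguide.simulate import simulate_guide_lfc_matrix

OUT = Path("results/consistency")
SEED = 0


def main():
    matrix, gene_map = simulate_guide_lfc_matrix(
        n_genes=80, guides_per_gene=6, n_lines=30,
        gene_sd=1.0, guide_noise_sd=0.25, inert_fraction=0.25, seed=SEED)
    model = cons.train_consistency_model(matrix, gene_map, seed=SEED)
    scores = cons.score_within_gene_pairs(model, matrix, gene_map)
    selected = cons.select_consistent_guides(scores, threshold=0.7, min_group=3)

    OUT.mkdir(parents=True, exist_ok=True)
    scores.to_csv(OUT / "agreement_scores.tsv", sep="\t", index=False)
    rows = [(g, gid) for g, gs in sorted(selected.items()) for gid in sorted(gs)]
    pd.DataFrame(rows, columns=["gene", "guide_id"]).to_csv(
        OUT / "selected_guides.tsv", sep="\t", index=False)
    with open(OUT / "model_card.json", "w") as fh:
        json.dump({"holdout_auc": model.holdout_auc,
                   "n_same_pairs": model.n_same, "n_random_pairs": model.n_random,
                   "features": cons.FEATURE_NAMES}, fh, indent=2)

    n_sel = sum(len(g) for g in selected.values())
    print(f"training pairs: {model.n_same} same-gene, {model.n_random} random")
    print(f"holdout AUC: {model.holdout_auc:.3f}")
    print(f"genes with a consistent group (>= 3 guides, score > 0.7): "
          f"{len(selected)}/80")
    print(f"guides selected: {n_sel}/{len(matrix)} "
          "(inert guides should be the ones rejected)")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
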