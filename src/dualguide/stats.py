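"""Screen statistics: normalization, log fold-changes, single/double gene
effects, synergy scores, Gaussian-mixture null p-values and BH FDR.

The synergy (sensitive-lethality) score of a paralog pair compares the
double-knockout depletion with the more lethal of the two single knockouts:

    score(a, b) = min(E_single(a), E_single(b)) - E_double(a, b)

so a positive score means the double knockout depletes more than the
strongest single — genetic synergy. Significance comes from the right tail
of a Gaussian mixture fitted to scores of non-synergistic (null) pairs,
followed by Benjamini-Hochberg correction.

Note the guide-level latent-efficacy modeling of the full GEMINI package is
intentionally not reproduced here; effects are replicate-pooled means of
construct LFCs, which is the computation this pipeline defines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .design import GuideLibrary, NEUTRAL_GENE


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 counts-per-million per sample: log2((x + pc) / column_total * 1e6)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    return np.log2((counts + pseudocount).div(totals, axis=1) * 1e6)


def compute_lfc(gdna_norm: pd.DataFrame, pdna_norm: pd.Series) -> pd.DataFrame:
    """Per-replicate LFC = normalized gDNA - normalized pDNA, plus the
    across-replicate mean in a 'mean' column."""
    if not gdna_norm.index.equals(pdna_norm.index):
        raise ValueError("gDNA and pDNA construct indices differ")
    lfc = gdna_norm.sub(pdna_norm, axis=0)
    lfc["mean"] = lfc.mean(axis=1)
    return lfc


def lfc_from_counts(counts: pd.DataFrame, pdna_col: str = "pDNA",
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Convenience: normalize a counts matrix and difference against pDNA."""
    norm = normalize_counts(counts, pseudocount)
    reps = [c for c in counts.columns if c != pdna_col]
    if not reps:
        raise ValueError("no gDNA replicate columns found")
    return compute_lfc(norm[reps], norm[pdna_col])


def center_lfc(lfc: pd.DataFrame, control_ids) -> pd.DataFrame:
    """Center each replicate on the median LFC of neutral control constructs.

    Sequencing depth is compositional: when essential constructs drop out,
    every non-depleting construct gains relative abundance, shifting all raw
    LFCs upward. Anchoring each replicate on the neutral-neutral controls
    (true LFC 0) removes that shift. The across-replicate mean is recomputed.
    """
    ids = [c for c in control_ids if c in lfc.index]
    if not ids:
        raise ValueError("no control constructs found in the LFC table")
    reps = lfc.drop(columns=["mean"], errors="ignore")
    centered = reps - reps.loc[ids].median(axis=0)
    centered["mean"] = centered.mean(axis=1)
    return centered


def pair_key(a: str, b: str) -> str:
    """Canonical orientation-free label for a gene pair."""
    return "|".join(sorted((a, b)))


@dataclass
class GeneEffects:
    single: pd.Series  # gene -> mean LFC of its guide+neutral constructs
    double: pd.Series  # "A|B" -> mean LFC of the pair's constructs
    missing: list[str]


def gene_effects(lfc: pd.DataFrame, library: GuideLibrary,
                 neutral_gene: str = NEUTRAL_GENE) -> GeneEffects:
    """Single effects from guide+neutral constructs (both positions pooled);
    double effects from pair constructs (both orientations pooled)."""
    mean_lfc = lfc["mean"] if "mean" in lfc.columns else lfc.mean(axis=1)
    single_vals: dict[str, list[float]] = {}
    double_vals: dict[str, list[float]] = {}
    for c in library:
        if c.construct_id not in mean_lfc.index:
            continue
        v = float(mean_lfc[c.construct_id])
        if c.category == "single_left":
            single_vals.setdefault(c.gene_left, []).append(v)
        elif c.category == "single_right":
            single_vals.setdefault(c.gene_right, []).append(v)
        elif c.category == "pair":
            double_vals.setdefault(pair_key(c.gene_left, c.gene_right), []).append(v)
    all_genes = {c.gene_left for c in library} | {c.gene_right for c in library}
    missing = sorted(all_genes - set(single_vals) - {neutral_gene})
    single = pd.Series({g: float(np.mean(v)) for g, v in single_vals.items()},
                       name="single_effect").sort_index()
    double = pd.Series({p: float(np.mean(v)) for p, v in double_vals.items()},
                       name="double_effect").sort_index()
    return GeneEffects(single=single, double=double, missing=missing)


def synergy_score(effects: GeneEffects) -> pd.Series:
    """score(a,b) = min(single_a, single_b) - double_ab; positive = synergistic."""
    scores = {}
    for pk in effects.double.index:
        a, b = pk.split("|")
        if a not in effects.single.index or b not in effects.single.index:
            continue
        scores[pk] = min(effects.single[a], effects.single[b]) - effects.double[pk]
    return pd.Series(scores, name="synergy_score").sort_index()


@dataclass
class NullModel:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    k: int
    bic: float

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "means": self.means.tolist(),
                "sds": self.sds.tolist(), "k": self.k, "bic": self.bic}


def fit_null_gmm(null_scores, k_candidates=(1, 2, 3), seed: int = 0,
                 min_scores: int = 20) -> NullModel:
    """EM fit of a 1-D Gaussian mixture to null synergy scores, model order
    chosen by BIC. Variance floor 1e-6 guards degenerate (constant) input."""
    x = np.asarray(null_scores, dtype=float).reshape(-1, 1)
    if len(x) < min_scores:
        raise ValueError(f"need at least {min_scores} null scores, got {len(x)}")
    best: NullModel | None = None
    for k in sorted(k_candidates):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=1e-6, tol=1e-8, max_iter=500,
                             n_init=5, random_state=seed)
        gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best.bic:
            best = NullModel(weights=gm.weights_.copy(),
                             means=gm.means_.ravel().copy(),
                             sds=np.sqrt(gm.covariances_.ravel()).copy(),
                             k=k, bic=float(bic))
    assert best is not None
    return best


def synergy_pvalues(scores: pd.Series, null: NullModel) -> pd.Series:
    """Right-tail mixture probability: p(s) = sum_j w_j * (1 - Phi((s-mu_j)/sd_j))."""
    s = np.asarray(scores, dtype=float)[:, None]
    tails = sps.norm.sf((s - null.means[None, :]) / null.sds[None, :])
    p = (tails * null.weights[None, :]).sum(axis=1)
    return pd.Series(np.clip(p, np.finfo(float).tiny, 1.0), index=scores.index,
                     name="p_value")


def bh_fdr(p_values) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, ties stable)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="fdr")
    return q


def score_screen(counts: pd.DataFrame, library: GuideLibrary,
                 null_pairs: list[str], seed: int = 0,
                 pseudocount: float = 1.0,
                 k_candidates=(1, 2, 3)) -> pd.DataFrame:
    """Counts-to-synergy pipeline for one screen.

    null_pairs are orientation-free pair labels ("A|B") of non-synergistic
    pairs used to fit the Gaussian-mixture null. Returns a per-pair table
    with effects, score, p and FDR.
    """
    lfc = lfc_from_counts(counts, pseudocount=pseudocount)
    eff = gene_effects(lfc, library)
    scores = synergy_score(eff)
    null_scores = scores.loc[[p for p in null_pairs if p in scores.index]]
    null = fit_null_gmm(null_scores.to_numpy(), k_candidates=k_candidates, seed=seed)
    p = synergy_pvalues(scores, null)
    q = bh_fdr(p)
    out = pd.DataFrame({"score": scores, "p_value": p, "fdr": q})
    singles = {pk: (eff.single[pk.split("|")[0]], eff.single[pk.split("|")[1]])
               for pk in out.index}
    out.insert(0, "single_b", pd.Series({k: v[1] for k, v in singles.items()}))
    out.insert(0, "single_a", pd.Series({k: v[0] for k, v in singles.items()}))
    out.insert(2, "double", eff.double.reindex(out.index))
    out.attrs["null_model"] = null.to_dict()
    return out.rename_axis("pair")
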