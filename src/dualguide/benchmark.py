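"""Library-quality metrics: control separation (ROC-AUC, NNMD), positional
balance between the two expression positions, tracrRNA-flip and promoter
effects, and replicate correlation.

Scores throughout are LFC-like: lower = stronger depletion = positive class
(essential). AUC is computed on negated scores so that good separation gives
AUC > 0.5; NNMD is negative when essentials separate from nonessentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve, roc_auc_score

from .design import GuideLibrary
from .stats import pair_key


@dataclass
class ControlLabels:
    positives: set[str]  # essential genes or pairs
    negatives: set[str]

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both control sets must be nonempty")
        if self.positives & self.negatives:
            raise ValueError("control sets overlap")


def roc_auc(scores: pd.Series, labels: ControlLabels,
            lower_is_positive: bool = True) -> tuple[float, pd.DataFrame]:
    """AUC for separating the two control sets by score threshold sweep.

    Equivalent to the Mann-Whitney rank statistic with tie correction
    (trapezoid over the tied thresholds). Items without a label are ignored.
    """
    items = [i for i in scores.index if i in labels.positives or i in labels.negatives]
    y = np.array([1 if i in labels.positives else 0 for i in items])
    if y.all() or not y.any():
        raise ValueError("need scores from both control classes")
    x = scores.loc[items].to_numpy(dtype=float)
    if lower_is_positive:
        x = -x
    fpr, tpr, thr = roc_curve(y, x)
    auc = float(roc_auc_score(y, x))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def nnmd(essential_scores, nonessential_scores, robust: bool = True) -> float:
    """Null-normalized median difference; more negative = better separation.

    robust=True (default): (median(ess) - median(non)) / (1.4826 * MAD(non)).
    robust=False: the mean/SD variant used by some dependency pipelines.
    """
    e = np.asarray(essential_scores, dtype=float)
    n = np.asarray(nonessential_scores, dtype=float)
    if len(e) < 3 or len(n) < 3:
        raise ValueError("need at least 3 scores per control set")
    if robust:
        spread = sps.median_abs_deviation(n, scale="normal")
        if spread == 0:
            raise ValueError("nonessential MAD is zero; scores are degenerate "
                             "(try robust=False or check the input)")
        return float((np.median(e) - np.median(n)) / spread)
    sd = n.std(ddof=1)
    if sd == 0:
        raise ValueError("nonessential SD is zero")
    return float((e.mean() - n.mean()) / sd)


@dataclass
class PositionalBalance:
    pearson_r: float
    pct_both_below: float  # % of essential genes with both position means < threshold
    per_gene: pd.DataFrame  # gene x (left_lfc, right_lfc)
    n_excluded: int


def positional_balance(lfc: pd.DataFrame, library: GuideLibrary,
                       essential_genes: set[str],
                       threshold: float = -1.0) -> PositionalBalance:
    """Mean single-construct LFC per gene in the left vs right position."""
    mean_lfc = lfc["mean"] if "mean" in lfc.columns else lfc.mean(axis=1)
    left: dict[str, list[float]] = {}
    right: dict[str, list[float]] = {}
    for c in library:
        if c.construct_id not in mean_lfc.index:
            continue
        v = float(mean_lfc[c.construct_id])
        if c.category == "single_left":
            left.setdefault(c.gene_left, []).append(v)
        elif c.category == "single_right":
            right.setdefault(c.gene_right, []).append(v)
    genes = sorted(set(left) & set(right))
    n_excluded = len((set(left) | set(right)) - set(genes))
    per_gene = pd.DataFrame({
        "left_lfc": [np.mean(left[g]) for g in genes],
        "right_lfc": [np.mean(right[g]) for g in genes],
    }, index=pd.Index(genes, name="gene"))
    r = float(per_gene["left_lfc"].corr(per_gene["right_lfc"]))
    ess = per_gene.loc[per_gene.index.isin(essential_genes)]
    pct = float(100.0 * ((ess["left_lfc"] < threshold) & (ess["right_lfc"] < threshold)).mean()) \
        if len(ess) else float("nan")
    return PositionalBalance(pearson_r=r, pct_both_below=pct,
                             per_gene=per_gene, n_excluded=n_excluded)


@dataclass
class TracrEffect:
    deltas: pd.DataFrame  # matched construct x (delta, promoter stratum)
    mean: float
    sd: float
    p_value: float  # location test of the deltas against 0
    n_unmatched: int


def tracr_effect(lfc_lib1: pd.DataFrame, lfc_lib2_flipped: pd.DataFrame,
                 library1: GuideLibrary, library2: GuideLibrary) -> TracrEffect:
    """LFC difference between the two scaffolds from a library and its
    tracr-flipped twin, matched per crRNA pair (same spacers and promoters,
    swapped scaffolds). delta = LFC(lib1) - LFC(lib2); under equal scaffold
    efficacies the deltas center on zero.
    """
    m1 = lfc_lib1["mean"] if "mean" in lfc_lib1.columns else lfc_lib1.mean(axis=1)
    m2 = lfc_lib2_flipped["mean"] if "mean" in lfc_lib2_flipped.columns else lfc_lib2_flipped.mean(axis=1)
    key1 = {(c.crRNA_left, c.crRNA_right): c.construct_id for c in library1}
    key2 = {(c.crRNA_left, c.crRNA_right): c.construct_id for c in library2}
    cat1 = {c.construct_id: c.category for c in library1}
    shared = [k for k in key1 if k in key2
              and key1[k] in m1.index and key2[k] in m2.index]
    n_unmatched = len(set(key1) ^ set(key2))
    if not shared:
        raise ValueError("no constructs shared between the two libraries")
    rows = {key1[k]: (float(m1[key1[k]] - m2[key2[k]]), cat1[key1[k]]) for k in shared}
    deltas = pd.DataFrame.from_dict(rows, orient="index", columns=["delta", "category"])
    d = deltas["delta"].to_numpy()
    stat = sps.ttest_1samp(d, 0.0)
    return TracrEffect(deltas=deltas, mean=float(d.mean()), sd=float(d.std(ddof=1)),
                       p_value=float(stat.pvalue), n_unmatched=n_unmatched)


@dataclass
class PromoterEffect:
    deltas: pd.Series  # per crRNA: LFC(U6 position) - LFC(H1 position)
    median: float
    wilcoxon_p: float


def promoter_effect(lfc: pd.DataFrame, library: GuideLibrary,
                    crRNA_subset: set[str] | None = None) -> PromoterEffect:
    """Paired U6-vs-H1 comparison for crRNAs present under both promoters.

    Uses single-gene constructs where the same gene spacer appears in the
    left (U6) and right (H1) position; delta = LFC(U6) - LFC(H1) per spacer,
    Wilcoxon signed-rank test against symmetry around zero.
    """
    mean_lfc = lfc["mean"] if "mean" in lfc.columns else lfc.mean(axis=1)
    u6: dict[str, list[float]] = {}
    h1: dict[str, list[float]] = {}
    for c in library:
        if c.construct_id not in mean_lfc.index:
            continue
        v = float(mean_lfc[c.construct_id])
        if c.category == "single_left":
            u6.setdefault(c.crRNA_left, []).append(v)
        elif c.category == "single_right":
            h1.setdefault(c.crRNA_right, []).append(v)
    shared = sorted(set(u6) & set(h1))
    if crRNA_subset is not None:
        shared = [s for s in shared if s in crRNA_subset]
    if len(shared) < 2:
        raise ValueError("need >= 2 crRNAs present under both promoters")
    deltas = pd.Series({s: np.mean(u6[s]) - np.mean(h1[s]) for s in shared},
                       name="delta")
    if np.allclose(deltas, 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(deltas.to_numpy()).pvalue)
    return PromoterEffect(deltas=deltas, median=float(deltas.median()), wilcoxon_p=p)


def replicate_correlation(lfc: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson matrix over replicate columns (diagonal 1; a constant
    replicate yields NaN against the others)."""
    reps = lfc.drop(columns=["mean"], errors="ignore")
    if reps.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    return reps.corr(method="pearson")
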