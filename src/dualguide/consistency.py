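"""Guide-consistency scoring: discriminate same-gene from random-gene guide
pairs across cell lines with a random-forest agreement classifier, then
select per-gene groups of mutually consistent guides.

The feature set (correlations, profile distance, spread ratio, co-extreme
membership) is this package's own; it is a re-implementation in the spirit
of the published approach, whose exact agreement metrics and forest
hyperparameters were not specified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._util import split_rng

FEATURE_NAMES = ["pearson_r", "spearman_r", "mean_abs_diff", "sd_ratio",
                 "top_decile_overlap"]
MIN_SHARED_LINES = 10


def agreement_features(matrix: pd.DataFrame, guide_a: str, guide_b: str,
                       min_shared: int = MIN_SHARED_LINES) -> np.ndarray | None:
    """Symmetric agreement feature vector for one guide pair.

    Features over the shared non-missing cell lines: Pearson r, Spearman r,
    mean |difference|, SD ratio (min/max), and the overlap fraction of the
    two guides' own most-depleted deciles. None when fewer than min_shared
    lines are shared.
    """
    a = matrix.loc[guide_a]
    b = matrix.loc[guide_b]
    mask = a.notna() & b.notna()
    if int(mask.sum()) < min_shared:
        return None
    x = a[mask].to_numpy(dtype=float)
    y = b[mask].to_numpy(dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        pear = spear = 0.0
    else:
        pear = float(np.corrcoef(x, y)[0, 1])
        spear = float(sps.spearmanr(x, y).statistic)
    mad = float(np.mean(np.abs(x - y)))
    sd_ratio = float(min(sx, sy) / max(sx, sy)) if max(sx, sy) > 0 else 1.0
    k = max(1, len(x) // 10)
    top_x = set(np.argsort(x)[:k])  # most depleted (lowest LFC)
    top_y = set(np.argsort(y)[:k])
    overlap = len(top_x & top_y) / k
    return np.array([pear, spear, mad, sd_ratio, overlap])


@dataclass
class ConsistencyModel:
    classifier: RandomForestClassifier
    holdout_auc: float
    n_same: int
    n_random: int

    def score_pairs(self, matrix: pd.DataFrame,
                    pairs: list[tuple[str, str]]) -> pd.Series:
        """Agreement score (probability of same-gene) per guide pair."""
        feats, keep = [], []
        for a, b in pairs:
            f = agreement_features(matrix, a, b)
            if f is not None:
                feats.append(f)
                keep.append((a, b))
        if not feats:
            return pd.Series(dtype=float)
        probs = self.classifier.predict_proba(np.vstack(feats))[:, 1]
        return pd.Series(probs, index=pd.MultiIndex.from_tuples(keep))


def _sample_pairs(matrix: pd.DataFrame, gene_map: pd.Series, n_same: int,
                  n_random: int, rng: np.random.Generator):
    """Sample distinct same-gene and distinct cross-gene guide pairs.

    Pairs are unique: a duplicated pair would leak identical feature vectors
    across the holdout split and inflate the reported AUC.
    """
    guides = [g for g in matrix.index if g in gene_map.index]
    by_gene: dict[str, list[str]] = {}
    for g in guides:
        by_gene.setdefault(gene_map[g], []).append(g)
    multi = [gs for gs in by_gene.values() if len(gs) >= 2]
    if len(multi) < 2:
        raise ValueError("need at least 2 genes with >= 2 guides each")

    all_same = [(gs[i], gs[j]) for gs in multi
                for i in range(len(gs)) for j in range(i + 1, len(gs))]
    order = rng.permutation(len(all_same))
    same = [all_same[i] for i in order[:n_same]]

    genes = list(by_gene)
    seen: set[tuple[str, str]] = set()
    rand: list[tuple[str, str]] = []
    attempts = 0
    while len(rand) < n_random and attempts < 50 * n_random:
        attempts += 1
        ga, gb = rng.choice(len(genes), size=2, replace=False)
        a = by_gene[genes[ga]][int(rng.integers(len(by_gene[genes[ga]])))]
        b = by_gene[genes[gb]][int(rng.integers(len(by_gene[genes[gb]])))]
        key = (a, b) if a < b else (b, a)
        if key not in seen:
            seen.add(key)
            rand.append(key)
    return same, rand


def train_consistency_model(matrix: pd.DataFrame, gene_map: pd.Series,
                            n_same: int = 5000, n_random: int = 5000,
                            seed: int = 0, n_trees: int = 200,
                            min_samples_leaf: int = 20,
                            holdout_fraction: float = 0.25) -> ConsistencyModel:
    """Train the same-gene vs random-gene pair classifier.

    Samples up to n_same distinct within-gene and n_random distinct
    cross-gene pairs (scaled down automatically when the input is small),
    computes agreement features, trains a random forest, and reports the
    stratified holdout AUC. min_samples_leaf keeps leaves averaged over many
    pairs so that scoring a pair the forest has seen does not just replay its
    training label (within-gene pairs are later scored with this model).
    """
    rng = split_rng(seed, 101)
    n_guides = len(matrix)
    cap = max(50, 5 * n_guides)
    n_same = min(n_same, cap)
    n_random = min(n_random, cap)
    same, rand = _sample_pairs(matrix, gene_map, n_same, n_random, rng)

    feats, labels = [], []
    for label, pairs in ((1, same), (0, rand)):
        for a, b in pairs:
            f = agreement_features(matrix, a, b)
            if f is not None:
                feats.append(f)
                labels.append(label)
    X = np.vstack(feats)
    y = np.array(labels)
    if len(set(y)) < 2:
        raise ValueError("could not build both training classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed)
    clf = RandomForestClassifier(n_estimators=n_trees,
                                 min_samples_leaf=min_samples_leaf,
                                 random_state=seed)
    clf.fit(X_tr, y_tr)
    auc = float(roc_auc_score(y_te, clf.predict_proba(X_te)[:, 1]))
    return ConsistencyModel(classifier=clf, holdout_auc=auc,
                            n_same=len(same), n_random=len(rand))


def score_within_gene_pairs(model: ConsistencyModel, matrix: pd.DataFrame,
                            gene_map: pd.Series) -> pd.DataFrame:
    """Agreement scores for every within-gene guide pair."""
    rows = []
    by_gene: dict[str, list[str]] = {}
    for g in matrix.index:
        if g in gene_map.index:
            by_gene.setdefault(gene_map[g], []).append(g)
    for gene, gs in by_gene.items():
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                f = agreement_features(matrix, gs[i], gs[j])
                if f is None:
                    continue
                p = float(model.classifier.predict_proba(f[None, :])[0, 1])
                rows.append((gene, gs[i], gs[j], p))
    return pd.DataFrame(rows, columns=["gene", "guide_a", "guide_b", "score"])


def select_consistent_guides(scores: pd.DataFrame, threshold: float = 0.7,
                             min_group: int = 3) -> dict[str, set[str]]:
    """Per gene, the largest connected component of the agreement graph.

    Guides are nodes; edges join pairs with agreement score > threshold.
    A gene contributes its largest component when it has at least min_group
    members, otherwise nothing.
    """
    out: dict[str, set[str]] = {}
    for gene, sub in scores.groupby("gene"):
        adj: dict[str, set[str]] = {}
        for _, row in sub.iterrows():
            adj.setdefault(row["guide_a"], set())
            adj.setdefault(row["guide_b"], set())
            if row["score"] > threshold:
                adj[row["guide_a"]].add(row["guide_b"])
                adj[row["guide_b"]].add(row["guide_a"])
        seen: set[str] = set()
        best: set[str] = set()
        for node in adj:
            if node in seen:
                continue
            comp, stack = set(), [node]
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            if len(comp) > len(best) or (len(comp) == len(best) and sorted(comp) < sorted(best)):
                best = comp
        if len(best) >= min_group:
            out[gene] = best
    return out
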