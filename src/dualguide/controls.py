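"""Control-gene and synthetic-lethal paralog-pair selection from
DepMap-style matrices (cell line x gene).

Pan-essential genes show strong dependency in nearly all lines in both the
CRISPR (probability > 0.8 in > 90% of lines) and RNAi (> 0.5 in > 50%)
datasets; nonessential genes show low dependency nearly everywhere (< 0.2 in
> 96% / > 95% of lines). The printed thresholds are strict inequalities and
are kept strict here.

Synthetic-lethal pair candidates are found by a two-class comparison of a
gene's dependency scores grouped by loss-of-function (LOF) of its paralog
partner: a one-sided Kolmogorov-Smirnov test on the continuous scores and a
one-sided Fisher's exact test on the scores binarized at 0.5, each
BH-adjusted across all tested pairs. A pair is selected when at least one
test reaches FDR < 0.05 and the mean significance percentile of the two
tests is in the top 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

DELETERIOUS_CLASSES = {"frameshift", "nonsense"}


def _fraction_of_lines(dep: pd.DataFrame, cmp, prob: float) -> pd.Series:
    """Per gene, the fraction of (non-missing) lines where cmp(dep, prob)."""
    ok = cmp(dep, prob)
    return ok.sum(axis=0) / dep.notna().sum(axis=0)


def select_pan_essential(dep_crispr: pd.DataFrame, dep_rnai: pd.DataFrame,
                         crispr_prob: float = 0.8, crispr_frac: float = 0.90,
                         rnai_prob: float = 0.5, rnai_frac: float = 0.50) -> set[str]:
    """Genes with dependency probability > crispr_prob in > crispr_frac of
    lines (CRISPR) AND > rnai_prob in > rnai_frac of lines (RNAi)."""
    shared = dep_crispr.columns.intersection(dep_rnai.columns)
    if shared.empty:
        raise ValueError("CRISPR and RNAi gene universes do not overlap")
    fc = _fraction_of_lines(dep_crispr[shared], lambda d, p: d > p, crispr_prob)
    fr = _fraction_of_lines(dep_rnai[shared], lambda d, p: d > p, rnai_prob)
    return set(shared[(fc > crispr_frac) & (fr > rnai_frac)])


def select_nonessential(dep_crispr: pd.DataFrame, dep_rnai: pd.DataFrame,
                        prob: float = 0.2, crispr_frac: float = 0.96,
                        rnai_frac: float = 0.95) -> set[str]:
    """Genes with dependency probability < prob in > 96% (CRISPR) and > 95%
    (RNAi) of lines."""
    shared = dep_crispr.columns.intersection(dep_rnai.columns)
    if shared.empty:
        raise ValueError("CRISPR and RNAi gene universes do not overlap")
    fc = _fraction_of_lines(dep_crispr[shared], lambda d, p: d < p, prob)
    fr = _fraction_of_lines(dep_rnai[shared], lambda d, p: d < p, prob)
    return set(shared[(fc > crispr_frac) & (fr > rnai_frac)])


def build_lof_matrix(cn_log2_relative: pd.DataFrame,
                     mutations: pd.DataFrame) -> pd.DataFrame:
    """Binary LOF call: copy number at least 2 SD below the gene's
    across-line mean, OR a truncating (frameshift / nonsense) mutation.

    A zero-variance gene can never satisfy the copy-number clause; its
    mutation clause still applies.
    """
    idx = cn_log2_relative.index.intersection(mutations.index)
    cols = cn_log2_relative.columns.intersection(mutations.columns)
    if idx.empty or cols.empty:
        raise ValueError("copy-number and mutation matrices share no lines/genes")
    cn = cn_log2_relative.loc[idx, cols]
    mut = mutations.loc[idx, cols].fillna("")
    mu = cn.mean(axis=0)
    sd = cn.std(axis=0, ddof=1)
    low_cn = cn.le(mu - 2.0 * sd, axis=1) & (sd > 0)
    deleterious = mut.isin(DELETERIOUS_CLASSES)
    return (low_cn | deleterious)


@dataclass
class PairTestResult:
    gene: str          # the gene whose dependency is tested
    partner: str       # the paralog whose LOF defines the two classes
    n_lof_lines: int
    ks_p: float
    fisher_p: float
    ks_fdr: float = float("nan")
    fisher_fdr: float = float("nan")
    mean_percentile: float = float("nan")
    selected: bool = False


def _directed_test(dep_gene: pd.Series, lof_partner: pd.Series,
                   min_lof_lines: int) -> tuple[int, float, float] | None:
    mask = dep_gene.notna() & lof_partner.notna()
    dep = dep_gene[mask]
    lof = lof_partner[mask].astype(bool)
    n_lof = int(lof.sum())
    if n_lof < min_lof_lines or n_lof == len(dep):
        return None
    dep_lof = dep[lof].to_numpy()
    dep_rest = dep[~lof].to_numpy()
    # one-sided KS: LOF-group dependency stochastically greater, i.e. its
    # empirical CDF lies below the rest's
    ks = sps.ks_2samp(dep_lof, dep_rest, alternative="less")
    table = [[int((dep_lof >= 0.5).sum()), int((dep_lof < 0.5).sum())],
             [int((dep_rest >= 0.5).sum()), int((dep_rest < 0.5).sum())]]
    fisher = sps.fisher_exact(table, alternative="greater")
    return n_lof, float(ks.pvalue), float(fisher[1])


def test_paralog_dependency(dep: pd.DataFrame, lof: pd.DataFrame,
                            pairs: list[tuple[str, str]],
                            min_lof_lines: int = 3,
                            fdr_threshold: float = 0.05,
                            percentile_threshold: float = 0.9) -> pd.DataFrame:
    """Directed two-class tests for every pair, both directions.

    For pair (A, B) the dependency of A is compared between B-LOF lines and
    the rest (and symmetrically). FDR adjustment is per test family (KS,
    Fisher) across all tested directions; the significance percentile of a p
    is the fraction of tested directions with p at least as large (smaller
    p -> percentile closer to 1). selected = min(FDR) < 0.05 and mean
    percentile >= 0.9.
    """
    results: list[PairTestResult] = []
    skipped: list[tuple[str, str]] = []
    for a, b in pairs:
        for gene, partner in ((a, b), (b, a)):
            if gene not in dep.columns or partner not in lof.columns:
                skipped.append((gene, partner))
                continue
            r = _directed_test(dep[gene], lof[partner], min_lof_lines)
            if r is None:
                skipped.append((gene, partner))
                continue
            n_lof, ks_p, fisher_p = r
            results.append(PairTestResult(gene=gene, partner=partner,
                                          n_lof_lines=n_lof, ks_p=ks_p,
                                          fisher_p=fisher_p))
    if not results:
        raise ValueError("no testable pairs (check LOF group sizes and gene names)")

    df = pd.DataFrame([r.__dict__ for r in results])
    df["ks_fdr"] = bh_fdr(df["ks_p"].to_numpy())
    df["fisher_fdr"] = bh_fdr(df["fisher_p"].to_numpy())
    n = len(df)
    for col, out in (("ks_p", "ks_percentile"), ("fisher_p", "fisher_percentile")):
        # fraction of tested directions with p >= this p (average rank for ties)
        df[out] = 1.0 - (sps.rankdata(df[col], method="average") - 1) / n
    df["mean_percentile"] = (df["ks_percentile"] + df["fisher_percentile"]) / 2
    df["selected"] = ((df[["ks_fdr", "fisher_fdr"]].min(axis=1) < fdr_threshold)
                      & (df["mean_percentile"] >= percentile_threshold))
    df.attrs["skipped"] = skipped
    return df


def selected_pairs(test_results: pd.DataFrame) -> set[tuple[str, str]]:
    """Pool the two directions: a pair is selected if either direction is."""
    out = set()
    for _, row in test_results[test_results["selected"]].iterrows():
        out.add(tuple(sorted((row["gene"], row["partner"]))))
    return out


def select_nonessential_pairs(expression: pd.DataFrame,
                              pairs: list[tuple[str, str]],
                              expr_threshold: float = 0.1,
                              frac_lines: float = 0.90) -> set[tuple[str, str]]:
    """Pairs where both genes have log2(TPM+1) < 0.1 in >= 90% of lines."""
    def _low(g: str) -> bool:
        if g not in expression.columns:
            return False
        col = expression[g].dropna()
        return bool((col < expr_threshold).mean() >= frac_lines)

    return {(a, b) for a, b in pairs if _low(a) and _low(b)}
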