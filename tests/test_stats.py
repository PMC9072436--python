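"""Normalization, LFC, gene effects, synergy scoring, the Gaussian-mixture
null and BH FDR — each against a closed form or brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from conftest import make_guides
from dualguide.design import GuideLibrary, design_pair_constructs, design_single_constructs
from dualguide.stats import (GeneEffects, bh_fdr, compute_lfc, fit_null_gmm,
                             gene_effects, normalize_counts, pair_key,
                             synergy_pvalues, synergy_score)


def _bh_oracle(p):
    """Definition-based step-up: q_i = min over j >= rank(i) of p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestNormalization:
    def test_two_construct_hand_calculation(self):
        counts = pd.DataFrame({"s": [1, 999_999]}, index=["a", "b"])
        norm = normalize_counts(counts, pseudocount=1.0)
        assert norm.loc["a", "s"] == pytest.approx(np.log2((1 + 1) / 1e6 * 1e6))
        assert norm.loc["b", "s"] == pytest.approx(np.log2(1_000_000 / 1e6 * 1e6))

    def test_proportional_columns_agree_at_scale(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1000, 50_000, size=50)
        counts = pd.DataFrame({"s1": base, "s2": base * 3})
        norm = normalize_counts(counts)
        # pseudocount breaks exact scale equivariance; at these depths the
        # columns agree to well under 0.01 log2 units
        assert np.allclose(norm["s1"], norm["s2"], atol=0.01)

    def test_uniform_counts_normalize_identically(self):
        counts = pd.DataFrame({"s": [500] * 8})
        norm = normalize_counts(counts)
        assert norm["s"].nunique() == 1

    def test_zero_total_names_sample(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            normalize_counts(counts)


class TestLfc:
    def test_identical_samples_give_zero(self):
        norm = pd.DataFrame({"r1": [1.0, 2.0], "r2": [1.0, 2.0]})
        lfc = compute_lfc(norm, norm["r1"])
        assert np.allclose(lfc["r1"], 0)

    def test_halved_proportion_gives_minus_one(self):
        # construct a at half its pDNA proportion in gDNA, two-construct toy
        pdna = pd.DataFrame({"pDNA": [200_000, 200_000]}, index=["a", "b"])
        gdna = pd.DataFrame({"rep1": [100_000, 200_000]}, index=["a", "b"])
        n = normalize_counts(pd.concat([pdna, gdna], axis=1), pseudocount=0.0)
        lfc = compute_lfc(n[["rep1"]], n["pDNA"])
        # relative proportion of a halves modulo the shared total shift
        assert (lfc.loc["a", "rep1"] - lfc.loc["b", "rep1"]) == pytest.approx(
            np.log2(0.5), abs=1e-9)

    def test_replicate_index_mismatch_rejected(self):
        g = pd.DataFrame({"r1": [1.0]}, index=["a"])
        p = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError):
            compute_lfc(g, p)


def _toy_library_and_lfc():
    ga, gb = make_guides("A", 2), make_guides("B", 2)
    neutral = make_guides("AAVS1", 1)
    singles = (design_single_constructs(ga, neutral, include_controls=False)
               + design_single_constructs(gb, neutral, include_controls=False))
    pairs = design_pair_constructs(ga, gb)
    lib = GuideLibrary(constructs=singles + pairs)
    vals = {}
    for i, c in enumerate(singles):
        vals[c.construct_id] = -1.0 if c.category == "single_left" else -0.5
    for c in pairs:
        vals[c.construct_id] = -3.0
    lfc = pd.DataFrame({"mean": pd.Series(vals)})
    return lib, lfc


class TestGeneEffects:
    def test_uniform_lfc_gives_uniform_effects(self):
        lib, lfc = _toy_library_and_lfc()
        lfc["mean"] = -1.0
        eff = gene_effects(lfc, lib)
        assert (eff.single == -1.0).all() and (eff.double == -1.0).all()

    def test_toy_means_match_hand_arithmetic(self):
        lib, lfc = _toy_library_and_lfc()
        eff = gene_effects(lfc, lib)
        # each gene: two single_left at -1, two single_right at -0.5
        assert eff.single["A"] == pytest.approx(-0.75)
        assert eff.single["B"] == pytest.approx(-0.75)
        assert eff.double["A|B"] == pytest.approx(-3.0)

    def test_double_effect_pools_both_orientations(self):
        lib, lfc = _toy_library_and_lfc()
        # make the two orientations differ; the pooled mean must see both
        for c in lib:
            if c.category == "pair":
                lfc.loc[c.construct_id, "mean"] = -4.0 if c.gene_left == "A" else -2.0
        eff = gene_effects(lfc, lib)
        assert eff.double["A|B"] == pytest.approx(-3.0)


class TestSynergyScore:
    def test_double_equal_to_min_single_scores_zero(self):
        eff = GeneEffects(single=pd.Series({"A": -1.0, "B": -0.2}),
                          double=pd.Series({"A|B": -1.0}), missing=[])
        assert synergy_score(eff)["A|B"] == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        eff = GeneEffects(single=pd.Series({"A": 0.0, "B": -0.2}),
                          double=pd.Series({"A|B": -1.5}), missing=[])
        assert synergy_score(eff)["A|B"] == pytest.approx(1.3)

    def test_pan_essential_buffering_scores_zero(self):
        # deep single depletion with an equal double is NOT synergy
        eff = GeneEffects(single=pd.Series({"A": -3.0, "B": -2.8}),
                          double=pd.Series({"A|B": -3.0}), missing=[])
        assert synergy_score(eff)["A|B"] == pytest.approx(0.0)

    def test_symmetric_in_pair_label(self):
        assert pair_key("B", "A") == pair_key("A", "B")


class TestNullGmm:
    def test_single_component_mle_recovery(self):
        rng = np.random.default_rng(5)
        null = fit_null_gmm(rng.normal(0, 1, size=1000), k_candidates=(1,), seed=0)
        assert null.means[0] == pytest.approx(0.0, abs=0.1)
        assert null.sds[0] == pytest.approx(1.0, abs=0.1)

    def test_degenerate_scores_guarded_by_variance_floor(self):
        null = fit_null_gmm(np.zeros(50), k_candidates=(1,), seed=0)
        assert null.sds[0] > 0

    def test_bic_selects_two_components_for_bimodal_null(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-2, 0.5, 1000), rng.normal(2, 0.5, 1000)])
        null = fit_null_gmm(x, k_candidates=(1, 2, 3), seed=0)
        assert null.k == 2

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            fit_null_gmm(np.zeros(5))


class TestPvalues:
    def _std_null(self):
        from dualguide.stats import NullModel
        return NullModel(weights=np.array([1.0]), means=np.array([0.0]),
                         sds=np.array([1.0]), k=1, bic=0.0)

    def test_score_at_mean_gives_half(self):
        p = synergy_pvalues(pd.Series({"x": 0.0}), self._std_null())
        assert p["x"] == pytest.approx(0.5)

    def test_normal_tail_value(self):
        p = synergy_pvalues(pd.Series({"x": 1.645}), self._std_null())
        assert p["x"] == pytest.approx(0.05, abs=0.001)

    def test_monotone_decreasing_in_score(self):
        s = pd.Series(np.linspace(-3, 3, 50))
        p = synergy_pvalues(s, self._std_null())
        assert (np.diff(p) < 0).all()

    def test_mixture_tail_is_weighted_sum(self):
        from dualguide.stats import NullModel
        null = NullModel(weights=np.array([0.3, 0.7]), means=np.array([0.0, 1.0]),
                         sds=np.array([1.0, 2.0]), k=2, bic=0.0)
        p = synergy_pvalues(pd.Series({"x": 1.5}), null)
        expected = 0.3 * sps.norm.sf(1.5) + 0.7 * sps.norm.sf((1.5 - 1) / 2)
        assert p["x"] == pytest.approx(expected)


class TestBhFdr:
    def test_hand_worked_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    @given(hst.lists(hst.floats(min_value=0, max_value=1, allow_nan=False),
                     min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_definition_based_oracle(self, p):
        assert np.allclose(bh_fdr(np.array(p)), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))
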