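"""Control-separation metrics, positional balance, scaffold-flip and
promoter effects, replicate correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dualguide import benchmark as bm
from dualguide import stats as st
from dualguide.simulate import SimConfig, simulate_counts, simulate_library


def _auc_oracle(pos_scores, neg_scores):
    """Brute-force Mann-Whitney pair counting with tie correction."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


class TestRocAuc:
    def _labels(self, n_pos, n_neg):
        return bm.ControlLabels(positives={f"p{i}" for i in range(n_pos)},
                                negatives={f"n{i}" for i in range(n_neg)})

    def test_perfect_separation(self):
        scores = pd.Series({"p0": -3.0, "p1": -2.5, "n0": 0.1, "n1": 0.0})
        auc, _ = bm.roc_auc(scores, self._labels(2, 2))
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        scores = pd.Series({"p0": 0.0, "p1": 0.0, "n0": 0.0, "n1": 0.0})
        auc, _ = bm.roc_auc(scores, self._labels(2, 2))
        assert auc == 0.5

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_pos = int(rng.integers(3, 50))
            n_neg = int(rng.integers(3, 50))
            pos = np.round(rng.normal(-1, 1, n_pos), 1)  # rounding forces ties
            neg = np.round(rng.normal(0, 1, n_neg), 1)
            scores = pd.Series(np.concatenate([pos, neg]),
                               index=[f"p{i}" for i in range(n_pos)]
                               + [f"n{i}" for i in range(n_neg)])
            auc, _ = bm.roc_auc(scores, self._labels(n_pos, n_neg))
            assert auc == pytest.approx(_auc_oracle(-pos, -neg), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=40),
                           index=[f"p{i}" for i in range(20)]
                           + [f"n{i}" for i in range(20)])
        labels = self._labels(20, 20)
        auc1, _ = bm.roc_auc(scores, labels)
        auc2, _ = bm.roc_auc(scores.apply(lambda x: np.exp(x) + x ** 3), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_one_class_rejected(self):
        scores = pd.Series({"p0": 1.0, "p1": 2.0})
        with pytest.raises(ValueError):
            bm.roc_auc(scores, bm.ControlLabels({"p0", "p1"}, {"absent"}))


class TestNnmd:
    def test_identical_distributions_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert bm.nnmd(x, x) == pytest.approx(0.0)

    def test_shift_in_mad_units_recovered(self):
        rng = np.random.default_rng(8)
        non = rng.normal(0, 1, 10_000)
        mad = sps.median_abs_deviation(non, scale="normal")
        ess = non[:5000] - 2 * mad
        assert bm.nnmd(ess, non) == pytest.approx(-2.0, abs=0.1)

    def test_monotone_in_shift(self):
        rng = np.random.default_rng(9)
        non = rng.normal(0, 1, 500)
        vals = [bm.nnmd(non - s, non) for s in (0.5, 1.0, 2.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_zero_mad_guarded(self):
        with pytest.raises(ValueError, match="MAD"):
            bm.nnmd([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPositionalBalance:
    def _toy(self):
        cfg = SimConfig(n_essential_genes=3, n_nonessential_genes=2,
                        n_sl_pairs=0, n_null_pairs=0, seed=41)
        library, truth = simulate_library(cfg)
        return cfg, library

    def test_hand_enumerated_five_gene_table(self):
        cfg, library = self._toy()
        vals = {}
        per_gene = {"ESS000": (-2.0, -1.8), "ESS001": (-1.5, -0.6),
                    "ESS002": (-0.4, -1.2), "NON000": (0.1, 0.2),
                    "NON001": (0.0, -0.1)}
        for c in library:
            if c.category == "single_left":
                vals[c.construct_id] = per_gene[c.gene_left][0]
            elif c.category == "single_right":
                vals[c.construct_id] = per_gene[c.gene_right][1]
        lfc = pd.DataFrame({"mean": pd.Series(vals)})
        res = bm.positional_balance(lfc, library, {"ESS000", "ESS001", "ESS002"})
        lefts = np.array([v[0] for v in per_gene.values()])
        rights = np.array([v[1] for v in per_gene.values()])
        assert res.pearson_r == pytest.approx(float(np.corrcoef(lefts, rights)[0, 1]))
        assert res.pct_both_below == pytest.approx(100.0 / 3)  # only ESS000

    def test_left_equals_right_gives_r_one(self):
        cfg, library = self._toy()
        vals = {}
        per_gene = {"ESS000": -2.0, "ESS001": -1.0, "ESS002": -1.5,
                    "NON000": 0.1, "NON001": -0.2}
        for c in library:
            if c.category == "single_left":
                vals[c.construct_id] = per_gene[c.gene_left]
            elif c.category == "single_right":
                vals[c.construct_id] = per_gene[c.gene_right]
        lfc = pd.DataFrame({"mean": pd.Series(vals)})
        res = bm.positional_balance(lfc, library, set(per_gene))
        assert res.pearson_r == pytest.approx(1.0)
        # strict threshold: ESS001 at exactly -1 does not count
        assert res.pct_both_below == pytest.approx(100 * 2 / 5)

    def test_simulated_unbiased_screen_balances(self):
        cfg = SimConfig(n_essential_genes=8, n_nonessential_genes=8,
                        n_sl_pairs=0, n_null_pairs=0, promoter_bias=1.0,
                        guide_efficacy_dist=(50.0, 1.0), sequencing_depth=2000,
                        seed=43)
        library, truth = simulate_library(cfg)
        counts = simulate_counts(library, truth, cfg)
        lfc = st.center_lfc(st.lfc_from_counts(counts.counts),
                            [c.construct_id for c in library if c.category == "control"])
        ess = {g for g in truth.gene_effect if g.startswith("ESS")}
        res = bm.positional_balance(lfc, library, ess)
        assert res.pct_both_below == pytest.approx(100.0)
        assert res.pearson_r > 0.9


class TestTracrAndPromoterEffects:
    def _flipped_screens(self, tracr_efficacy_scale=1.0, seed=47):
        """Simulate a library and its scaffold-flipped twin; optionally make
        the second scaffold weaker in the second screen."""
        cfg1 = SimConfig(n_essential_genes=10, n_nonessential_genes=4,
                         n_sl_pairs=0, n_null_pairs=0, promoter_bias=1.0,
                         sequencing_depth=2000, seed=seed)
        lib1, truth1 = simulate_library(cfg1)
        counts1 = simulate_counts(lib1, truth1, cfg1)
        cfg2 = SimConfig(**{**cfg1.__dict__,
                            "tracr_combination": ("WCR3", "VCR1")})
        lib2, truth2 = simulate_library(cfg2)
        if tracr_efficacy_scale != 1.0:
            # the flipped screen expresses every guide on the other scaffold;
            # scale its true LFCs to plant a scaffold-efficacy difference
            truth2.construct_true_lfc *= tracr_efficacy_scale
            truth2.construct_left_only_lfc *= tracr_efficacy_scale
        counts2 = simulate_counts(lib2, truth2, cfg2)
        # center on neutral controls so the compositional shift (which differs
        # between screens of different overall depletion) cancels
        ctrl1 = [c.construct_id for c in lib1 if c.category == "control"]
        ctrl2 = [c.construct_id for c in lib2 if c.category == "control"]
        l1 = st.center_lfc(st.lfc_from_counts(counts1.counts), ctrl1)
        l2 = st.center_lfc(st.lfc_from_counts(counts2.counts), ctrl2)
        return l1, l2, lib1, lib2

    def test_equal_scaffolds_center_on_zero(self):
        l1, l2, lib1, lib2 = self._flipped_screens()
        res = bm.tracr_effect(l1, l2, lib1, lib2)
        se = res.sd / np.sqrt(len(res.deltas))
        assert abs(res.mean) < max(3 * se, 0.05)

    def test_planted_weak_scaffold_shifts_deltas(self):
        l1, l2, lib1, lib2 = self._flipped_screens(tracr_efficacy_scale=0.5)
        res = bm.tracr_effect(l1, l2, lib1, lib2)
        # screen 2 depletes only half as much, so delta = LFC1 - LFC2 < 0
        assert res.mean < -0.2 and res.p_value < 1e-6

    def test_disjoint_libraries_error(self):
        l1, l2, lib1, _ = self._flipped_screens()
        cfg = SimConfig(n_essential_genes=1, n_nonessential_genes=1,
                        n_sl_pairs=0, n_null_pairs=0, seed=999)
        lib_other, _ = simulate_library(cfg)
        with pytest.raises(ValueError, match="shared"):
            bm.tracr_effect(l1, l1, lib1, lib_other)

    def test_promoter_bias_depletes_u6_position_more(self):
        cfg = SimConfig(n_essential_genes=10, n_nonessential_genes=2,
                        n_sl_pairs=0, n_null_pairs=0, promoter_bias=0.7,
                        sequencing_depth=2000, seed=53)
        library, truth = simulate_library(cfg)
        counts = simulate_counts(library, truth, cfg)
        lfc = st.lfc_from_counts(counts.counts)
        res = bm.promoter_effect(lfc, library)
        assert res.median < -0.1  # U6 position more depleting
        assert res.wilcoxon_p < 0.01

    def test_no_bias_gives_null_promoter_effect(self):
        cfg = SimConfig(n_essential_genes=10, n_nonessential_genes=2,
                        n_sl_pairs=0, n_null_pairs=0, promoter_bias=1.0,
                        sequencing_depth=2000, seed=59)
        library, truth = simulate_library(cfg)
        counts = simulate_counts(library, truth, cfg)
        lfc = st.lfc_from_counts(counts.counts)
        res = bm.promoter_effect(lfc, library)
        assert abs(res.median) < 0.1

    def test_wilcoxon_matches_brute_force_signed_rank(self):
        # 10-pair toy: exhaustive signed-rank statistic
        deltas = np.array([-0.5, -0.3, 0.2, -0.7, 0.1, -0.4, -0.6, 0.3, -0.2, -0.8])
        ranks = sps.rankdata(np.abs(deltas))
        w_pos = ranks[deltas > 0].sum()
        w_ref = sps.wilcoxon(deltas)
        assert w_ref.statistic == pytest.approx(min(w_pos, ranks[deltas < 0].sum()))


class TestReplicateCorrelation:
    def test_duplicated_replicate_r_one(self):
        lfc = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.0, 2.0, 3.0]})
        r = bm.replicate_correlation(lfc)
        assert r.loc["r1", "r2"] == pytest.approx(1.0)
        assert (np.diag(r) == 1).all()

    def test_independent_null_replicates_near_zero(self):
        rng = np.random.default_rng(13)
        lfc = pd.DataFrame(rng.normal(size=(500, 3)), columns=["r1", "r2", "r3"])
        r = bm.replicate_correlation(lfc)
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_three_replicate_toy_matches_formula(self):
        lfc = pd.DataFrame({"r1": [1.0, 2.0, 4.0], "r2": [1.0, 3.0, 5.0],
                            "r3": [0.0, 1.0, 1.5]})
        r = bm.replicate_correlation(lfc)
        expected = np.corrcoef(lfc["r1"], lfc["r2"])[0, 1]
        assert r.loc["r1", "r2"] == pytest.approx(expected)

    def test_constant_replicate_is_missing(self):
        lfc = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [5.0, 5.0, 5.0]})
        r = bm.replicate_correlation(lfc)
        assert np.isnan(r.loc["r1", "r2"])
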