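"""Splits, matched undersampling, metrics, and repeated-measures statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from patchcascade.cohort import SubjectRecord
from patchcascade.evaluation import (
    SplitConfig,
    class_weights,
    compute_metrics,
    largest_remainder,
    rm_anova,
    stratified_split,
    tukey_posthoc,
    undersample_match,
)


def _records(n_ad, n_cn, split=None):
    recs = [SubjectRecord(f"ad{i:03d}", "AD") for i in range(n_ad)]
    recs += [SubjectRecord(f"cn{i:03d}", "CN") for i in range(n_cn)]
    if split:
        for r in recs:
            r.split = split
    return recs


class TestStratifiedSplit:
    def test_full_cohort_apportionment(self):
        """187 AD / 229 CN at 70/10/20 -> (131,19,37) and (160,23,46) per class."""
        out = stratified_split(_records(187, 229), SplitConfig(seed=0))
        for label, expected in (("AD", (131, 19, 37)), ("CN", (160, 23, 46))):
            counts = tuple(
                sum(1 for r in out if r.label == label and r.split == s)
                for s in ("train", "val", "test")
            )
            assert counts == expected

    def test_relaxed_all_train(self):
        cfg = SplitConfig(fractions=(1.0, 0.0, 0.0), strict=False)
        out = stratified_split(_records(5, 5), cfg)
        assert all(r.split == "train" for r in out)

    def test_same_seed_same_assignment(self):
        a = stratified_split(_records(20, 30), SplitConfig(seed=7))
        b = stratified_split(_records(20, 30), SplitConfig(seed=7))
        assert [r.split for r in a] == [r.split for r in b]

    def test_no_subject_in_two_splits_and_none_lost(self):
        out = stratified_split(_records(33, 47), SplitConfig(seed=1))
        assert len(out) == 80
        assert all(r.split in ("train", "val", "test") for r in out)

    def test_small_class_rejected_in_strict_mode(self):
        with pytest.raises(ValueError, match="AD"):
            stratified_split(_records(2, 50), SplitConfig(seed=0))

    def test_input_not_mutated(self):
        recs = _records(10, 10)
        stratified_split(recs, SplitConfig(seed=0))
        assert all(r.split == "unassigned" for r in recs)

    @settings(max_examples=40, deadline=None)
    @given(n=st.integers(1, 500))
    def test_largest_remainder_sums_and_bounds(self, n):
        fr = (0.7, 0.1, 0.2)
        counts = largest_remainder(n, fr)
        assert sum(counts) == n
        assert all(abs(c - n * f) < 1 for c, f in zip(counts, fr))


class TestUndersampleMatch:
    def test_forced_argmin(self):
        recs = _records(1, 2, split="test")
        vols = {"ad000": np.zeros((4, 4)), "cn000": np.full((4, 4), 0.2),
                "cn001": np.full((4, 4), 0.1)}
        out = undersample_match(recs, vols)
        assert sorted(r.subject_id for r in out) == ["ad000", "cn001"]

    def test_already_balanced_identity(self):
        recs = _records(2, 2, split="test")
        out = undersample_match(recs, {r.subject_id: np.zeros(3) for r in recs})
        assert out == recs

    def test_minority_controls_warns_and_returns_unchanged(self):
        recs = _records(3, 1, split="test")
        with pytest.warns(UserWarning):
            out = undersample_match(recs, {r.subject_id: np.zeros(3) for r in recs})
        assert out == recs

    def test_missing_volume_names_subject(self):
        recs = _records(1, 2, split="test")
        with pytest.raises(FileNotFoundError, match="ad000|cn00"):
            undersample_match(recs, {})

    def test_greedy_rule_matches_brute_force(self):
        """2 AD x 3 CN with random distance tables vs exhaustive greedy replay."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            recs = _records(2, 3, split="test")
            vols = {r.subject_id: rng.random(8) for r in recs}
            out = undersample_match(recs, vols)
            # oracle: replay the stated greedy rule by explicit enumeration
            used, kept = set(), []
            for ad in ["ad000", "ad001"]:
                dists = {
                    cn: float(np.mean(np.abs(vols[ad] - vols[cn])))
                    for cn in ["cn000", "cn001", "cn002"]
                    if cn not in used
                }
                best = min(sorted(dists), key=lambda c: dists[c])
                used.add(best)
                kept.append(best)
            expected = {"ad000", "ad001"} | set(kept)
            assert {r.subject_id for r in out} == expected

    def test_balance_exact_whenever_precondition_holds(self):
        rng = np.random.default_rng(3)
        recs = _records(4, 9, split="test")
        vols = {r.subject_id: rng.random(5) for r in recs}
        out = undersample_match(recs, vols)
        labels = [r.label for r in out]
        assert labels.count("AD") == labels.count("CN") == 4


class TestMetrics:
    def test_symmetric_confusion_by_substitution(self):
        # TP=9 TN=9 FP=1 FN=1: all four indices = 0.9
        labels = ["AD"] * 10 + ["CN"] * 10
        scores = [0.9] * 9 + [0.1] + [0.1] * 9 + [0.9]
        m = compute_metrics(labels, scores)
        assert (m.tp, m.tn, m.fp, m.fn) == (9, 9, 1, 1)
        assert m.acc == m.sen == m.spe == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)

    def test_perfect_separation_auc_one(self):
        m = compute_metrics(["AD", "AD", "CN", "CN"], [0.9, 0.8, 0.2, 0.1])
        assert m.auc == 1.0

    def test_pair_enumeration_auc_and_monotone_invariance(self):
        labels, scores = ["AD", "CN", "AD"], np.array([0.9, 0.8, 0.4])
        m = compute_metrics(labels, scores)
        assert m.auc == pytest.approx(0.5)  # one concordant, one discordant pair
        m2 = compute_metrics(labels, scores**2)
        assert m2.auc == m.auc

    def test_single_class_auc_nan_other_metrics_defined(self):
        m = compute_metrics(["AD", "AD"], [0.9, 0.2])
        assert np.isnan(m.auc)
        assert m.sen == 0.5
        assert m.acc == 0.5

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 40), tn=st.integers(0, 40),
        fp=st.integers(0, 40), fn=st.integers(0, 40),
    )
    def test_identities_on_random_confusions(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        labels = ["AD"] * (tp + fn) + ["CN"] * (tn + fp)
        scores = [1.0] * tp + [0.0] * fn + [0.0] * tn + [1.0] * fp
        m = compute_metrics(labels, scores)
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
        total = tp + tn + fp + fn
        assert m.acc * total == pytest.approx(tp + tn)
        if tp + fn:
            assert m.sen * (tp + fn) == pytest.approx(tp)
        if 2 * tp + fp + fn:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_auc_equals_trapezoidal_roc_area(self):
        """Rank AUC vs sklearn's trapezoidal ROC on 25 random score sets."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            labels = np.where(rng.random(n) < 0.5, "AD", "CN")
            if len(set(labels.tolist())) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            m = compute_metrics(labels, scores)
            ref = roc_auc_score((labels == "AD").astype(int), scores)
            assert m.auc == pytest.approx(ref, abs=1e-12)


class TestClassWeights:
    def test_balanced_is_unity(self):
        w = class_weights(["AD"] * 5 + ["CN"] * 5)
        assert w == {"AD": 1.0, "CN": 1.0}

    def test_imbalanced_formula(self):
        w = class_weights(["AD"] * 40 + ["CN"] * 60)
        assert w["AD"] == pytest.approx(1.25)
        assert w["CN"] == pytest.approx(100 / 120)

    def test_weighted_average_is_one(self):
        labels = ["AD"] * 13 + ["CN"] * 29
        w = class_weights(labels)
        assert np.mean([w[l] for l in labels]) == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(["AD", "AD"])


class TestRMAnova:
    def test_constant_table_f_zero(self):
        table = pd.DataFrame(np.full((6, 3), 0.8), columns=list("abc"))
        res = rm_anova(table)
        assert res.f_stat == 0.0

    def test_two_conditions_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            a = rng.normal(size=n)
            b = a + rng.normal(0.3, 0.5, size=n)
            table = pd.DataFrame({"a": a, "b": b})
            res = rm_anova(table)
            t, p = stats.ttest_rel(a, b)
            assert res.f_stat == pytest.approx(t**2, rel=1e-9)
            assert res.p_uncorrected == pytest.approx(p, rel=1e-9)

    def test_compound_symmetric_data_epsilon_near_one(self):
        rng = np.random.default_rng(2)
        eps_vals = []
        for seed in range(10):
            subj = rng.normal(size=(200, 1))
            table = pd.DataFrame(subj + rng.normal(scale=1.0, size=(200, 4)))
            eps_vals.append(rm_anova(table).gg_epsilon)
        assert np.mean(eps_vals) > 0.93

    def test_agrees_with_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        wide = pd.DataFrame(
            rng.normal(size=(12, 4)) + rng.normal(size=(12, 1)),
            columns=["c1", "c2", "c3", "c4"],
        )
        long = wide.reset_index().melt(id_vars="index", var_name="cond", value_name="y")
        ref = pingouin.rm_anova(
            data=long, dv="y", within="cond", subject="index", correction=True
        )
        res = rm_anova(wide)
        assert res.f_stat == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p_uncorrected == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
        assert res.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_mauchly_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(rng.normal(size=(15, 4)) * [1.0, 1.0, 2.0, 4.0])
        spher = pingouin.sphericity(wide)
        res = rm_anova(wide)
        assert res.mauchly_w == pytest.approx(float(spher.W), rel=1e-6)
        # same chi-square statistic; pingouin adds a second-order Box term to p
        assert res.mauchly_p == pytest.approx(float(spher.pval), rel=0.05)

    def test_incomplete_table_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(table)


class TestTukey:
    def test_identical_conditions_p_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        table = pd.DataFrame({"a": base, "b": base.copy(), "c": base.copy()})
        out = tukey_posthoc(table)
        assert (out["p_adj"] > 0.99).all()

    def test_two_conditions_reduce_to_paired_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = a + rng.normal(0.4, 0.6, size=12)
        out = tukey_posthoc(pd.DataFrame({"a": a, "b": b}))
        _, p_ref = stats.ttest_rel(a, b)
        assert out["p_adj"].iloc[0] == pytest.approx(p_ref, rel=1e-6)

    def test_shifted_condition_has_smallest_p(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=15)
        table = pd.DataFrame(
            {
                "a": base + rng.normal(scale=0.2, size=15),
                "b": base + rng.normal(scale=0.2, size=15),
                "c": base + 5.0 + rng.normal(scale=0.2, size=15),
            }
        )
        out = tukey_posthoc(table)
        with_c = out[(out.A == "c") | (out.B == "c")]["p_adj"]
        without_c = out[(out.A != "c") & (out.B != "c")]["p_adj"]
        assert with_c.max() < without_c.min()

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        out1 = tukey_posthoc(table)
        out2 = tukey_posthoc(table[["c", "b", "a"]])
        p1 = {frozenset((r.A, r.B)): r.p_adj for r in out1.itertuples()}
        p2 = {frozenset((r.A, r.B)): r.p_adj for r in out2.itertuples()}
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], rel=1e-12)
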