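import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from miror.classification import (
    PRESET_FEATURES,
    loocv_threshold,
    mann_whitney_u,
    model_cv,
    nri,
    roc_auc,
    select_features,
    smote,
    threshold_classify,
)
from miror.synthetic_phantom import CohortSpec, generate_feature_cohort

from .conftest import make_records


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.U == 0.0
        assert r.p_raw == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    def test_tie_symmetry(self):
        assert mann_whitney_u([1, 2], [1, 2]).U == 2.0  # n1*n2/2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([5.0], [])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n1=st.integers(1, 7), n2=st.integers(1, 7), seed=st.integers(0, 2**16))
    def test_exact_p_matches_scipy_enumeration(self, n1, n2, seed):
        """For tie-free small samples the enumerated P equals the exact
        Mann-Whitney null distribution (independent implementation)."""
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        a, b = pooled[:n1], pooled[n1:]
        mine = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        # scipy's U is the rank-sum variant of the same statistic
        assert mine.U == pytest.approx(ref.statistic)
        assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_close_to_scipy(self, rng):
        a = rng.normal(0.0, 1.0, size=25)
        b = rng.normal(0.6, 1.0, size=18)
        mine = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-6)

    def test_tied_large_groups_use_corrected_approximation(self, rng):
        a = rng.integers(0, 4, size=12).astype(float)
        b = rng.integers(1, 5, size=12).astype(float)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mann_whitney_u(a, b).p_raw == pytest.approx(ref.pvalue, rel=1e-6)


class TestSelectFeatures:
    def test_separated_groups_select_location_feature(self, separated_cohort):
        selected, results = select_features(separated_cohort, alpha=0.05)
        assert "mean" in selected
        by_name = {r.feature: r for r in results}
        assert by_name["mean"].p_raw < 1e-4

    def test_bonferroni_arithmetic(self):
        # raw P=.004 over m=15 comparisons adjusts to .06: not significant
        assert min(1.0, 0.004 * 15) == pytest.approx(0.06)
        rng = np.random.default_rng(4)
        features = {f"f{i}": (0.0, 1.0) for i in range(15)}
        spec = CohortSpec(group_stats={"malignant": features, "benign": features},
                          n_per_group={"malignant": 10, "benign": 10}, seed=2)
        records = generate_feature_cohort(spec)
        _, results = select_features(records, use_correction=True)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 15))

    def test_preset_reproduces_manual_choice(self, default_cohort):
        selected, _ = select_features(default_cohort, preset=True)
        assert selected == list(PRESET_FEATURES)

    def test_correlation_pruning_keeps_one_per_cluster(self):
        # strongly equicorrelated location features collapse to a single
        # representative (the smallest raw P)
        stats_m = {f: (0.0, 1.0) for f in ("c10", "c15", "c25")}
        stats_b = {f: (5.0, 1.0) for f in ("c10", "c15", "c25")}
        spec = CohortSpec(group_stats={"malignant": stats_m, "benign": stats_b},
                          n_per_group={"malignant": 15, "benign": 15},
                          seed=9, equicorrelation=0.97)
        records = generate_feature_cohort(spec)
        selected, results = select_features(records, correlation_prune=0.8)
        assert len(selected) == 1
        p_of = {r.feature: r.p_raw for r in results}
        assert p_of[selected[0]] == min(p_of.values())


class TestThresholdClassify:
    # published group statistics: ADC mean malignant (1098, 295) / benign
    # (1443, 462); kurtosis malignant (2.1, 0.09) / benign (2.031, 0.11)
    ADC_M, ADC_B = (1098.0, 295.0), (1443.0, 462.0)
    KURT_M, KURT_B = (2.1, 0.09), (2.031, 0.11)

    def test_step1_unique_interval(self):
        out = threshold_classify(900.0, self.ADC_M, self.ADC_B)
        assert (out.predicted, out.step, out.ambiguous) == ("malignant", "interval", False)

    def test_step2_inside_both(self):
        out = threshold_classify(2.1, self.KURT_M, self.KURT_B)
        assert (out.predicted, out.step, out.ambiguous) == ("malignant", "nearest-mean", True)

    def test_step2_inside_neither(self):
        out = threshold_classify(2000.0, self.ADC_M, self.ADC_B)
        assert (out.predicted, out.step, out.ambiguous) == ("benign", "nearest-mean", True)

    def test_tie_goes_to_malignant(self):
        out = threshold_classify(0.5, (0.0, 2.0), (1.0, 2.0))
        assert out.predicted == "malignant" and out.ambiguous

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            threshold_classify(1.0, (0.0, 0.0), (1.0, 1.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(value=st.floats(-10, 10),
           scale=st.floats(0.1, 50),
           offset=st.floats(-100, 100))
    def test_affine_equivariance(self, value, scale, offset):
        """A positive-slope affine map of the value and both group stats
        leaves the outcome unchanged."""
        m, b = (0.0, 1.0), (3.0, 2.0)
        base = threshold_classify(value, m, b)
        mapped = threshold_classify(
            scale * value + offset,
            (scale * m[0] + offset, scale * m[1]),
            (scale * b[0] + offset, scale * b[1]),
        )
        assert (base.predicted, base.step, base.ambiguous) == \
            (mapped.predicted, mapped.step, mapped.ambiguous)


def replay_loocv(records, feature):
    """Independent literal replay of the leave-one-out procedure."""
    correct = {"malignant": 0, "benign": 0}
    totals = {"malignant": 0, "benign": 0}
    for i, rec in enumerate(records):
        rest = records[:i] + records[i + 1:]
        mv = np.array([r.features[feature] for r in rest if r.group == "malignant"])
        bv = np.array([r.features[feature] for r in rest if r.group == "benign"])
        v = rec.features[feature]
        in_m = abs(v - mv.mean()) <= mv.std()
        in_b = abs(v - bv.mean()) <= bv.std()
        if in_m and not in_b:
            pred = "malignant"
        elif in_b and not in_m:
            pred = "benign"
        else:
            pred = "malignant" if abs(v - mv.mean()) <= abs(v - bv.mean()) else "benign"
        totals[rec.group] += 1
        correct[rec.group] += pred == rec.group
    sens = correct["malignant"] / totals["malignant"]
    spec = correct["benign"] / totals["benign"]
    acc = (correct["malignant"] + correct["benign"]) / len(records)
    return sens, spec, acc


class TestLOOCVThreshold:
    def test_well_separated_cohort_is_perfect(self, separated_cohort):
        metrics = loocv_threshold(separated_cohort, "mean")
        assert metrics.sensitivity == 1.0
        assert metrics.specificity == 1.0
        assert metrics.accuracy == 1.0

    def test_matches_literal_replay(self):
        rng = np.random.default_rng(13)
        records = make_records(rng.normal(0.0, 1.0, 25), rng.normal(1.0, 1.0, 15))
        metrics = loocv_threshold(records, "mean")
        sens, spec, acc = replay_loocv(records, "mean")
        assert metrics.sensitivity == pytest.approx(sens)
        assert metrics.specificity == pytest.approx(spec)
        assert metrics.accuracy == pytest.approx(acc)

    def test_constant_feature_rejected(self):
        records = make_records([1.0] * 5, [1.0] * 5)
        with pytest.raises(ValueError):
            loocv_threshold(records, "mean")

    def test_too_small_group_rejected(self):
        records = make_records([1.0, 2.0], [3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            loocv_threshold(records, "mean")

    def test_every_case_evaluated_once(self, separated_cohort):
        metrics = loocv_threshold(separated_cohort, "mean")
        assert len(metrics.per_case) == len(separated_cohort)
        assert len({o.case_id for o in metrics.per_case}) == len(separated_cohort)


class TestSMOTE:
    def test_1d_convexity(self):
        synth = smote(np.array([[0.0], [10.0]]), k=1, n_new=50, rng=7)
        assert ((synth >= 0.0) & (synth <= 10.0)).all()

    def test_identical_minority_points(self):
        synth = smote(np.full((4, 2), 3.0), k=2, n_new=10, rng=0)
        np.testing.assert_allclose(synth, 3.0)

    def test_seed_determinism_and_formula_replay(self):
        minority = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        a = smote(minority, k=2, n_new=5, rng=42)
        b = smote(minority, k=2, n_new=5, rng=42)
        np.testing.assert_array_equal(a, b)
        # hand-trace the first sample from the same generator state
        rng = np.random.default_rng(42)
        base = rng.integers(0, 4, size=5)
        pick = rng.integers(1, 3, size=5)
        u = rng.uniform(0.0, 1.0, size=5)
        from sklearn.neighbors import NearestNeighbors
        _, nb = NearestNeighbors(n_neighbors=3).fit(minority).kneighbors(minority)
        x0 = minority[base[0]]
        xnn = minority[nb[base[0], pick[0]]]
        np.testing.assert_allclose(a[0], x0 + u[0] * (xnn - x0))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            smote(np.zeros((3, 2)), k=3, n_new=1, rng=0)

    def test_convex_hull_membership_multidim(self, rng):
        """Synthetic points lie on segments between minority points, hence
        inside the per-coordinate bounding box."""
        minority = rng.normal(size=(12, 4))
        synth = smote(minority, k=5, n_new=200, rng=1)
        assert (synth >= minority.min(axis=0) - 1e-12).all()
        assert (synth <= minority.max(axis=0) + 1e-12).all()


class TestModelCV:
    @pytest.fixture
    def clustered_cohort(self):
        stats = {
            "malignant": {"mean": (0.0, 0.5), "c15": (0.0, 0.5)},
            "benign": {"mean": (30.0, 0.5), "c15": (30.0, 0.5)},
        }
        return generate_feature_cohort(CohortSpec(
            group_stats=stats, n_per_group={"malignant": 25, "benign": 15}, seed=3))

    @pytest.mark.parametrize("model", ["knn", "svm"])
    def test_separable_cohort_is_perfect(self, clustered_cohort, model):
        metrics = model_cv(clustered_cohort, model=model, folds=5, seed=17)
        assert metrics.accuracy == 1.0
        assert metrics.auc == 1.0

    def test_ambiguity_band_on_probabilities(self, default_cohort):
        metrics = model_cv(default_cohort, model="knn", folds=5, seed=17)
        for o in metrics.per_case:
            confidence = max(o.probability, 1.0 - o.probability)
            assert o.ambiguous == (confidence <= 0.8)
            assert o.predicted == ("malignant" if o.probability >= 0.5 else "benign")

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=120)
        records = make_records(values[:60], values[60:])
        metrics = model_cv(records, model="knn", folds=5, seed=23)
        assert metrics.auc == pytest.approx(0.5, abs=0.1)

    def test_class_smaller_than_folds_rejected(self, clustered_cohort):
        with pytest.raises(ValueError, match="per class"):
            model_cv(clustered_cohort, model="knn", folds=20, seed=0)

    def test_seed_reproducibility(self, default_cohort):
        a = model_cv(default_cohort, model="svm", folds=5, seed=7)
        b = model_cv(default_cohort, model="svm", folds=5, seed=7)
        assert [o.probability for o in a.per_case] == [o.probability for o in b.per_case]


class TestROCAUC:
    def test_perfect_separation(self):
        *_, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_identical_scores_are_chance(self):
        *_, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_pair_counting_example(self):
        # scores (0.9, 0.8, 0.3) truth (+, -, +): one win, one loss of 2 pairs
        *_, auc = roc_auc([0.9, 0.8, 0.3], [1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), n1=st.integers(2, 15), n2=st.integers(2, 15))
    def test_auc_equals_u_over_n1n2(self, seed, n1, n2):
        """Cross-operation consistency: trapezoidal AUC equals the
        Mann-Whitney U statistic of the scores divided by n1*n2."""
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.5, 0.3, n1).round(1)  # rounding forces ties
        neg = rng.normal(0.3, 0.3, n2).round(1)
        scores = np.concatenate([pos, neg])
        truth = np.r_[np.ones(n1, dtype=int), np.zeros(n2, dtype=int)]
        *_, auc = roc_auc(scores, truth)
        u = mann_whitney_u(pos, neg).U
        assert auc == pytest.approx(u / (n1 * n2), rel=1e-9)


class TestNRI:
    def test_identity_is_zero(self):
        truth = ["malignant"] * 3 + ["benign"] * 2
        pred = ["malignant", "benign", "malignant", "benign", "malignant"]
        r = nri(pred, pred, truth)
        assert r.nri == 0.0

    def test_maximum_improvement(self):
        truth = ["malignant"] * 3 + ["benign"] * 2
        wrong = ["benign"] * 3 + ["malignant"] * 2
        r = nri(truth, wrong, truth)
        assert r.nri == pytest.approx(2.0)

    def test_counted_example(self):
        # 10 malignant: old 7 right -> new 9 right; 5 benign: old 3 -> new 4
        truth = ["malignant"] * 10 + ["benign"] * 5
        old = ["malignant"] * 7 + ["benign"] * 3 + ["benign"] * 3 + ["malignant"] * 2
        new = ["malignant"] * 9 + ["benign"] * 1 + ["benign"] * 4 + ["malignant"] * 1
        r = nri(new, old, truth)
        assert r.event_net == pytest.approx(0.2)
        assert r.nonevent_net == pytest.approx(0.2)
        assert r.nri == pytest.approx(0.4)

    def test_antisymmetry(self, rng):
        truth = np.where(rng.random(30) < 0.6, "malignant", "benign")
        old = np.where(rng.random(30) < 0.5, "malignant", "benign")
        new = np.where(rng.random(30) < 0.5, "malignant", "benign")
        truth[:2] = ["malignant", "benign"]  # both classes present
        assert nri(new, old, truth).nri == pytest.approx(-nri(old, new, truth).nri)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            nri(["malignant"], ["malignant"], ["malignant"])

    def test_equals_delta_sens_plus_delta_spec(self, rng):
        truth = np.r_[["malignant"] * 12, ["benign"] * 8]
        old = np.where(rng.random(20) < 0.5, "malignant", "benign")
        new = np.where(rng.random(20) < 0.7, "malignant", "benign")

        def sens_spec(pred):
            s = np.mean(pred[:12] == "malignant")
            p = np.mean(pred[12:] == "benign")
            return s, p

        s_new, p_new = sens_spec(new)
        s_old, p_old = sens_spec(old)
        assert nri(new, old, truth).nri == pytest.approx((s_new - s_old) + (p_new - p_old))
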