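"""Group summaries, slope fits, cut-off selection and classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from cardiopol import (
    CutoffLine,
    SlopeCutoffClassifier,
    TissueSample,
    classify,
    confusion_metrics,
    fit_group,
    group_summary,
    select_cutoff,
)
from cardiopol.datasets import load_study_dolp


def ts(subject, group, vent, t, d):
    return TissueSample(subject, group, vent, t, d)


def cohort(group, pairs, vent="LV"):
    return [ts(f"s{i}", group, vent, t, d) for i, (t, d) in enumerate(pairs)]


class TestTissueSampleValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(group="LV"), "unknown group"),
            (dict(ventricle="left"), "unknown ventricle"),
            (dict(thickness_mm=0.0), "thickness"),
            (dict(dolp=1.2), "dolp"),
        ],
    )
    def test_rejects_bad_fields(self, kwargs, match):
        base = dict(
            subject_id="x", group="control", ventricle="LV", thickness_mm=1.0, dolp=0.1
        )
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            TissueSample(**base)


class TestGroupSummary:
    # expected values frozen from direct recomputation of the published
    # per-subject DOLP tables (sample SD with n-1 denominator over sqrt n)
    @pytest.mark.parametrize(
        "group, vent, mean, sem",
        [
            ("control", "LV", 0.0881428571, 0.0110398166),
            ("control", "RV", 0.0597142857, 0.0080436733),
            ("RHD", "LV", 0.0895714286, 0.0214574409),
            ("RHD", "RV", 0.0771428571, 0.0186846366),
            ("MV", "LV", 0.0973333333, 0.0603443820),
            ("MV", "RV", 0.1210000000, 0.0279344471),
        ],
    )
    def test_study_cohort_statistics(self, group, vent, mean, sem):
        g = group_summary(load_study_dolp(), group, vent)
        assert g.mean_dolp == pytest.approx(mean, abs=1e-9)
        assert g.sem_dolp == pytest.approx(sem, abs=1e-9)
        assert g.n == (3 if group == "MV" else 7)

    def test_single_sample_sem_zero(self):
        g = group_summary([ts("a", "control", "LV", 1.0, 0.5)], "control", "LV")
        assert (g.mean_dolp, g.sem_dolp, g.n) == (0.5, 0.0, 1)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            group_summary([], "control", "LV")


class TestFitGroup:
    def test_two_point_line_exact(self):
        fit = fit_group(cohort("control", [(1.0, 0.10), (2.0, 0.05)]))
        assert fit.slope == pytest.approx(-0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(0.15, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_data(self):
        fit = fit_group(cohort("control", [(1.0, 0.1), (1.5, 0.1), (2.0, 0.1)]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_group(cohort("control", [(1.0, 0.1), (1.0, 0.2)]))

    def test_missing_thickness_rejected(self):
        with pytest.raises(ValueError, match="lack thickness"):
            fit_group([ts("a", "control", "LV", None, 0.1), ts("b", "control", "LV", 1.0, 0.1)])

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError, match="single group"):
            fit_group([ts("a", "control", "LV", 1.0, 0.1), ts("b", "RHD", "LV", 2.0, 0.1)])

    def test_matches_brute_force_grid_minimizer(self, rng):
        # independent oracle: dense grid search over (slope, intercept)
        pairs = [(t, d) for t, d in zip(rng.uniform(0.5, 3, 8), rng.uniform(0, 0.3, 8))]
        fit = fit_group(cohort("RHD", pairs))
        t = np.array([p[0] for p in pairs])
        d = np.array([p[1] for p in pairs])
        slopes = np.linspace(fit.slope - 0.02, fit.slope + 0.02, 401)
        intercepts = np.linspace(fit.intercept - 0.02, fit.intercept + 0.02, 401)
        ss = np.array(
            [
                [np.sum((d - (m * t + b)) ** 2) for b in intercepts]
                for m in slopes
            ]
        )
        i, j = np.unravel_index(np.argmin(ss), ss.shape)
        assert abs(slopes[i] - fit.slope) <= 1e-4
        assert abs(intercepts[j] - fit.intercept) <= 1e-4
        # normal equations: residuals orthogonal to predictor and constant
        resid = d - (fit.slope * t + fit.intercept)
        assert abs(resid @ t) < 1e-9 and abs(resid.sum()) < 1e-9

    def test_parameter_recovery_within_confidence_interval(self):
        # cohort generated at a known slope; OLS recovers it within its own
        # 95% CI (fixed seed)
        from scipy import stats

        rng = np.random.default_rng(42)
        slope_true = -0.0422
        t = rng.uniform(1.2, 2.2, 14)
        d = 0.15 + slope_true * t + rng.normal(0, 0.01, 14)
        fit = fit_group(cohort("control", list(zip(t, d))))
        resid = d - (fit.slope * t + fit.intercept)
        se = np.sqrt(resid @ resid / 12 / np.sum((t - t.mean()) ** 2))
        half = stats.t.ppf(0.975, 12) * se
        assert abs(fit.slope - slope_true) <= half


def separable_cohort():
    """Control on a shallow line, diseased on a steep line, no overlap."""
    control = cohort("control", [(1.0, 0.14), (1.5, 0.13), (2.0, 0.11), (2.5, 0.10)])
    diseased = cohort("RHD", [(1.0, 0.10), (1.5, 0.02), (2.0, 0.01), (2.2, 0.005)])
    return control, diseased


class TestSelectCutoff:
    @pytest.mark.parametrize("slope", [-0.056, -0.1])
    def test_fixed_strategy_replicates_requested_slope(self, slope):
        control, diseased = separable_cohort()
        line = select_cutoff(
            fit_group(control), fit_group(diseased), strategy="fixed", fixed_slope=slope
        )
        assert line.slope == slope and line.strategy == "fixed"

    def test_equal_slopes_rejected(self):
        control, _ = separable_cohort()
        fit = fit_group(control)
        with pytest.raises(ValueError, match="not separable"):
            select_cutoff(fit, fit, strategy="fixed", fixed_slope=-0.05)

    def test_max_accuracy_on_separable_groups(self):
        control, diseased = separable_cohort()
        cf, df = fit_group(control), fit_group(diseased)
        line = select_cutoff(cf, df, control + diseased, strategy="max-accuracy")
        _, metrics = classify(control + diseased, line, diseased_groups=("RHD",))
        assert metrics.accuracy == 1.0
        lo, hi = sorted((cf.slope, df.slope))
        assert lo < line.slope < hi
        # brute force over the same candidate set confirms 1.0 is attainable
        # and that no candidate beats the selected one
        at, ad = line.anchor_thickness_mm, line.anchor_dolp
        best = max(
            classify(
                control + diseased,
                CutoffLine(c, at, ad),
                diseased_groups=("RHD",),
            )[1].accuracy
            for c in np.linspace(lo, hi, 203)[1:-1]
        )
        assert best == metrics.accuracy

    def test_anchor_intersection_lies_on_both_lines(self):
        control, diseased = separable_cohort()
        cf, df = fit_group(control), fit_group(diseased)
        line = select_cutoff(cf, df, strategy="fixed", fixed_slope=-0.06)
        t, d = line.anchor_thickness_mm, line.anchor_dolp
        assert cf.predict(t) == pytest.approx(d, abs=1e-12)
        assert df.predict(t) == pytest.approx(d, abs=1e-12)

    def test_anchor_intercept_mean(self):
        control, diseased = separable_cohort()
        cf, df = fit_group(control), fit_group(diseased)
        line = select_cutoff(
            cf, df, strategy="fixed", fixed_slope=-0.06, anchor="intercept-mean"
        )
        assert line.anchor_thickness_mm == 0.0
        assert line.anchor_dolp == pytest.approx(0.5 * (cf.intercept + df.intercept))


class TestClassify:
    def test_hand_computed_sample_slope(self):
        # slope from anchor (0, 0.15) to (1.0, 0.05) is -0.10, steeper than
        # the -0.056 cut-off, hence diseased
        line = CutoffLine(-0.056, 0.0, 0.15)
        labels, _ = classify(
            [ts("a", "RHD", "LV", 1.0, 0.05), ts("b", "control", "LV", 1.0, 0.12)],
            line,
            diseased_groups=("RHD",),
        )
        assert labels == ["diseased", "control"]

    def test_boundary_sample_is_control(self):
        line = CutoffLine(-0.056, 0.0, 0.15)
        labels, _ = classify(
            [
                ts("a", "RHD", "LV", 1.0, 0.15 - 0.056),
                ts("b", "control", "LV", 1.0, 0.12),
            ],
            line,
            diseased_groups=("RHD",),
        )
        assert labels[0] == "control"

    def test_sample_at_anchor_thickness_uses_dolp_side(self):
        line = CutoffLine(-0.056, 1.0, 0.10)
        labels, _ = classify(
            [
                ts("hi", "RHD", "LV", 1.0, 0.12),
                ts("lo", "control", "LV", 1.0, 0.08),
                ts("eq", "control", "LV", 1.0, 0.10),
            ],
            line,
            diseased_groups=("RHD",),
        )
        assert labels == ["diseased", "control", "control"]

    def test_perfect_separation_gives_perfect_metrics(self):
        control, diseased = separable_cohort()
        line = select_cutoff(
            fit_group(control), fit_group(diseased), control + diseased
        )
        _, m = classify(control + diseased, line, diseased_groups=("RHD",))
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    @given(st.integers(0, 2000))
    def test_accuracy_invariant_under_label_and_rule_swap(self, seed):
        rng = np.random.default_rng(seed)
        samples = [
            ts(
                f"s{i}",
                "RHD" if rng.random() < 0.5 else "control",
                "LV",
                float(rng.uniform(0.5, 3.0)),
                float(rng.uniform(0.0, 0.3)),
            )
            for i in range(12)
        ]
        if not any(s.group == "RHD" for s in samples) or not any(
            s.group == "control" for s in samples
        ):
            return
        line = CutoffLine(float(rng.uniform(-0.12, -0.02)), 0.0, float(rng.uniform(0.05, 0.25)))
        _, m1 = classify(samples, line, diseased_groups=("RHD",), diseased_side="steeper")
        swapped = [
            ts(s.subject_id, "control" if s.group == "RHD" else "RHD",
               s.ventricle, s.thickness_mm, s.dolp)
            for s in samples
        ]
        _, m2 = classify(swapped, line, diseased_groups=("RHD",), diseased_side="shallower")
        assert m1.accuracy == pytest.approx(m2.accuracy)


class TestConfusionMetrics:
    def test_published_style_counts(self):
        m = confusion_metrics(11, 3, 10, 4)
        assert m.sensitivity == pytest.approx(11 / 15)
        assert m.specificity == pytest.approx(10 / 13)
        assert m.accuracy == pytest.approx(21 / 28)

    def test_perfect(self):
        m = confusion_metrics(5, 0, 5, 0)
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_fully_wrong(self):
        m = confusion_metrics(0, 5, 0, 5)
        assert m.sensitivity == 0.0 and m.specificity == 0.0

    @pytest.mark.parametrize(
        "counts, match",
        [((0, 1, 1, 0), "sensitivity"), ((1, 0, 0, 1), "specificity")],
    )
    def test_undefined_metric_named(self, counts, match):
        with pytest.raises(ValueError, match=match):
            confusion_metrics(*counts)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_identities_hold_exactly(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = confusion_metrics(tp, fp, tn, fn)
        assert m.sensitivity == tp / (tp + fn)
        assert m.specificity == tn / (tn + fp)
        assert m.accuracy == (tp + tn) / (tp + tn + fp + fn)


class TestSlopeCutoffClassifier:
    def _xy(self):
        control, diseased = separable_cohort()
        X = np.array([[s.thickness_mm, s.dolp] for s in control + diseased])
        y = np.array(["control"] * len(control) + ["diseased"] * len(diseased))
        return X, y, control, diseased

    def test_fit_predict_matches_functional_path(self):
        X, y, control, diseased = self._xy()
        clf = SlopeCutoffClassifier().fit(X, y)
        line = select_cutoff(
            fit_group(control), fit_group(diseased), control + diseased,
            strategy="max-accuracy", diseased_groups=("RHD",),
        )
        assert clf.cutoff_.slope == pytest.approx(line.slope)
        labels, _ = classify(control + diseased, line, diseased_groups=("RHD",))
        pred = ["diseased" if p == "diseased" else "control" for p in clf.predict(X)]
        assert pred == labels
        assert clf.score(X, y) == 1.0

    def test_fixed_strategy(self):
        X, y, *_ = self._xy()
        clf = SlopeCutoffClassifier(cutoff_strategy="fixed", fixed_slope=-0.056).fit(X, y)
        assert clf.cutoff_.slope == -0.056

    def test_clone_and_params_round_trip(self):
        clf = SlopeCutoffClassifier(cutoff_strategy="fixed", fixed_slope=-0.1, n_grid=51)
        params = clone(clf).get_params()
        assert params["fixed_slope"] == -0.1 and params["n_grid"] == 51

    def test_wrong_shape_rejected(self):
        X, y, *_ = self._xy()
        with pytest.raises(ValueError, match="2 columns"):
            SlopeCutoffClassifier().fit(X[:, :1], y)

    def test_requires_two_classes(self):
        X, y, *_ = self._xy()
        with pytest.raises(ValueError):
            SlopeCutoffClassifier().fit(X, np.array(["control"] * len(y)))
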