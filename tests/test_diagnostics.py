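import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urimet import (
    ConfusionCounts,
    confusion,
    accuracy_panel,
    accuracy_panel_from_rates,
    marker_panel_from_counts,
    roc_auc,
    multi_roc_ranking,
    metabolite_levels,
    simulate_spectrum,
    SimConfig,
    SpectrumSet,
)
from urimet.diagnostics import pct_half_up, pct_truncated


class TestConfusion:
    def test_all_correct_counts_and_strings(self):
        truth = np.array([0] * 52 + [1] * 30)
        counts = confusion(truth, truth)
        assert (counts.tn, counts.fp, counts.tp, counts.fn) == (52, 0, 30, 0)
        assert counts.per_class_strings() == ("52/52", "30/30")

    def test_validation_style_counts(self):
        # 50 of 52 controls and 30 of 30 cases predicted correctly
        truth = np.array([0] * 52 + [1] * 30)
        pred = truth.copy()
        pred[:2] = 1
        counts = confusion(truth, pred)
        assert (counts.tn, counts.fp, counts.tp, counts.fn) == (50, 2, 30, 0)
        assert counts.per_class_strings() == ("50/52", "30/30")

    def test_flipping_predictions_swaps_cells(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 40)
        pred = rng.integers(0, 2, 40)
        a = confusion(truth, pred)
        b = confusion(truth, 1 - pred)
        assert (a.tp, a.fn, a.tn, a.fp) == (b.fn, b.tp, b.fp, b.tn)

    def test_non_binary_labels_error(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.array([0, 1, 2]), np.array([0, 1, 1]))


class TestAccuracyPanel:
    def test_perfect_test_any_prevalence(self):
        for prev in (0.1, 0.366, 0.8):
            panel = accuracy_panel_from_rates(1.0, 1.0, prev)
            assert panel.ppv == panel.npv == 1.0
            assert panel.plr is None and panel.nlr == 0.0

    def test_high_sensitivity_row(self):
        panel = accuracy_panel_from_rates(1.0, 50 / 52, 30 / 82)
        assert panel.formatted() == {
            "prevalence": "36.6%", "sensitivity": "100.0%", "specificity": "96.2%",
            "ppv": "93.8%", "npv": "100.0%", "plr": "26.0", "nlr": "0.00",
        }

    def test_perfect_specificity_row_reports_na_plr(self):
        panel = accuracy_panel_from_rates(0.75, 1.0, 12 / 64)
        fmt = panel.formatted()
        assert fmt["ppv"] == "100.0%" and fmt["plr"] == "N/A" and fmt["nlr"] == "0.25"

    def test_counts_route_matches_rates_route(self):
        counts = ConfusionCounts(tp=19, fn=1, tn=50, fp=2)
        a = accuracy_panel(counts)
        b = accuracy_panel_from_rates(19 / 20, 50 / 52, 20 / 72)
        assert a == b

    def test_ppv_npv_monotone_in_prevalence(self):
        grid = np.linspace(0.01, 0.99, 25)
        ppvs = [accuracy_panel_from_rates(0.9, 0.8, p).ppv for p in grid]
        npvs = [accuracy_panel_from_rates(0.9, 0.8, p).npv for p in grid]
        assert np.all(np.diff(ppvs) > 0)
        assert np.all(np.diff(npvs) < 0)

    def test_posterior_odds_identity(self):
        for se, sp, pr in [(0.9, 0.8, 0.3), (0.75, 0.95, 0.1), (0.6, 0.7, 0.5)]:
            panel = accuracy_panel_from_rates(se, sp, pr)
            post_odds = panel.ppv / (1 - panel.ppv)
            assert np.isclose(post_odds, panel.plr * pr / (1 - pr))

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError, match="prevalence"):
            accuracy_panel_from_rates(0.9, 0.9, 0.0)
        with pytest.raises(ValueError, match="classes"):
            accuracy_panel(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))


class TestMarkerPanel:
    def test_serum_marker_style_counts(self):
        panel = marker_panel_from_counts(2, 32, 1, 156)
        assert panel["sensitivity_pct"] == "6.2%"
        assert panel["specificity_pct"] == "99.3%"

    def test_degenerate_extremes(self):
        lo = marker_panel_from_counts(0, 10, 0, 10)
        hi = marker_panel_from_counts(10, 10, 10, 10)
        assert (lo["sensitivity_pct"], lo["specificity_pct"]) == ("0.0%", "100.0%")
        assert (hi["sensitivity_pct"], hi["specificity_pct"]) == ("100.0%", "0.0%")

    def test_zero_totals_error(self):
        with pytest.raises(ValueError, match="totals"):
            marker_panel_from_counts(0, 0, 1, 10)


def pair_count_auc(scores, labels):
    """Exhaustive Mann-Whitney pair counting: wins + half ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1])
        curve = roc_auc(scores, labels)
        assert curve.auc == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert np.isclose(roc_auc(-scores, labels).auc, 1 - roc_auc(scores, labels).auc)

    def test_tied_scores_match_pair_counting(self):
        scores = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 0.0])
        labels = np.array([0, 1, 0, 1, 1, 0])
        assert np.isclose(roc_auc(scores, labels).auc, pair_count_auc(scores, labels))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.booleans()), min_size=2, max_size=12
        ).filter(lambda v: len({l for _, l in v}) == 2)
    )
    def test_auc_equals_pair_count_oracle(self, pairs):
        scores = np.array([s for s, _ in pairs], dtype=float)
        labels = np.array([int(l) for _, l in pairs])
        assert np.isclose(roc_auc(scores, labels).auc, pair_count_auc(scores, labels))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.integers(0, 6, 25).astype(float)
            labels = rng.integers(0, 2, 25)
            if labels.min() == labels.max():
                continue
            assert np.isclose(roc_auc(scores, labels).auc, roc_auc_score(labels, scores))

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc(np.arange(4.0), np.zeros(4))


class TestMultiRocRanking:
    def test_strong_marker_ranked_first_among_nulls(self):
        rng = np.random.default_rng(3)
        labels = np.array([0] * 25 + [1] * 25)
        X = rng.standard_normal((50, 5))
        X[:, 2] += 3.0 * labels
        table = multi_roc_ranking(X, labels)
        assert table.loc[0, "metabolite"] == "m2"
        assert table.loc[0, "direction"] == "increased"

    def test_decreased_marker_direction_and_orientation(self):
        labels = np.array([0] * 10 + [1] * 10)
        x = np.concatenate([np.arange(10, 20), np.arange(10)]).astype(float)
        table = multi_roc_ranking(x[:, None], labels, names=["down_marker"])
        assert table.loc[0, "direction"] == "decreased"
        assert table.loc[0, "auc"] == 1.0

    def test_null_cohort_aucs_near_half(self):
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(20):
            labels = np.array([0] * 20 + [1] * 20)
            X = rng.standard_normal((40, 3))
            aucs.extend(multi_roc_ranking(X, labels)["auc"])
        # oriented AUC >= 0.5 by construction; null values stay small
        assert np.mean(aucs) < 0.62
        assert max(aucs) < 0.85


class TestMetaboliteLevels:
    def test_level_proportional_to_concentration(self, library):
        cfg = SimConfig(seed=0, n_points=8192, noise_sd=0.0, water_amplitude=0.0)
        specs = [simulate_spectrum({"taurine": c}, cfg) for c in (1.0, 2.0)]
        sset = SpectrumSet(
            specs[0].ppm, np.vstack([s.intensity for s in specs]), ["a", "b"]
        )
        levels = metabolite_levels(sset, library, normalize=False)
        assert np.isclose(levels.loc["b", "taurine"], 2 * levels.loc["a", "taurine"], rtol=1e-2)

    def test_taurine_windows_used(self, library):
        """The taurine level responds to both its 3.27 and 3.45 ppm lines."""
        cfg = SimConfig(seed=0, n_points=8192, noise_sd=0.0, water_amplitude=0.0)
        spec = simulate_spectrum({"taurine": 1.0}, cfg)
        sset = SpectrumSet(spec.ppm, spec.intensity[None, :], ["a"])
        levels = metabolite_levels(sset, library, normalize=False)
        for center in (3.27, 3.45):
            window = np.abs(spec.ppm - center) <= 0.02
            assert spec.intensity[window].sum() > 0.1
            assert levels.loc["a", "taurine"] >= spec.intensity[window].sum()

    def test_zero_concentration_gives_baseline_level(self, library):
        cfg = SimConfig(seed=0, n_points=8192, noise_sd=0.0, water_amplitude=0.0)
        spec = simulate_spectrum({}, cfg)
        sset = SpectrumSet(spec.ppm, spec.intensity[None, :], ["a"])
        levels = metabolite_levels(sset, library, normalize=False)
        # only reference-tail baseline remains under the valine window
        assert levels.loc["a", "valine"] < 1.0

    def test_window_outside_axis_errors(self, library):
        ppm = np.linspace(2.0, 3.0, 100)
        sset = SpectrumSet(ppm, np.ones((1, 100)), ["a"])
        with pytest.raises(ValueError, match="outside"):
            metabolite_levels(sset, library, normalize=False)


def test_percent_formatting_conventions():
    assert pct_half_up(0.36585) == "36.6%"
    assert pct_half_up(0.875) == "87.5%"
    assert pct_truncated(0.0625) == "6.2%"
    assert pct_truncated(155 / 156) == "99.3%"
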