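"""MCC-maximizing cutoff screening against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset, make_record
from modycalib import metrics
from modycalib.data_model import Label
from modycalib.score_conversion import MethodSpec, Conversion, convert_dataset
from modycalib.threshold_optimizer import (
    CalibrationError,
    calibrate_all,
    candidate_cutoffs,
    optimize_arrays,
)


def brute_force_max_mcc(cases, controls):
    """Try every observed value plus +/-inf-like sentinels as a cutoff."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    pooled = np.concatenate((cases, controls))
    cuts = np.concatenate((pooled, [pooled.min() - 1, pooled.max() + 1]))
    best = -2.0
    labels = np.concatenate((np.ones(cases.size, bool),
                             np.zeros(controls.size, bool)))
    for c in cuts:
        best = max(best, metrics.mcc(metrics.tabulate(pooled, labels, c)))
    return best


class TestCandidateCutoffs:
    def test_midpoints_plus_sentinels(self):
        cuts = candidate_cutoffs([0.2, 0.4, 0.8])
        assert cuts.tolist() == pytest.approx([-0.2, 0.3, 0.6, 1.2])

    def test_single_distinct_value_two_candidates(self):
        assert candidate_cutoffs([0.5]).size == 2
        assert candidate_cutoffs([0.5, 0.5]).size == 2

    def test_strictly_increasing_and_covers_all_splits(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=30)
        cuts = candidate_cutoffs(v)
        assert np.all(np.diff(cuts) > 0)
        # each candidate realizes a distinct (n above cutoff) split
        splits = {int(np.sum(v > c)) for c in cuts}
        assert splits == set(range(0, np.unique(v).size + 1))

    def test_no_scored_values_is_error(self):
        with pytest.raises(ValueError):
            candidate_cutoffs([np.nan])


class TestOptimize:
    def test_perfectly_separated_panel(self):
        tr = optimize_arrays("GCK", "m", [0.9, 0.8, 0.7], [0.3, 0.2, 0.1], 0.5)
        assert tr.max_mcc == 1.0
        assert tr.redefined_threshold == pytest.approx(0.5)
        assert tr.n_cases == 3 and tr.n_controls == 3

    def test_single_crossover_matches_hand_enumeration(self):
        # one case below all controls: best split is above that case
        cases, controls = [0.9, 0.05], [0.3, 0.2]
        tr = optimize_arrays("g", "m", cases, controls, 0.5)
        assert tr.max_mcc == pytest.approx(brute_force_max_mcc(cases, controls))
        # tp=1, fn=1, fp=0, tn=2 -> mcc = 2/sqrt(1*2*2*3)... via oracle
        assert tr.max_mcc == pytest.approx((1 * 2) / math.sqrt(1 * 2 * 2 * 3))

    def test_identical_distributions_small_mcc(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 40)
        tr = optimize_arrays("g", "m", v[::2], v[1::2], 0.5)
        assert tr.max_mcc == pytest.approx(brute_force_max_mcc(v[::2], v[1::2]))
        assert 0.0 <= tr.max_mcc < 0.6

    def test_max_mcc_at_least_default(self):
        rng = np.random.default_rng(1)
        tr = optimize_arrays("g", "m", rng.normal(0.6, 0.2, 30),
                             rng.normal(0.4, 0.2, 30), 0.5)
        assert tr.max_mcc >= tr.default_mcc

    def test_roc_points_are_valid(self):
        tr = optimize_arrays("g", "m", [0.9, 0.4], [0.5, 0.1], 0.45)
        for p in tr.roc:
            assert 0.0 <= p.sensitivity <= 1.0
            assert 0.0 <= p.specificity <= 1.0
        assert tr.max_mcc == max(p.mcc_at for p in tr.roc)

    def test_empty_class_is_calibration_error(self):
        with pytest.raises(CalibrationError, match="g/m"):
            optimize_arrays("g", "m", [], [0.1], 0.5)
        with pytest.raises(CalibrationError):
            optimize_arrays("g", "m", [np.nan], [0.1], 0.5)

    def test_tie_break_prefers_higher_specificity(self):
        # both cutoffs 0.35 and 0.55 give the same confusion? construct ties:
        # cases {0.6, 0.7}, controls {0.2, 0.3}: every cutoff in (0.3, 0.6)
        # attains MCC 1; candidates include midpoint 0.45; the chosen cutoff
        # must be a maximizer and specificity 1
        tr = optimize_arrays("g", "m", [0.6, 0.7], [0.2, 0.3], 0.5)
        assert tr.max_mcc == 1.0
        cc = metrics.tabulate([0.6, 0.7, 0.2, 0.3],
                              [True, True, False, False],
                              tr.redefined_threshold)
        assert metrics.specificity(cc) == 1.0


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_optimize_equals_brute_force_oracle(data):
    """Exhaustive-split screening equals trying every data value as cutoff."""
    n1 = data.draw(st.integers(1, 25))
    n0 = data.draw(st.integers(1, 25))
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    cases = np.round(rng.normal(0.6, 0.25, n1), 2)
    controls = np.round(rng.normal(0.4, 0.25, n0), 2)
    tr = optimize_arrays("g", "m", cases, controls, 0.5)
    assert tr.max_mcc == pytest.approx(brute_force_max_mcc(cases, controls),
                                       abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_monotone_transform_equivariance(seed):
    """A strictly increasing score transform leaves max MCC unchanged and
    maps the redefined threshold to a classification-equivalent cutoff."""
    rng = np.random.default_rng(seed)
    cases = rng.normal(0.7, 0.2, 20)
    controls = rng.normal(0.3, 0.2, 20)
    f = lambda x: np.exp(1.7 * x) - 2.0  # strictly increasing
    tr = optimize_arrays("g", "m", cases, controls, 0.5)
    tr2 = optimize_arrays("g", "m", f(cases), f(controls), f(0.5))
    assert tr2.max_mcc == pytest.approx(tr.max_mcc, abs=1e-12)
    pooled = np.concatenate((cases, controls))
    labels = np.concatenate((np.ones(20, bool), np.zeros(20, bool)))
    cc1 = metrics.tabulate(pooled, labels, tr.redefined_threshold)
    cc2 = metrics.tabulate(f(pooled), labels, tr2.redefined_threshold)
    assert (cc1.tp, cc1.fp, cc1.fn, cc1.tn) == (cc2.tp, cc2.fp, cc2.fn, cc2.tn)


class TestCalibrateAll:
    def test_full_panel_bookkeeping(self, generated_panel, registry):
        from modycalib.data_model import filter_for_analysis
        from modycalib.score_conversion import convert_dataset

        ds = filter_for_analysis(generated_panel[0])
        converted = convert_dataset(ds, registry)
        results, skips = calibrate_all(ds, registry, converted)
        assert len(results) + len(skips) == 7 * 12
        for (gene, method), (tr, drow, rrow) in results.items():
            assert rrow.mcc >= drow.mcc  # default cutoff always a candidate
            assert tr.gene == gene and tr.method == method

    def test_missing_class_skipped_others_intact(self):
        reg = (MethodSpec("A", Conversion.IDENTITY, 0.5, bounded01=False),)
        recs = [make_record("GCK", "c1", scores={"A": 0.9}),
                make_record("GCK", "k1", Label.CONTROL, scores={"A": 0.1}),
                make_record("INS", "c2", scores={"A": 0.8})]  # no INS controls
        ds = make_dataset(recs)
        results, skips = calibrate_all(ds, reg, convert_dataset(ds, reg))
        assert ("GCK", "A") in results
        assert len(skips) == 1 and skips[0].gene == "INS"
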