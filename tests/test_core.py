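"""Cosine-bank detection: amplitude statistic, grid fit, analytic oracle."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from moltimetable.core import (CosinePhaseGrid, DetectionConfig,
                               amplitude_stat, best_cosine_fit, cosine_bank,
                               closed_form_peak, detect_oscillating)
from moltimetable.design import TimeCourseDesign, default_design
from moltimetable.io import ExpressionMatrix


def _em(rows, design, ids=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    if ids is None:
        ids = [f"c{i}" for i in range(rows.shape[0])]
    return ExpressionMatrix(np.array(ids, object), rows, design)


def _circular_diff(a, b, period=24.0):
    return abs((a - b + period / 2) % period - period / 2)


class TestPhaseGrid:
    def test_default_bank_holds_1440_curves(self):
        grid = CosinePhaseGrid()
        assert grid.n_curves == 1440
        peaks = grid.peak_times
        assert len(peaks) == 1440
        assert peaks[0] == 0.0
        assert peaks[-1] < 24.0
        assert np.allclose(np.diff(peaks), 1.0 / 60.0)

    def test_step_must_divide_period(self):
        with pytest.raises(ValueError):
            CosinePhaseGrid(24.0, 7.0)

    def test_bank_shape(self, design_ll):
        bank = cosine_bank(CosinePhaseGrid(), design_ll.times)
        assert bank.shape == (1440, 24)


class TestAmplitudeStat:
    def test_alternating_row(self):
        assert amplitude_stat([8, 12, 8, 12]) == pytest.approx(0.2)

    def test_constant_row_is_zero(self):
        assert amplitude_stat([5.0] * 6) == 0.0

    def test_planted_amplitude_is_recovered(self, design_ll, cosine_row):
        row = cosine_row(design_ll.times, baseline=10.0, a=0.3, peak=17.0)
        assert amplitude_stat(row) == pytest.approx(0.3, abs=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            amplitude_stat([0.0, 0.0, 0.0, 0.0])


class TestBestCosineFit:
    def test_recovers_on_grid_peak(self, design_ll, cosine_row):
        row = cosine_row(design_ll.times, peak=6.0)
        r, peak = best_cosine_fit(row, design_ll)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert peak == pytest.approx(6.0, abs=1e-9)

    def test_negated_cosine_lands_antiphase(self, design_ll):
        t = design_ll.times
        row = 10.0 - 3.0 * np.cos(2 * np.pi * (t - 6.0) / 24.0)
        r, peak = best_cosine_fit(row, design_ll)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert peak == pytest.approx(18.0, abs=1e-9)

    def test_zero_variance_rejected(self, design_ll):
        with pytest.raises(ValueError, match="zero-variance"):
            best_cosine_fit(np.ones(24), design_ll)

    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-5.0, 100.0),
           peak=st.floats(0.0, 23.9))
    @settings(max_examples=40, derandomize=True)
    def test_invariant_under_positive_affine_maps(self, scale, shift, peak,
                                                  design_ll, cosine_row):
        row = cosine_row(design_ll.times, peak=peak)
        r0, p0 = best_cosine_fit(row, design_ll)
        r1, p1 = best_cosine_fit(scale * row + shift, design_ll)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == p0

    def test_matches_scipy_pearson(self, design_ll):
        """Vectorised correlations agree with the reference implementation."""
        rng = np.random.default_rng(11)
        row = rng.gamma(3.0, 4.0, size=24)
        grid = CosinePhaseGrid()
        bank = cosine_bank(grid, design_ll.times)
        r_best, peak = best_cosine_fit(row, design_ll, grid)
        idx = int(round(peak * 60.0))
        ref = scipy.stats.pearsonr(row, bank[idx]).statistic
        assert r_best == pytest.approx(ref, abs=1e-12)
        # and no other template correlates better, per scipy
        for j in rng.choice(1440, size=25, replace=False):
            assert scipy.stats.pearsonr(row, bank[j]).statistic <= r_best + 1e-12


class TestClosedFormPeak:
    def test_self_recovery(self, design_ll, cosine_row):
        row = cosine_row(design_ll.times, peak=6.0)
        assert closed_form_peak(row, design_ll) == pytest.approx(6.0,
                                                                 abs=1e-9)

    def test_off_grid_phase(self, design_ll, cosine_row):
        row = cosine_row(design_ll.times, peak=13.37)
        assert closed_form_peak(row, design_ll) == pytest.approx(13.37,
                                                                 abs=1e-9)

    def test_pure_sine_peaks_at_quarter_period(self, design_ll):
        row = 10.0 + np.sin(2 * np.pi * design_ll.times / 24.0)
        assert closed_form_peak(row, design_ll) == pytest.approx(6.0,
                                                                 abs=1e-9)

    def test_refuses_partial_cycle_design(self):
        design = TimeCourseDesign((0.0, 2.0, 4.0, 6.0, 8.0), "LL")
        with pytest.raises(ValueError, match="integer number of periods"):
            closed_form_peak(np.arange(5.0), design)

    def test_refuses_non_uniform_design(self):
        design = TimeCourseDesign((0.0, 2.0, 5.0, 24.0 - 2.0, 24.0 - 1.0,
                                   24.0), "LL")
        with pytest.raises(ValueError):
            closed_form_peak(np.arange(6.0), design)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_grid_search_agrees_with_oracle_on_smooth_rows(self, seed,
                                                           design_ll):
        """On uniform full-cycle designs the grid peak must sit within half
        a grid step of the continuous correlation maximiser, for arbitrary
        rows — not only pure cosines."""
        rng = np.random.default_rng(seed)
        t = design_ll.times
        row = (10.0
               + rng.uniform(0.5, 3.0) * np.cos(
                   2 * np.pi * (t - rng.uniform(0, 24)) / 24.0)
               + rng.uniform(0.0, 0.4) * np.cos(
                   2 * np.pi * (t - rng.uniform(0, 24)) / 12.0)
               + rng.normal(0.0, 0.2, size=t.size))
        _, grid_peak = best_cosine_fit(row, design_ll)
        oracle = closed_form_peak(row, design_ll)
        assert _circular_diff(grid_peak, oracle) <= 0.5 / 60.0 + 1e-9


class TestDetect:
    def test_noiseless_planted_oscillators_only(self, design_ll, cosine_row):
        rows = [cosine_row(design_ll.times, a=a, peak=p)
                for a, p in [(0.2, 3.0), (0.35, 11.0), (0.5, 22.0)]]
        rows += [np.full(24, 7.0), np.full(24, 0.0)]  # flat -> excluded
        res = detect_oscillating(_em(rows, design_ll))
        assert res.n_detected == 3
        assert set(res.passing["contig_id"]) == {"c0", "c1", "c2"}
        assert len(res.excluded) == 2

    def test_all_constant_matrix_has_no_stats(self, design_ll):
        res = detect_oscillating(_em([np.full(24, 1.0), np.full(24, 2.0)],
                                     design_ll))
        assert len(res.stats) == 0
        assert len(res.excluded) == 2

    def test_empty_matrix_rejected(self, design_ll):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.array([], object), np.empty((0, 24)),
                             design_ll)

    def test_amplitude_cutoff_is_binding(self, design_ll, cosine_row):
        """A perfect cosine with a = 0.14 fails the default a >= 0.15 cut
        even though its correlation is exactly 1."""
        res = detect_oscillating(_em([cosine_row(design_ll.times, a=0.14)],
                                     design_ll))
        row = res.stats.iloc[0]
        assert row["best_r"] == pytest.approx(1.0, abs=1e-9)
        assert row["amplitude"] == pytest.approx(0.14, abs=1e-9)
        assert not row["passes"]

    def test_block_size_does_not_change_results(self, design_ll):
        rng = np.random.default_rng(5)
        x = rng.gamma(3.0, 5.0, size=(40, 24))
        full = detect_oscillating(_em(x, design_ll))
        chunked = detect_oscillating(_em(x, design_ll), block_size=7)
        assert full.stats.equals(chunked.stats)

    @pytest.mark.parametrize("tighten", ["a_cutoff", "r_cutoff"])
    def test_raising_cutoffs_shrinks_passing_set(self, tighten, design_ll):
        rng = np.random.default_rng(9)
        em, _ = _synthetic_mixture(rng, design_ll)
        loose = detect_oscillating(em, DetectionConfig())
        kwargs = {tighten: {"a_cutoff": 0.3, "r_cutoff": 0.95}[tighten]}
        tight = detect_oscillating(em, DetectionConfig(**kwargs))
        assert tight.passing_ids() <= loose.passing_ids()


def _synthetic_mixture(rng, design, n=60):
    t = design.times
    rows, ids = [], []
    for i in range(n):
        base = rng.uniform(5, 50)
        amp = rng.uniform(0.0, 0.6)
        peak = rng.uniform(0, 24)
        row = base * (1 + np.sqrt(2) * amp
                      * np.cos(2 * np.pi * (t - peak) / 24.0))
        row = np.clip(row + rng.normal(0, 0.1 * base, size=t.size), 0, None)
        rows.append(row)
        ids.append(f"c{i}")
    return _em(rows, design, ids), None
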