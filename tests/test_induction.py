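"""Threshold classifier, Bernoulli draws, and the marker surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senolattice import (
    CalibrationError,
    InductionSpec,
    MarkerPanel,
    SurrogateParams,
    ThresholdSet,
    classify_presenescent,
    compute_thresholds,
    draw_induction,
    read_marker_csv,
    simulate_marker_population,
    write_marker_csv,
)
from senolattice.induction import classified_fraction, panels_at_day


def panel(v):
    return MarkerPanel(v, v, v, v)


class TestThresholds:
    def test_mean_of_population(self):
        pop = [
            MarkerPanel(1, 10, 100, 0.5),
            MarkerPanel(2, 20, 200, 1.0),
            MarkerPanel(3, 30, 300, 1.5),
        ]
        thr = compute_thresholds(pop)
        assert thr.p21 == 2 and thr.sa_b_gal == 20
        assert thr.ros == 200 and thr.dna_damage == 1.0

    def test_single_cell_population(self):
        thr = compute_thresholds([MarkerPanel(1, 2, 3, 4)])
        assert thr.as_array().tolist() == [1, 2, 3, 4]

    def test_empty_population_raises(self):
        with pytest.raises(CalibrationError):
            compute_thresholds([])


class TestClassifier:
    thr = ThresholdSet(1.0, 1.0, 1.0, 1.0)

    def test_all_four_above_is_positive(self):
        assert classify_presenescent(panel(1.1), self.thr)

    def test_three_of_four_is_negative(self):
        assert not classify_presenescent(MarkerPanel(1.1, 1.1, 1.1, 0.9), self.thr)

    def test_exact_threshold_is_negative(self):
        """Strict inequality: a marker exactly at threshold does not count."""
        assert not classify_presenescent(MarkerPanel(1.1, 1.0, 1.1, 1.1), self.thr)

    @settings(deadline=None, derandomize=True)
    @given(
        levels=st.lists(st.floats(0, 10, allow_nan=False), min_size=4, max_size=4),
        bump=st.floats(0.001, 5),
        idx=st.integers(0, 3),
    )
    def test_monotone_in_levels(self, levels, bump, idx):
        """Raising any one marker level never flips a positive call to
        negative; raising a threshold never flips negative to positive."""
        p = MarkerPanel(*levels)
        raised = list(levels)
        raised[idx] += bump
        if classify_presenescent(p, self.thr):
            assert classify_presenescent(MarkerPanel(*raised), self.thr)
        thr_raised = list(self.thr.as_array())
        thr_raised[idx] += bump
        if not classify_presenescent(p, self.thr):
            assert not classify_presenescent(p, ThresholdSet(*thr_raised))


class TestBernoulliDraws:
    @pytest.mark.parametrize("p,expected", [(0.0, False), (1.0, True)])
    def test_degenerate_probabilities(self, p, expected, rng):
        spec = InductionSpec(mode="bernoulli", p_ind=p)
        assert all(draw_induction(spec, rng) is expected for _ in range(50))

    def test_empirical_frequency(self, rng):
        spec = InductionSpec(mode="bernoulli", p_ind=0.1)
        n = 100_000
        hits = sum(draw_induction(spec, rng) for _ in range(n))
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) < 3 * se


class TestSurrogate:
    def test_same_seed_same_trajectories(self):
        params = SurrogateParams()
        a = simulate_marker_population(params, 5, np.random.default_rng(7))
        b = simulate_marker_population(params, 5, np.random.default_rng(7))
        assert a.equals(b)

    def test_zero_noise_population_classifies_nobody(self):
        """Identical cells cannot strictly exceed their own population mean."""
        params = SurrogateParams(cell_sd=0.0, marker_sd=0.0, day_sd=0.0)
        pop = simulate_marker_population(params, 20, np.random.default_rng(0))
        thr = compute_thresholds(panels_at_day(pop, 21))
        assert classified_fraction(pop, thr) == 0.0

    def test_default_classified_fraction_near_ten_percent(self):
        """Self-calibrated all-of-four classification of the default
        surrogate population lands near the 10% design target."""
        params = SurrogateParams()
        fracs = []
        for seed in range(10):
            pop = simulate_marker_population(
                params, 1000, np.random.default_rng(seed)
            )
            thr = compute_thresholds(panels_at_day(pop, 21))
            fracs.append(classified_fraction(pop, thr))
        mean = np.mean(fracs)
        assert 0.06 < mean < 0.14
        # with positive noise the ALL-policy fraction is strictly between 0
        # and each marker's marginal exceedance fraction
        assert all(0 < f < 0.5 for f in fracs)

    def test_surrogate_mode_requires_calibration(self, rng):
        spec = InductionSpec(mode="marker_surrogate")
        with pytest.raises(CalibrationError):
            draw_induction(spec, rng)

    def test_calibrated_surrogate_draw_rate_matches_population_fraction(self):
        rng = np.random.default_rng(3)
        spec = InductionSpec(mode="marker_surrogate").calibrate(rng)
        n = 400
        hits = sum(draw_induction(spec, rng) for _ in range(n))
        # population fraction ~0.10 with seed-to-seed sd ~0.017
        assert 0.03 < hits / n < 0.20


def test_marker_csv_roundtrip(tmp_path):
    pop = simulate_marker_population(SurrogateParams(), 3, np.random.default_rng(1))
    path = tmp_path / "markers.csv"
    write_marker_csv(pop, path)
    back = read_marker_csv(path)
    assert list(back.columns) == ["cell_id", "day", "p21", "sa_b_gal", "ros", "dna_damage"]
    assert len(back) == 3 * 22
    np.testing.assert_allclose(
        back["p21"].to_numpy(), pop["p21"].to_numpy(), rtol=1e-9
    )


def test_thresholdset_json_roundtrip(tmp_path):
    thr = ThresholdSet(1.5, 2.5, 3.5, 4.5, reference_day=21)
    path = tmp_path / "thr.json"
    thr.to_json(path)
    assert ThresholdSet.from_json(path) == thr
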