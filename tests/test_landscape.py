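"""Peak detection, intensity/width/area metrics, sweeps and surveys."""

from dataclasses import replace

import numpy as np
import pytest

from _oracles import brute_force_extrema
from goldilocks.landscape import (
    default_window,
    find_extrema,
    goldilocks_peaks,
    intensity_map,
    parameter_sweep,
    peak_area,
    peak_width_half_height,
    sweep_factors,
    three_state_scenarios,
)
from goldilocks.models import (
    CleavageRates,
    FoldingThreeState,
    FoldingTwoState,
    ModelSpec,
    lifetime,
    lifetime_curve,
)


class TestFindExtrema:
    def test_equal_rates_give_monotone_landscape(self):
        spec = ModelSpec(
            states=2,
            folding=FoldingTwoState(K_D=1.0, n=4.0),
            rates=CleavageRates(k_u=1.0, k_f=1.0),
            units="relative",
        )
        assert find_extrema(spec, (0.01, 100)) == []

    def test_reference_landscape_min_then_max(self, rel_two_state):
        extrema = find_extrema(rel_two_state, (0.01, 100))
        assert [e.kind for e in extrema] == ["minimum", "maximum"]
        assert extrema[0].mg < extrema[1].mg

    def test_agrees_with_dense_grid_oracle(self, rel_two_state):
        extrema = find_extrema(rel_two_state, (0.01, 100))
        oracle = brute_force_extrema(rel_two_state, (0.01, 100))
        assert len(extrema) == len(oracle)
        for e, (kind, mg, lt) in zip(extrema, oracle):
            assert e.kind == kind
            assert e.mg == pytest.approx(mg, rel=1e-3)
            assert e.lifetime == pytest.approx(lt, rel=1e-6)

    def test_scaling_midpoints_scales_extrema(self, rel_two_state):
        base = find_extrema(rel_two_state, (0.01, 100))
        scaled_spec = replace(
            rel_two_state, folding=replace(rel_two_state.folding, K_D=2.0)
        )
        scaled = find_extrema(scaled_spec, (0.02, 200))
        for b, s in zip(base, scaled):
            assert s.mg == pytest.approx(2 * b.mg, rel=1e-9)

    def test_bad_window_rejected(self, rel_two_state):
        with pytest.raises(ValueError):
            find_extrema(rel_two_state, (-1.0, 10.0))
        with pytest.raises(ValueError):
            find_extrema(rel_two_state, (5.0, 5.0))


class TestGoldilocksPeaks:
    def test_modest_peak_at_ratio3_n4(self):
        spec = ModelSpec(
            states=2,
            folding=FoldingTwoState(K_D=1.0, n=4.0),
            rates=CleavageRates(k_u=1.0, k_f=1.0 / 3.0),
            units="relative",
        )
        peaks = goldilocks_peaks(spec)
        assert len(peaks) == 1
        assert peaks[0].intensity > 1.0

    def test_sharp_transition_intensity_approaches_rate_ratio(self):
        """As folding becomes step-like, the min->max lifetime jump tends to
        k_u/k_f; convergence is logarithmically slow (4.67 at n=200, within
        2% of the limit only by n ~ 1000, the supported ceiling)."""
        ratio = 5.0

        def intensity(n):
            spec = ModelSpec(
                states=2,
                folding=FoldingTwoState(K_D=1.0, n=n),
                rates=CleavageRates(k_u=1.0, k_f=1.0 / ratio),
                units="relative",
            )
            (peak,) = goldilocks_peaks(spec)
            return peak.intensity

        i200, i1000 = intensity(200), intensity(1000)
        assert i200 == pytest.approx(4.668, abs=0.01)  # brute-force oracle value
        assert i200 < i1000 < ratio
        assert i1000 == pytest.approx(ratio, rel=0.02)

    def test_resolved_three_state_transitions_give_two_peaks(self):
        spec = ModelSpec(
            states=3,
            folding=FoldingThreeState(K_D1=1.0, n1=8.0, K_D2=100.0, n2=8.0),
            rates=CleavageRates(k_u=1.0, k_i=0.2, k_f=0.02),
            units="relative",
        )
        peaks = goldilocks_peaks(spec, (0.01, 1e4))
        assert len(peaks) == 2
        assert all(p.intensity > 1 for p in peaks)

    def test_no_peak_conditions(self, rel_two_state):
        # (i) non-folding RNA
        one = ModelSpec(states=1, rates=CleavageRates(k_u=1.0), units="relative")
        assert goldilocks_peaks(one, (0.01, 100)) == []
        # (ii) always folded: midpoint far below any surveyed concentration
        folded = replace(rel_two_state, folding=FoldingTwoState(K_D=1e-9, n=4.1))
        assert goldilocks_peaks(folded, (0.01, 100)) == []
        # (iii) equal rate constants
        equal = replace(rel_two_state, rates=CleavageRates(k_u=1.0, k_f=1.0))
        assert goldilocks_peaks(equal, (0.01, 100)) == []
        # (iv) very gradual transition with modest protection
        gradual = ModelSpec(
            states=2,
            folding=FoldingTwoState(K_D=1.0, n=0.5),
            rates=CleavageRates(k_u=1.0, k_f=0.5),
            units="relative",
        )
        assert goldilocks_peaks(gradual, (0.001, 1000)) == []


class TestPeakMetrics:
    def test_width_and_area_deterministic(self, rel_two_state):
        (p1,) = goldilocks_peaks(rel_two_state)
        (p2,) = goldilocks_peaks(rel_two_state)
        assert peak_area(rel_two_state, p1) == peak_area(rel_two_state, p2)
        assert peak_width_half_height(rel_two_state, p1) == peak_width_half_height(
            rel_two_state, p2
        )

    def test_larger_n_concentrates_area(self):
        """At fixed k_u/k_f a sharper transition narrows the peak: the same
        protection is concentrated locally instead of dispersed in
        Mg2+-space."""

        def metrics(n):
            spec = ModelSpec(
                states=2,
                folding=FoldingTwoState(K_D=1.0, n=n),
                rates=CleavageRates(k_u=1.0, k_f=0.2),
                units="relative",
            )
            (peak,) = goldilocks_peaks(spec)
            return (
                peak_width_half_height(spec, peak),
                peak_area(spec, peak),
                peak.intensity,
            )

        w4, a4, i4 = metrics(4.0)
        w16, a16, i16 = metrics(16.0)
        assert w16 < w4
        assert a16 / w16 > a4 / w4  # protection concentrated into a narrower span
        assert i16 > i4

    def test_area_requires_window_spanning_peak(self, rel_two_state):
        (peak,) = goldilocks_peaks(rel_two_state)
        with pytest.raises(ValueError):
            peak_area(rel_two_state, peak, window=(10.0, 100.0))


class TestParameterSweep:
    def test_factor_ladder_matches_doubling_rule(self):
        assert sweep_factors() == pytest.approx(
            [1.2, 1.4, 1.8, 2.6, 4.2, 7.4, 13.8, 26.6]
        )

    def test_kd_sweep_shifts_peak_position(self, rel_two_state):
        res = parameter_sweep(rel_two_state, "K_D", directions=("multiply",))
        positions = []
        for spec in res.specs:
            (peak,) = goldilocks_peaks(spec, (0.001, 1000))
            positions.append(peak.maximum.mg)
        # position scales with K_D: each factor moves the peak proportionally
        assert positions == pytest.approx(
            [positions[0] * f for f in res.factors], rel=1e-6
        )

    def test_n_sweep_sharpens_without_moving_peak(self, rel_two_state):
        res = parameter_sweep(rel_two_state, "n", directions=("multiply",))
        mgs, intensities = [], []
        for spec in res.specs:
            (peak,) = goldilocks_peaks(spec, (0.001, 1000))
            mgs.append(peak.maximum.mg)
            intensities.append(peak.intensity)
        assert np.all(np.diff(intensities) > 0)  # sharper = more intense
        assert max(mgs) / min(mgs) < 2.5  # position approximately fixed

    def test_unknown_parameter_rejected(self, rel_two_state):
        with pytest.raises(ValueError):
            parameter_sweep(rel_two_state, "k_q")


class TestIntensityMap:
    def test_survey_monotone_and_anchored(self):
        m = intensity_map(np.geomspace(1, 20, 8), np.geomspace(1, 50, 8))
        # ratio = 1 column: no peak anywhere (no differential protection)
        assert not m.peak_present[:, 0].any()
        assert m.intensity[:, 0] == pytest.approx(1.0)
        # intensity non-decreasing along n (rows) and ratio (columns)
        assert np.all(np.diff(m.intensity, axis=0) >= -1e-9)
        assert np.all(np.diff(m.intensity, axis=1) >= -1e-9)
        # peak-present region upward-closed in both axes
        assert np.all(m.peak_present[1:, :] >= m.peak_present[:-1, :])
        assert np.all(m.peak_present[:, 1:] >= m.peak_present[:, :-1])

    def test_modest_cell_has_peak(self):
        m = intensity_map([4.0], [3.0])
        assert m.peak_present[0, 0]
        assert m.intensity[0, 0] > 1.0

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            intensity_map([4.0], [0.5])


class TestThreeStateScenarios:
    def test_protected_intermediate_favors_early_peak(self, rel_three_state):
        k_f = rel_three_state.rates.k_f
        (res,) = three_state_scenarios([k_f / 4], rel_three_state)
        assert res.dominant_position == "early"

    def test_labile_intermediate_favors_late_peak(self, rel_three_state):
        k_u = rel_three_state.rates.k_u
        (res,) = three_state_scenarios([k_u * 3], rel_three_state)
        assert res.dominant_position == "late"

    def test_ki_equal_kf_collapses_to_transition1_two_state(self, rel_three_state):
        (res,) = three_state_scenarios([rel_three_state.rates.k_f], rel_three_state)
        two = ModelSpec(
            states=2,
            folding=FoldingTwoState(
                K_D=rel_three_state.folding.K_D1, n=rel_three_state.folding.n1
            ),
            rates=CleavageRates(
                k_u=rel_three_state.rates.k_u, k_f=rel_three_state.rates.k_f
            ),
            units="relative",
        )
        grid = np.geomspace(0.01, 100, 500)
        assert lifetime_curve(grid, res.spec).lifetime == pytest.approx(
            lifetime_curve(grid, two).lifetime, rel=1e-14
        )

    def test_requires_three_state_base(self, rel_two_state):
        with pytest.raises(ValueError):
            three_state_scenarios([0.1], rel_two_state)


def test_default_window_spans_all_midpoints(rel_three_state):
    lo, hi = default_window(rel_three_state)
    assert lo == pytest.approx(0.01) and hi == pytest.approx(200.0)
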