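"""Forward model: frame expectations, decay handling, clinical fixtures."""

import numpy as np
import pytest

from gdctac import DecayConfig, GDCParams, TimeActivityCurve, clinical_frames, expected_counts
from gdctac.tac_model import decay_factor, load_clinical_table


class TestClinicalFixtures:
    def test_nine_cases(self, case_list):
        assert len(case_list) == 9
        assert [c.case_id for c in case_list] == [
            "1L", "1R", "1T", "2L", "2R", "2T", "3L", "3R", "3T",
        ]

    def test_first_case_digits(self, cases):
        p = cases["1L"].params
        assert (p.t_A, p.a, p.b) == (0.195, 0.846, 0.909)
        assert (p.alpha, p.beta) == (0.8577, 0.001849)
        assert p.S == pytest.approx(3.529e6)

    def test_washout_shapes_all_valid(self, case_list):
        for c in case_list:
            assert 0.85 < c.params.alpha < 0.95
            assert c.params.shape.washout.is_washout

    def test_last_case_washout(self, cases):
        p = cases["3T"].params
        assert (p.alpha, p.beta) == (0.8947, 0.002554)

    def test_printed_fit_error_mean(self):
        df = load_clinical_table()
        assert df["fit_err_pct"].mean() == pytest.approx(1.44, abs=0.005)


class TestFrameGrid:
    def test_clinical_layout(self, frames):
        assert frames.n_frames == 89
        assert frames.frame_start[0] == 0.0
        assert frames.frame_end[-1] == 89.0
        np.testing.assert_allclose(frames.frame_duration, 1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frame_start=[0, 0.5], frame_duration=[1, 1], counts=[1, 1]),
            dict(frame_start=[0, 1], frame_duration=[1, -1], counts=[1, 1]),
            dict(frame_start=[0, 1], frame_duration=[1, 1], counts=[1, -2]),
        ],
    )
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TimeActivityCurve(**{k: np.asarray(v, float) for k, v in kwargs.items()})


class TestExpectedCounts:
    def test_total_expectation_is_scale(self, cases, no_decay):
        """Over a grid covering essentially all of [0, inf), counts sum to S."""
        p = cases["1T"].params
        unit = GDCParams.from_values(p.t_A, p.a, p.b, p.alpha, p.beta, 1.0)
        grid = clinical_frames(n_frames=10_000)  # 10^4 min of 1-min frames
        M = expected_counts(unit, grid, no_decay)
        assert M.sum() == pytest.approx(1.0, abs=1e-4)

    def test_decay_factor_halves_at_half_life(self):
        d = DecayConfig(enabled=True, half_life=360.4)
        assert decay_factor(360.4, d) == pytest.approx(0.5, rel=1e-12)
        assert decay_factor(123.0, DecayConfig(enabled=False)) == 1.0

    def test_decay_never_increases_expectations(self, cases, frames):
        p = cases["2R"].params
        on = expected_counts(p, frames, DecayConfig(enabled=True))
        off = expected_counts(p, frames, DecayConfig(enabled=False))
        assert np.all(on <= off + 1e-12)

    def test_integration_rules_agree_away_from_peak(self, cases, frames, no_decay):
        """Midpoint and Gauss-Legendre agree once the density is smooth."""
        p = cases["2R"].params
        g = expected_counts(p, frames, no_decay, method="gauss3")
        m = expected_counts(p, frames, no_decay, method="midpoint")
        dev = np.abs(m / g - 1.0)
        assert dev[4:].max() < 1e-3  # frames 5-89
        assert dev[1:].max() < 0.025  # frames 2-4: peak curvature

    def test_arrival_shift_translates_curve(self, cases, no_decay):
        """Shifting t_A by a whole frame shifts the expectation curve."""
        p = cases["2T"].params
        grid = clinical_frames(n_frames=120)
        base = expected_counts(p, grid, no_decay)
        shifted = expected_counts(
            GDCParams.from_values(p.t_A + 3.0, p.a, p.b, p.alpha, p.beta, p.S),
            grid,
            no_decay,
        )
        np.testing.assert_allclose(shifted[3:], base[:-3], rtol=1e-10)

    def test_all_fixtures_positive_after_first_frame(self, case_list, frames, no_decay):
        for c in case_list:
            M = expected_counts(c.params, frames, no_decay)
            assert np.all(M[1:] > 0)

    def test_frames_before_arrival_have_zero_expectation(self, no_decay):
        p = GDCParams.from_values(0.9, 2.0, 3.0, 0.9, 0.01, 1e6)
        grid = TimeActivityCurve(
            frame_start=np.array([0.0, 0.3, 0.6]),
            frame_duration=np.array([0.3, 0.3, 0.3]),
            counts=np.zeros(3),
        )
        M = expected_counts(p, grid, no_decay)
        assert M[0] == 0.0 and M[1] == 0.0  # both end before t_A = 0.9

    def test_longer_frames_collect_proportional_counts(self, cases, no_decay):
        """A 2-min frame in the slow tail collects ~2x a 1-min frame."""
        p = cases["2T"].params
        one = TimeActivityCurve(
            frame_start=np.array([60.0, 61.0]),
            frame_duration=np.array([1.0, 1.0]),
            counts=np.zeros(2),
        )
        two = TimeActivityCurve(
            frame_start=np.array([60.0]),
            frame_duration=np.array([2.0]),
            counts=np.zeros(1),
        )
        M1 = expected_counts(p, one, no_decay)
        M2 = expected_counts(p, two, no_decay)
        assert M2[0] == pytest.approx(M1.sum(), rel=1e-9)
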