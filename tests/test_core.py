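import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prevsize import (
    InvalidPrecisionError,
    PlanningWarning,
    StudyParameters,
    anticipated_ci,
    apply_design_effect,
    apply_loss,
    compute_base_n,
    compute_sample_size,
    z_for_confidence,
)

# (prevalence, precision) -> printed sample size, CI bounds, CI width; the
# published relationship-of-precision-to-CI-width table.
GOLDEN_TABLE = [
    (0.25, 0.02, 1801, (23.0, 27.0), 4.0),
    (0.25, 0.05, 289, (20.0, 30.0), 10.0),
    (0.25, 0.10, 73, (15.0, 35.0), 20.0),
    (0.30, 0.02, 2017, (28.0, 32.0), 4.0),
    (0.30, 0.05, 323, (25.0, 35.0), 10.0),
    (0.30, 0.10, 81, (20.0, 40.0), 20.0),
]

valid_pd = st.tuples(
    st.floats(0.01, 0.99), st.floats(0.001, 0.5)
).filter(lambda t: t[1] < t[0] and t[1] < 1 - t[0])


class TestZForConfidence:
    def test_conventional_95(self):
        assert z_for_confidence(0.95) == pytest.approx(1.96, abs=5e-3)

    def test_median_quartile(self):
        # 50% two-sided level is the upper-quartile quantile 0.6745
        assert z_for_confidence(0.50) == pytest.approx(0.6745, abs=5e-5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5, float("nan")])
    def test_rejects_degenerate_levels(self, bad):
        with pytest.raises(ValueError):
            z_for_confidence(bad)


class TestBaseN:
    @pytest.mark.parametrize("p,d,expected,_ci,_w", GOLDEN_TABLE)
    def test_published_table_reproduces(self, p, d, expected, _ci, _w):
        assert compute_base_n(p, d) == expected

    def test_hand_evaluated_ceiling(self):
        # 1.96^2 * 0.3 * 0.7 / 0.03^2 = 896.4 -> 897
        assert compute_base_n(0.30, 0.03) == 897

    @pytest.mark.parametrize("target_n", [10, 100, 997, 12345])
    def test_algebraic_inversion_at_half(self, target_n):
        # at p = 0.5, d = z/(2 sqrt N) makes the closed form exactly N
        z = z_for_confidence(0.95)
        d = 0.5 * z / math.sqrt(target_n)
        assert compute_base_n(0.5, d) == target_n

    @pytest.mark.parametrize("p,d", [(0.02, 0.05), (0.95, 0.05), (0.3, 0.3), (0.3, 0.8)])
    def test_rejects_precision_at_or_beyond_bound(self, p, d):
        with pytest.raises(InvalidPrecisionError):
            compute_base_n(p, d)

    @pytest.mark.parametrize("p,d", [(float("nan"), 0.05), (0.3, float("inf")), (0.0, 0.05), (1.0, 0.05)])
    def test_rejects_nonfinite_or_degenerate(self, p, d):
        with pytest.raises(ValueError):
            compute_base_n(p, d)

    @settings(max_examples=200, deadline=None)
    @given(valid_pd)
    def test_symmetry_in_prevalence(self, pd):
        p, d = pd
        assert compute_base_n(p, d) == compute_base_n(1 - p, d)

    @settings(max_examples=200, deadline=None)
    @given(valid_pd, st.floats(1.01, 3.0))
    def test_monotone_nonincreasing_in_precision(self, pd, factor):
        p, d = pd
        wider = min(d * factor, min(p, 1 - p) * 0.999)
        assert compute_base_n(p, wider) <= compute_base_n(p, d)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.06, 0.49), st.floats(0.001, 0.05))
    def test_monotone_in_prevalence_below_half(self, p, d):
        higher = min(p * 1.1, 0.5)
        assert compute_base_n(higher, d) >= compute_base_n(p, d)


class TestInflation:
    @pytest.mark.parametrize("n,deff,expected", [(897, 1.0, 897), (897, 2.0, 1794), (81, 1.5, 122)])
    def test_design_effect_ceiling(self, n, deff, expected):
        assert apply_design_effect(n, deff) == expected

    def test_design_effect_below_one_warns(self):
        with pytest.warns(PlanningWarning):
            assert apply_design_effect(100, 0.8) == 80

    @pytest.mark.parametrize("deff", [0.0, -1.0, float("nan")])
    def test_design_effect_domain(self, deff):
        with pytest.raises(ValueError):
            apply_design_effect(100, deff)

    def test_loss_inflation_matches_worked_example(self):
        with pytest.warns(PlanningWarning):
            assert apply_loss(897, 0.10) == 997

    @pytest.mark.parametrize("n", [1, 7, 897, 10**6])
    def test_zero_loss_is_identity(self, n):
        assert apply_loss(n, 0.0) == n

    def test_half_loss_doubles(self):
        with pytest.warns(PlanningWarning):
            assert apply_loss(100, 0.50) == 200

    def test_loss_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            apply_loss(100, 1.0)

    def test_high_loss_warns(self):
        with pytest.warns(PlanningWarning, match="10%"):
            apply_loss(100, 0.25)

    def test_rounding_order_is_ceil_then_divide_then_ceil(self):
        """Pin the pipeline order with the worked example.

        Inflating the unrounded base (896.4/0.9 = 995.97 -> 996) or
        multiplying by 1 + loss (897 * 1.1 -> 987) both disagree with the
        pipeline's 997, so the golden value rejects those orderings.
        """
        z = z_for_confidence(0.95)
        unrounded = z * z * 0.3 * 0.7 / 0.03**2
        assert math.ceil(unrounded / 0.9) == 996
        assert math.ceil(math.ceil(unrounded) * 1.1) == 987
        with pytest.warns(PlanningWarning):
            assert apply_loss(compute_base_n(0.30, 0.03), 0.10) == 997


class TestAnticipatedCI:
    @pytest.mark.parametrize("p,d,_n,ci,width", GOLDEN_TABLE)
    def test_published_ci_bounds(self, p, d, _n, ci, width):
        low, high = anticipated_ci(p, d)
        assert (low, high) == ci
        assert high - low == width

    def test_worked_example_interval(self):
        assert anticipated_ci(0.30, 0.03) == (27.0, 33.0)

    def test_interval_leaving_scale_rejected(self):
        with pytest.raises(InvalidPrecisionError):
            anticipated_ci(0.02, 0.05)


class TestPipeline:
    def test_worked_example_end_to_end(self):
        with pytest.warns(PlanningWarning):
            result = compute_sample_size(StudyParameters(0.30, 0.03, loss=0.10))
        assert result.n_base == 897
        assert result.n_adjusted == 997
        assert (result.ci_low, result.ci_high) == (27.0, 33.0)

    def test_no_loss_no_deff_passthrough(self):
        result = compute_sample_size(StudyParameters(0.25, 0.05))
        assert result.n_base == result.n_deff == result.n_adjusted == 289
        assert (result.ci_low, result.ci_high) == (20.0, 30.0)
        assert result.ci_width == 10.0

    def test_quarter_precision_at_half(self):
        # p(1-p)/d^2 = 4 at p = 0.5, d = 0.25: n = ceil(4 z^2) = 16
        result = compute_sample_size(StudyParameters(0.5, 0.25))
        assert result.n_base == 16

    def test_serialization_keys_and_values(self):
        with pytest.warns(PlanningWarning):
            result = compute_sample_size(
                StudyParameters(0.30, 0.03, loss=0.10, design_effect=1.5)
            )
        d = result.to_dict()
        assert d == {
            "expected_prevalence_pct": 30.0,
            "precision_pct": 3.0,
            "confidence_pct": 95.0,
            "loss_pct": 10.0,
            "design_effect": 1.5,
            "n_base": 897,
            "n_deff": 1346,
            "n_adjusted": 1496,
            "ci_low_pct": 27.0,
            "ci_high_pct": 33.0,
            "ci_width_pct": 6.0,
        }

    @settings(max_examples=150, deadline=None)
    @given(valid_pd, st.floats(0.0, 0.09), st.floats(1.0, 3.0))
    def test_inflation_ordering_invariant(self, pd, loss, deff):
        p, d = pd
        result = compute_sample_size(StudyParameters(p, d, loss=loss, design_effect=deff))
        assert 1 <= result.n_base <= result.n_deff <= result.n_adjusted
        assert result.ci_width == pytest.approx(2 * 100 * d, rel=1e-9)

    def test_nondefault_confidence_warns(self):
        with pytest.warns(PlanningWarning, match="0.9"):
            StudyParameters(0.3, 0.03, confidence=0.90)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidPrecisionError):
            StudyParameters(0.02, 0.05)
        with pytest.raises(ValueError):
            StudyParameters(0.3, 0.03, loss=1.0)
        with pytest.raises(ValueError):
            StudyParameters(0.3, 0.03, design_effect=0.0)
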