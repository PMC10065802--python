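"""Synthetic trace generation and boundary quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timernet import (
    DomainSpec,
    ExpressionTrace,
    boundary_positions,
    boundary_shift,
    normalize_trace,
    synthesize_trace,
    window_trace,
)
from timernet.traces import DEFAULT_WINDOW, TraceError


@pytest.fixture
def single_domain():
    return [DomainSpec("cad", 80.0, 95.0, amplitude=10.0, edge_sharpness=0.5,
                       baseline=1.0)]


class TestSynthesize:
    def test_plateau_above_baseline(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=301, noise_sd=0.0)
        y = trace.series("cad")
        mid = y[np.argmin(np.abs(trace.positions - 87.5))]
        outside = y[np.argmin(np.abs(trace.positions - 70.0))]
        assert mid > outside

    def test_plateau_height_matches_closed_form(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=301, noise_sd=0.0)
        assert np.max(trace.series("cad")) == pytest.approx(11.0, abs=0.01)

    def test_seeded_determinism(self, single_domain):
        a = synthesize_trace(single_domain, n_points=101, noise_sd=1.0, seed=7)
        b = synthesize_trace(single_domain, n_points=101, noise_sd=1.0, seed=7)
        assert np.array_equal(a.series("cad"), b.series("cad"))
        c = synthesize_trace(single_domain, n_points=101, noise_sd=1.0, seed=8)
        assert not np.array_equal(a.series("cad"), c.series("cad"))

    def test_intensities_floored_at_zero(self):
        dom = [DomainSpec("g", 40.0, 60.0, amplitude=1.0, baseline=0.0)]
        trace = synthesize_trace(dom, n_points=200, noise_sd=5.0, seed=0)
        assert (trace.series("g") >= 0).all()

    def test_multiple_domains_sum(self):
        doms = [
            DomainSpec("g", 20.0, 30.0, amplitude=5.0, edge_sharpness=0.5),
            DomainSpec("g", 70.0, 80.0, amplitude=5.0, edge_sharpness=0.5),
        ]
        trace = synthesize_trace(doms, n_points=501, noise_sd=0.0)
        y = trace.series("g")
        for center in (25.0, 75.0):
            assert y[np.argmin(np.abs(trace.positions - center))] > 4.5

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(anterior_edge=95.0, posterior_edge=80.0), "edge"),
            (dict(amplitude=0.0), "amplitude"),
            (dict(edge_sharpness=0.0), "sharpness"),
            (dict(baseline=-1.0), "baseline"),
        ],
    )
    def test_invalid_domain_names_field(self, kwargs, field):
        spec = dict(gene="g", anterior_edge=10.0, posterior_edge=20.0)
        spec.update(kwargs)
        with pytest.raises(TraceError, match=field):
            DomainSpec(**spec)

    def test_too_few_points_rejected(self, single_domain):
        with pytest.raises(TraceError, match="n_points"):
            synthesize_trace(single_domain, n_points=5)


class TestNormalize:
    def test_min_max_scaling(self):
        trace = ExpressionTrace(np.array([0.0, 1.0, 2.0]),
                                {"g": np.array([2.0, 4.0, 6.0])})
        out = normalize_trace(trace)
        assert out.series("g").tolist() == [0.0, 0.5, 1.0]
        assert out.normalized

    def test_constant_series_flagged_degenerate(self):
        trace = ExpressionTrace(np.array([0.0, 1.0, 2.0]),
                                {"g": np.array([3.0, 3.0, 3.0])})
        out = normalize_trace(trace)
        assert out.series("g").tolist() == [0.0, 0.0, 0.0]
        assert "g" in out.degenerate

    def test_idempotent(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=101, noise_sd=0.5, seed=3)
        once = normalize_trace(trace)
        twice = normalize_trace(once)
        assert np.allclose(once.series("cad"), twice.series("cad"))

    def test_window_then_normalize_spans_unit_interval(self, single_domain):
        windowed = normalize_trace(window_trace(
            synthesize_trace(single_domain, n_points=301, noise_sd=0.0)))
        y = windowed.series("cad")
        assert y.min() == 0.0 and y.max() == 1.0

    def test_order_non_commutative_when_extrema_outside_window(self):
        # a domain peaking anterior to the window: normalize-then-window
        # leaves the windowed series well below 1
        dom = [DomainSpec("g", 30.0, 50.0, amplitude=10.0, edge_sharpness=1.0,
                          baseline=1.0)]
        trace = synthesize_trace(dom, n_points=601, noise_sd=0.0)
        win_then_norm = normalize_trace(window_trace(trace))
        norm_then_win = window_trace(normalize_trace(trace))
        assert win_then_norm.series("g").max() == 1.0
        assert norm_then_win.series("g").max() < 0.5


class TestWindow:
    def test_default_window_bounds(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=301)
        windowed = window_trace(trace)
        assert DEFAULT_WINDOW == (67.5, 97.5)
        assert windowed.positions.min() >= 67.5
        assert windowed.positions.max() <= 97.5

    def test_full_range_window_is_identity(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=301)
        same = window_trace(trace, 0.0, 100.0)
        assert np.array_equal(same.positions, trace.positions)
        assert np.array_equal(same.series("cad"), trace.series("cad"))

    def test_inverted_window_rejected(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=301)
        with pytest.raises(TraceError):
            window_trace(trace, 97.5, 67.5)


class TestBoundaries:
    def test_half_max_crossings_sit_at_edge_parameters(self, single_domain):
        trace = normalize_trace(window_trace(
            synthesize_trace(single_domain, n_points=301, noise_sd=0.0)))
        crossings = boundary_positions(trace, "cad")
        assert len(crossings) == 2
        (rise, rdir), (fall, fdir) = crossings
        assert (rdir, fdir) == ("rising", "falling")
        assert rise < fall
        assert rise == pytest.approx(80.0, abs=0.1)
        assert fall == pytest.approx(95.0, abs=0.1)

    def test_flat_trace_has_no_crossings(self):
        trace = ExpressionTrace(np.linspace(0, 100, 50),
                                {"g": np.zeros(50)}, normalized=True)
        assert boundary_positions(trace, "g") == []

    def test_unnormalized_trace_rejected(self, single_domain):
        trace = synthesize_trace(single_domain, n_points=301)
        with pytest.raises(TraceError, match="normalized"):
            boundary_positions(trace, "cad")

    def test_unknown_gene_rejected(self, single_domain):
        trace = normalize_trace(synthesize_trace(single_domain, n_points=301))
        with pytest.raises(TraceError, match="opa"):
            boundary_positions(trace, "opa")

    def test_parameter_recovery_under_noise(self):
        """>=95% of 100 seeded runs recover both edges within 0.5% egg
        length at 5%-of-amplitude noise."""
        hits = 0
        for seed in range(100):
            trace = synthesize_trace(
                [DomainSpec("g", 80.0, 95.0, amplitude=10.0, edge_sharpness=1.0,
                            baseline=0.5)],
                n_points=301, noise_sd=0.5, seed=seed,
            )
            norm = normalize_trace(window_trace(trace))
            crossings = boundary_positions(norm, "g")
            rising = [p for p, d in crossings if d == "rising"]
            falling = [p for p, d in crossings if d == "falling"]
            if rising and falling and abs(rising[0] - 80.0) <= 0.5 \
                    and abs(falling[-1] - 95.0) <= 0.5:
                hits += 1
        assert hits >= 95


class TestBoundaryShift:
    def make(self, posterior_edge, seed=0, noise=0.0):
        return normalize_trace(window_trace(synthesize_trace(
            [DomainSpec("g", 80.0, posterior_edge, amplitude=10.0,
                        edge_sharpness=0.5, baseline=0.5)],
            n_points=301, noise_sd=noise, seed=seed,
        )))

    def test_identical_traces_shift_zero(self):
        trace = self.make(95.0)
        assert boundary_shift(trace, trace, "g", "falling") == pytest.approx(0.0)

    def test_anterior_shift_is_negative(self):
        ref, test = self.make(95.0), self.make(93.0)
        shift = boundary_shift(ref, test, "g", "falling")
        assert shift == pytest.approx(-2.0, abs=0.1)

    def test_missing_crossing_returns_none(self):
        ref = self.make(95.0)
        flat = ExpressionTrace(ref.positions, {"g": np.zeros_like(ref.positions)},
                               normalized=True)
        assert boundary_shift(flat, ref, "g", "falling") is None

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(edge_a=st.floats(85.0, 92.0), edge_b=st.floats(85.0, 92.0))
    def test_antisymmetry(self, edge_a, edge_b):
        a, b = self.make(edge_a), self.make(edge_b)
        ab = boundary_shift(a, b, "g", "falling")
        ba = boundary_shift(b, a, "g", "falling")
        assert ab == pytest.approx(-ba, abs=1e-9)
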