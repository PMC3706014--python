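"""Greedy window scan and streaming driver: behavior, scaling, equivalences."""

from __future__ import annotations

import math

import numpy as np
import pytest

from presee.geometry import DistanceWeights, TimePoint
from presee.segmenter import (
    SegmenterConfig,
    StreamOrderError,
    presee_stream,
    segment_file,
    segment_series,
    segment_window,
)
from presee.synthgen import GeneratorConfig, generate_arrays

from conftest import (
    exhaustive_optimum,
    greedy_total_cost,
    make_points,
    random_window,
)


def stream_positions(points, **cfg_kwargs) -> list[int]:
    cfg = SegmenterConfig(**cfg_kwargs)
    return [g for _, g in presee_stream(iter(points), cfg)]


class TestSegmentWindow:
    def test_two_points_are_kept(self):
        pts = make_points([(0, 0), (5, 3)])
        assert segment_window(pts).projections == [0, 1]

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            segment_window(make_points([(0, 0)]))

    def test_well_spaced_collinear_collapses_to_endpoints(self):
        pts = make_points([(0, 0), (10, 0), (20, 0), (30, 0)])
        assert segment_window(pts).projections == [0, 3]

    def test_large_sawtooth_keeps_every_point(self):
        # no merge satisfies the MDL criterion (13.6 > 7.6 bits per pair)
        pts = make_points([(0, 0), (10, 10), (20, 0), (30, 10)])
        assert segment_window(pts).projections == [0, 1, 2, 3]

    def test_greedy_cost_never_beats_exhaustive_optimum(self, weights):
        rng = np.random.default_rng(123)
        for _ in range(150):
            pts = random_window(rng)
            cs = segment_window(pts, weights)
            greedy = greedy_total_cost(pts, cs.projections, weights)
            optimum = exhaustive_optimum(pts, weights)
            assert greedy >= optimum - 1e-9

    def test_greedy_matches_optimum_on_collinear_input(self, weights):
        pts = make_points([(i * 10, i * 10) for i in range(8)])
        cs = segment_window(pts, weights)
        assert cs.projections == [0, 7]
        greedy = greedy_total_cost(pts, cs.projections, weights)
        assert greedy == pytest.approx(exhaustive_optimum(pts, weights))

    def test_greedy_matches_optimum_on_single_breakpoint(self, weights):
        pts = make_points(
            [(i * 10, i * 100) for i in range(5)]
            + [(40 + i * 10, 400 - i * 100) for i in range(1, 5)]
        )
        cs = segment_window(pts, weights)
        assert cs.projections == [0, 4, 8]
        greedy = greedy_total_cost(pts, cs.projections, weights)
        assert greedy == pytest.approx(exhaustive_optimum(pts, weights))


class TestStreamingDriver:
    def test_matches_window_result_when_input_fits(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            pts = random_window(rng)
            want = segment_window(pts).projections
            got = stream_positions(pts, window_size=max(3, len(pts)))
            assert got == want

    def test_well_spaced_collinear_long_stream_window_joins(self):
        # collinear with spacing 10: every window collapses to its ends and
        # the window is re-anchored at its last point
        n, w = 101, 11
        pts = make_points([(10 * i, 0) for i in range(n)])
        got = stream_positions(pts, window_size=w)
        expected_count = math.ceil((n - 1) / (w - 1)) + 1
        assert len(got) == expected_count
        assert got[0] == 0 and got[-1] == n - 1

    def test_unit_constant_stream_passes_through(self):
        # zero-length code for unit lines: nothing can merge, the stream is
        # deemed incompressible and forwarded unchanged
        pts = make_points([(i, 5) for i in range(25)])
        assert stream_positions(pts, window_size=10) == list(range(25))

    def test_large_alternation_passes_through(self):
        pts = make_points([(i, 500 if i % 2 else -500) for i in range(25)])
        assert stream_positions(pts, window_size=10) == list(range(25))

    def test_empty_source_yields_nothing(self):
        assert stream_positions([]) == []

    def test_single_point_source(self):
        assert stream_positions(make_points([(3, 1)])) == [0]

    def test_order_violation_raises(self):
        pts = make_points([(0, 0), (2, 1), (1, 2)])
        with pytest.raises(StreamOrderError):
            stream_positions(pts)

    def test_each_point_read_exactly_once(self):
        x, y = generate_arrays(GeneratorConfig(size=3000, seed=2))
        reads = 0

        def counting():
            nonlocal reads
            for a, b in zip(x, y):
                reads += 1
                yield TimePoint(int(a), float(b))

        stats: dict = {}
        out = list(presee_stream(counting(), SegmenterConfig(window_size=100),
                                 stats=stats))
        assert reads == 3000
        assert stats["points_read"] == 3000
        assert stats["points_emitted"] == len(out)
        assert stats["buffer_high_water"] <= 100

    def test_operation_count_scales_linearly(self):
        # per-point cost varies with the local walk regime, so the ratio is
        # taken over multi-seed means
        def ops_for(n: int, seed: int) -> int:
            x, y = generate_arrays(GeneratorConfig(size=n, seed=seed))
            src = (TimePoint(int(a), float(b)) for a, b in zip(x, y))
            stats: dict = {}
            list(presee_stream(src, SegmenterConfig(window_size=200), stats=stats))
            return stats["kernel_ops"]

        seeds = range(5)
        ratio = (sum(ops_for(4000, s) for s in seeds)
                 / sum(ops_for(2000, s) for s in seeds))
        assert 1.8 <= ratio <= 2.6

    def test_projections_monotone_endpoints_kept(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(2, 400))
            x = np.arange(n, dtype=float)
            y = rng.normal(0, rng.choice([0.5, 5, 50]), n).cumsum()
            pts = make_points(zip(x, y))
            got = stream_positions(pts, window_size=20)
            assert got[0] == 0 and got[-1] == n - 1
            assert all(b > a for a, b in zip(got, got[1:]))

    def test_batch_size_irrelevant_when_input_fits_one_window(self):
        x, y = generate_arrays(GeneratorConfig(size=500, seed=3))
        pts = make_points(zip(x, y))
        results = {
            b: stream_positions(pts, window_size=600, batch_size=b)
            for b in (1, 2, 5, 50)
        }
        assert len({tuple(v) for v in results.values()}) == 1

    def test_window_sizes_agree_on_most_character_points(self):
        x, y = generate_arrays(GeneratorConfig(size=10_000, seed=0))
        a = set(segment_series((x, y), SegmenterConfig(window_size=100)).projections)
        b = set(segment_series((x, y), SegmenterConfig(window_size=1000)).projections)
        agreement = len(a & b) / max(len(a), len(b))
        assert agreement >= 0.9

    def test_array_driver_equals_streaming_driver(self):
        for seed in range(3):
            x, y = generate_arrays(GeneratorConfig(size=4000, seed=seed))
            for ws, bs in [(100, 1), (1000, 1), (250, 5)]:
                cfg = SegmenterConfig(window_size=ws, batch_size=bs)
                fast = segment_series((x, y), cfg).projections
                src = (TimePoint(int(a), float(b)) for a, b in zip(x, y))
                slow = [g for _, g in presee_stream(src, cfg)]
                assert fast == slow


class TestSegmentFile:
    def test_collinear_csv_collapses(self, tmp_path):
        src = tmp_path / "in.csv"
        src.write_text("0,0\n10,0\n20,0\n")
        out = tmp_path / "out.csv"
        summary = segment_file(src, out)
        assert (summary.n_in, summary.n_out) == (3, 2)
        assert out.read_text() == "0,0\n20,0\n"

    def test_empty_file(self, tmp_path):
        src = tmp_path / "in.csv"
        src.write_text("")
        out = tmp_path / "out.csv"
        summary = segment_file(src, out)
        assert summary.n_in == 0 and summary.n_out == 0
        assert summary.compress_rate == 0.0
        assert out.read_text() == ""

    def test_single_window_file_matches_segment_window(self, tmp_path):
        rng = np.random.default_rng(9)
        pts = random_window(rng)
        src = tmp_path / "in.csv"
        src.write_text("".join(f"{p.index:g},{p.value!r}\n" for p in pts))
        out = tmp_path / "out.csv"
        summary = segment_file(src, out)
        assert summary.n_out == len(segment_window(pts))


class TestConfigValidation:
    def test_bad_window(self):
        with pytest.raises(ValueError):
            SegmenterConfig(window_size=2)

    def test_bad_batch(self):
        with pytest.raises(ValueError):
            SegmenterConfig(batch_size=0)
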