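"""Streaming ≡ batch, emission timing, and the buffer/latency model."""

import numpy as np
import pytest

from streamspot import pipeline as pl
from streamspot import streaming as st
from streamspot import synthgen as sg

from conftest import records_key


def random_scene(rng):
    """A small random scene: either raw noise-like values or spot-bearing."""
    H = int(rng.integers(4, 20))
    W = int(rng.integers(8, 24))
    if rng.random() < 0.5:
        img = rng.integers(0, 256, size=(H, W))
    else:
        spec = sg.SceneSpec(
            W=W, H=H,
            spots=tuple(sg.PSFSpot.from_peak(
                float(rng.uniform(50, 220)),
                float(rng.uniform(1, H - 1)), float(rng.uniform(1, W - 1)),
                float(rng.uniform(0.5, 1.2)))
                for _ in range(rng.integers(0, 3))),
            background=sg.FlatBackground(float(rng.uniform(0, 60))),
            noise=sg.NoiseSpec(read_noise_sigma=float(rng.uniform(0, 4))),
            seed=int(rng.integers(0, 2**31)))
        img, _ = sg.render_scene(spec)
    return img


def random_params(rng):
    threshold = (pl.absolute_threshold(float(rng.integers(2, 30)))
                 if rng.random() < 0.7 else
                 pl.adaptive_threshold(float(rng.uniform(2, 6))))
    return pl.PipelineParams(
        L_bg=int(rng.integers(3, 16)), threshold=threshold,
        recovery=bool(rng.random() < 0.8))


class TestStreamEqualsBatch:
    def test_fuzz_corpus_1000_scenes(self, rng):
        """The central contract: row-by-row processing emits exactly the
        records of whole-image processing, for 1000 random scenes and
        random pipeline parameters."""
        for _ in range(1000):
            img = random_scene(rng)
            params = random_params(rng)
            batch = pl.detect(img, params)
            stream = st.detect_streaming(img, params)
            assert records_key(batch) == records_key(stream)

    def test_spot_scene_detailed_equality(self):
        spec = sg.SceneSpec(
            W=64, H=48,
            spots=(sg.PSFSpot.from_peak(180, 10.3, 20.6, 0.8),
                   sg.PSFSpot.from_peak(120, 30.8, 50.2, 1.0)),
            background=sg.FlatBackground(20),
            noise=sg.NoiseSpec(read_noise_sigma=2.0), seed=9)
        img, _ = sg.render_scene(spec)
        params = pl.PipelineParams(L_bg=15,
                                   threshold=pl.absolute_threshold(8))
        assert records_key(pl.detect(img, params)) == \
            records_key(st.detect_streaming(img, params))


class TestStreamingBehaviour:
    def test_target_emitted_before_two_rows_later(self):
        """An isolated spot whose last pixels are in row r is emitted
        while row r+1 is being consumed."""
        spec = sg.SceneSpec(W=32, H=32,
                            spots=(sg.PSFSpot.from_peak(200, 10.0, 16.0, 0.7),),
                            background=sg.FlatBackground(20), seed=0)
        img, _ = sg.render_scene(spec)
        params = pl.PipelineParams(L_bg=15, threshold=pl.absolute_threshold(10))
        det = st.StreamingDetector(32, params)
        emitted_at = None
        for r in range(32):
            if det.process_row(img[r], r) and emitted_at is None:
                emitted_at = r
        det.flush()
        (rec,) = det.records
        last_row = rec.row_span[1]
        assert emitted_at == last_row + 1

    def test_out_of_order_and_bad_width_rejected(self):
        det = st.StreamingDetector(16)
        det.process_row(np.zeros(16), 0)
        with pytest.raises(ValueError):
            det.process_row(np.zeros(16), 2)
        with pytest.raises(ValueError):
            det.process_row(np.zeros(8))

    def test_empty_rows_no_state_growth(self):
        det = st.StreamingDetector(64)
        for r in range(500):
            assert det.process_row(np.zeros(64), r) == []
        assert det.flush() == []
        assert det.records == []

    def test_timestamps_attached_when_scheduled(self):
        from streamspot.ers import ExposureSchedule, row_timestamp

        spec = sg.SceneSpec(W=32, H=32,
                            spots=(sg.PSFSpot.from_peak(200, 10.0, 16.0, 0.7),),
                            background=sg.FlatBackground(20), seed=0)
        img, _ = sg.render_scene(spec)
        sched = ExposureSchedule(dt=1e-3, T_exp=5e-3)
        params = pl.PipelineParams(L_bg=15, threshold=pl.absolute_threshold(10))
        (rec,) = st.detect_streaming(img, params, sched)
        assert rec.timestamp_s == row_timestamp(sched, rec.row_span[1])


class TestMemoryModel:
    def test_budget_under_0p1_percent_of_megapixel_frame(self):
        rep = st.memory_report()
        assert rep.percent_of_image <= 0.1
        assert rep.fits_in_one_row
        assert rep.pixel_equivalents < 1024

    def test_budget_identity(self):
        rep = st.memory_report()
        assert rep.total_bits == sum(dict(rep.entries).values())

    def test_height_independence(self):
        a = st.memory_report(W=1024, H=1024)
        b = st.memory_report(W=1024, H=4096)
        assert a.total_bits == b.total_bits
        assert b.percent_of_image == pytest.approx(a.percent_of_image / 4)

    def test_line_fifo_scales_with_L(self):
        small = st.memory_report(pl.PipelineParams(L_bg=9))
        large = st.memory_report(pl.PipelineParams(L_bg=31))
        diff = dict(large.entries)
        base = dict(small.entries)
        # only the line FIFOs and the sync delay depend on L
        for k in base:
            if k in ("line_erode_fifo", "line_dilate_fifo", "sync_delay_line"):
                assert diff[k] > base[k]
            else:
                assert diff[k] == base[k]
        assert large.total_bits - small.total_bits == \
            (31 - 9) * 2 * 8 + (2 * 15 - 2 * 4) * 8


class TestLatencyModel:
    def test_stage_table_and_total(self):
        lat = st.latency_report()
        delays = dict(lat.stage_delays)
        L = pl.PipelineParams().L_bg
        assert delays["line_erode"] == L // 2 + 1
        assert delays["line_dilate"] == L // 2 + 1
        assert lat.pipeline_delay_px == sum(delays.values())

    def test_latency_within_printed_band_at_25mhz(self):
        lat = st.latency_report(f_clk=25e6)
        assert 2e-6 <= lat.latency_s <= 3e-6

    def test_latency_scales_with_clock(self):
        slow = st.latency_report(f_clk=25e6)
        fast = st.latency_report(f_clk=2.5e9)
        assert fast.latency_s == pytest.approx(slow.latency_s / 100)

    def test_improvement_factor_and_time_advance(self):
        model = st.ReadoutModel()
        lat = st.latency_report()
        factor, dT_last = st.improvement_factor(model, lat,
                                                target_row=model.H - 1)
        assert factor >= 5000 * (1 - 1e-9)
        assert dT_last == pytest.approx(model.T_proc_traditional)
        _, dT_first = st.improvement_factor(model, lat, target_row=0)
        assert dT_first == pytest.approx(model.T_read
                                         + model.T_proc_traditional)
        _, dT_mid = st.improvement_factor(model, lat, target_row=model.H // 2)
        assert dT_last < dT_mid < dT_first

    def test_readout_time_megapixel(self):
        model = st.ReadoutModel(W=1024, H=1024, f_clk=25e6)
        assert model.T_read == pytest.approx(0.042, rel=0.02)
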