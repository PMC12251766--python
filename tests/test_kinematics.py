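"""Direction, velocity, length, height, silhouette and timestamp checks."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishcurtain import (
    FishSpec,
    SensorConfig,
    VelocityEstimate,
    analyze_candidate,
    assign_timestamp,
    estimate_directions,
    estimate_height,
    estimate_length,
    estimate_velocities,
    reconstruct_silhouette,
    segment_events,
    simulate_passage,
)
from conftest import START, make_stream


def event_from_masks(config, mask_a, mask_b):
    stream = make_stream(config, interrupted_a=mask_a, interrupted_b=mask_b)
    events = segment_events(stream, min_active_frames=1, gap_frames=10_000)
    assert len(events) == 1
    return stream, events[0]


def block_masks(config, n_frames, a_span, b_span, beams=(2, 5)):
    """Rectangular occupancy on given frame spans (inclusive) per array."""
    mask_a = np.zeros((n_frames, config.n_beams), dtype=bool)
    mask_b = np.zeros_like(mask_a)
    if a_span:
        mask_a[a_span[0] : a_span[1] + 1, beams[0] : beams[1]] = True
    if b_span:
        mask_b[b_span[0] : b_span[1] + 1, beams[0] : beams[1]] = True
    return mask_a, mask_b


class TestDirections:
    def test_a_first_is_positive_entry(self, mini_config):
        ma, mb = block_masks(mini_config, 60, (10, 30), (16, 36))
        _, event = event_from_masks(mini_config, ma, mb)
        d = estimate_directions(event)
        assert (d.entry, d.exit) == (1, 1)

    def test_same_frame_tie_is_zero(self, mini_config):
        ma, mb = block_masks(mini_config, 60, (10, 30), (10, 30))
        _, event = event_from_masks(mini_config, ma, mb)
        d = estimate_directions(event)
        assert (d.entry, d.exit) == (0, 0)

    def test_untouched_array_gives_zero(self, mini_config):
        ma, mb = block_masks(mini_config, 60, (10, 30), None)
        _, event = event_from_masks(mini_config, ma, mb)
        assert estimate_directions(event) == estimate_directions(event)
        assert estimate_directions(event).entry == 0
        assert estimate_directions(event).exit == 0

    def test_simulated_reverse_travel(self, full_config):
        fish = FishSpec(length=14.0, height=6.0, depth_center=30.0, speed=25.0,
                        direction=-1, entry_time=1.0)
        stream, _ = simulate_passage(fish, full_config, 4.0)
        event = segment_events(stream)[0]
        d = estimate_directions(event)
        assert (d.entry, d.exit) == (-1, -1)


class TestVelocities:
    def test_six_frame_delay_at_50hz(self, full_config):
        ma, mb = block_masks(full_config, 80, (10, 40), (16, 46))
        _, event = event_from_masks(full_config, ma, mb)
        v = estimate_velocities(event)
        assert v.entry == pytest.approx(50.0)  # 6 cm / (6/50 s)
        assert v.exit == pytest.approx(50.0)
        assert v.mean == pytest.approx(50.0)

    def test_zero_delay_undefined(self, full_config):
        ma, mb = block_masks(full_config, 80, (10, 40), (10, 46))
        _, event = event_from_masks(full_config, ma, mb)
        v = estimate_velocities(event)
        assert v.entry is None
        assert v.exit is not None
        assert v.mean == v.exit

    def test_both_undefined_mean_none(self, full_config):
        ma, mb = block_masks(full_config, 80, (10, 40), (10, 40))
        _, event = event_from_masks(full_config, ma, mb)
        assert estimate_velocities(event).mean is None

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        speed=st.floats(min_value=5.0, max_value=100.0),
        phase=st.floats(min_value=0.0, max_value=0.02),
    )
    def test_recovery_within_quantization(self, speed, phase):
        """Estimated speed lies within one frame-quantization step."""
        cfg = SensorConfig()
        fish = FishSpec(length=20.0, height=6.0, depth_center=30.0, speed=speed,
                        shape="rectangle", entry_time=1.0 + phase)
        stream, _ = simulate_passage(fish, cfg, 2.5 + 30.0 / speed)
        event = segment_events(stream)[0]
        v = estimate_velocities(event).mean
        assert v is not None
        d_true = cfg.array_gap / speed * cfg.sampling_rate  # frames
        v_lo = cfg.array_gap * cfg.sampling_rate / (np.floor(d_true) + 1)
        v_hi = cfg.array_gap * cfg.sampling_rate / max(np.floor(d_true) - 1, 1)
        assert v_lo - 1e-9 <= v <= v_hi + 1e-9


class TestLength:
    def test_length_from_span_and_velocity(self, full_config):
        # array A active frames 100-127 -> span 27 frames = 0.54 s
        ma, mb = block_masks(full_config, 200, (100, 127), (110, 137))
        _, event = event_from_masks(full_config, ma, mb)
        la, lb, mean = estimate_length(event, VelocityEstimate(30.0, 30.0))
        assert la == pytest.approx(16.2)
        assert lb == pytest.approx(16.2)
        assert mean == pytest.approx(16.2)

    def test_single_frame_span_zero_length(self, full_config):
        ma, mb = block_masks(full_config, 50, (10, 10), (14, 15))
        _, event = event_from_masks(full_config, ma, mb)
        la, _, _ = estimate_length(event, VelocityEstimate(30.0, None))
        assert la == 0.0

    def test_undefined_velocity_propagates(self, full_config):
        ma, mb = block_masks(full_config, 50, (10, 20), (10, 20))
        _, event = event_from_masks(full_config, ma, mb)
        assert estimate_length(event, VelocityEstimate(None, None)) == (None, None, None)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(phase=st.floats(min_value=0.0, max_value=0.02))
    def test_rigid_fish_recovery(self, phase):
        """Noise-free 16.5 cm rigid fish: error within the combined
        frame-quantization bound."""
        cfg = SensorConfig()
        speed, true_len = 30.0, 16.5
        fish = FishSpec(length=true_len, height=6.4, depth_center=30.0,
                        speed=speed, shape="rectangle", entry_time=1.0 + phase)
        stream, _ = simulate_passage(fish, cfg, 4.0)
        event = segment_events(stream)[0]
        v = estimate_velocities(event)
        _, _, length = estimate_length(event, v)
        dx = speed / cfg.sampling_rate
        d_true = cfg.array_gap / speed * cfg.sampling_rate
        v_err = cfg.array_gap * cfg.sampling_rate / max(np.floor(d_true) - 1, 1) - speed
        t_span = true_len / speed
        assert abs(length - true_len) <= 2 * dx + v_err * t_span + 1e-9


class TestHeight:
    def test_single_beam_reads_half_pitch(self, full_config):
        ma, mb = block_masks(full_config, 50, (10, 30), (14, 34), beams=(7, 8))
        _, event = event_from_masks(full_config, ma, mb)
        assert estimate_height(event) == pytest.approx(0.75)

    def test_four_beam_band(self, full_config):
        ma, mb = block_masks(full_config, 50, (10, 30), (14, 34), beams=(10, 14))
        _, event = event_from_masks(full_config, ma, mb)
        assert estimate_height(event) == pytest.approx(5.25)  # 4.5 + 0.75

    def test_union_of_both_arrays(self, full_config):
        ma, _ = block_masks(full_config, 50, (10, 30), None, beams=(5, 7))
        _, mb = block_masks(full_config, 50, None, (14, 34), beams=(8, 10))
        _, event = event_from_masks(full_config, ma, mb)
        # beams 5..9 -> span 4 * 1.5 + 0.75
        assert estimate_height(event) == pytest.approx(6.75)

    def test_offset_sweep_bounds_for_tall_fish(self, full_config):
        """6.4 cm body at every vertical offset reads 5.25-6.75 cm."""
        estimates = set()
        for offset in np.arange(20.0, 21.5, 0.05):
            fish = FishSpec(length=16.5, height=6.4, depth_center=offset,
                            speed=30.0, entry_time=1.0)
            stream, _ = simulate_passage(fish, full_config, 3.0)
            event = segment_events(stream)[0]
            estimates.add(round(estimate_height(event), 6))
        assert min(estimates) >= 5.25
        assert max(estimates) <= 6.75

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        height=st.floats(min_value=2.0, max_value=12.0),
        offset=st.floats(min_value=15.0, max_value=16.5),
    )
    def test_quantization_bounds_any_height(self, height, offset):
        """Estimate within [(floor(h/s)-1)*s + c, h + c] for all offsets."""
        cfg = SensorConfig()
        fish = FishSpec(length=18.0, height=height, depth_center=offset,
                        speed=30.0, shape="rectangle", entry_time=1.0)
        stream, _ = simulate_passage(fish, cfg, 3.0)
        event = segment_events(stream)[0]
        h_hat = estimate_height(event)
        s, c = cfg.beam_spacing, cfg.height_correction
        lo = (np.floor(height / s + 1e-9) - 1) * s + c
        assert lo - 1e-9 <= h_hat <= height + c + 1e-9


class TestSilhouette:
    def test_dx_is_speed_over_rate(self, full_config):
        ma, mb = block_masks(full_config, 80, (10, 40), (16, 46))
        _, event = event_from_masks(full_config, ma, mb)
        sil = reconstruct_silhouette(event, VelocityEstimate(50.0, 50.0))
        assert sil.dx == pytest.approx(1.0)
        assert sil.extent[0] == pytest.approx(30.0)  # 31 columns

    def test_ellipse_profile_is_unimodal(self, full_config):
        fish = FishSpec(length=16.5, height=6.4, depth_center=30.0, speed=30.0,
                        entry_time=1.0)
        stream, _ = simulate_passage(fish, full_config, 4.0)
        event = segment_events(stream)[0]
        v = estimate_velocities(event)
        sil = reconstruct_silhouette(event, v)
        profile = sil.occupancy.sum(axis=1).astype(int)
        peak = int(np.argmax(profile))
        assert (np.diff(profile[: peak + 1]) >= 0).all()
        assert (np.diff(profile[peak:]) <= 0).all()

    def test_single_frame_event(self, full_config):
        ma, mb = block_masks(full_config, 20, (5, 5), None)
        _, event = event_from_masks(full_config, ma, mb)
        sil = reconstruct_silhouette(event, VelocityEstimate(30.0, None))
        assert sil.occupancy.shape[0] == 1
        assert sil.extent[0] == pytest.approx(0.0)

    def test_reverse_direction_draws_nose_first(self, full_config):
        fish = FishSpec(length=16.5, height=6.4, depth_center=30.0, speed=30.0,
                        direction=-1, entry_time=1.0)
        stream, _ = simulate_passage(fish, full_config, 4.0)
        event = segment_events(stream)[0]
        v = estimate_velocities(event)
        forward = reconstruct_silhouette(event, v, direction=1)
        backward = reconstruct_silhouette(event, v, direction=-1)
        assert np.array_equal(backward.occupancy, forward.occupancy[::-1])

    def test_undefined_velocity_no_silhouette(self, full_config):
        ma, mb = block_masks(full_config, 50, (10, 20), (10, 20))
        _, event = event_from_masks(full_config, ma, mb)
        assert reconstruct_silhouette(event, VelocityEstimate(None, None)) is None


class TestTimestamp:
    def test_offset_from_stream_start(self, full_config):
        ma, mb = block_masks(full_config, 200, (150, 160), (152, 162))
        stream, event = event_from_masks(full_config, ma, mb)
        ts = assign_timestamp(event, stream)
        assert ts == START + dt.timedelta(seconds=3.0)

    def test_frame_zero_is_start_time(self, full_config):
        ma, mb = block_masks(full_config, 50, (0, 10), (2, 12))
        stream, event = event_from_masks(full_config, ma, mb)
        assert assign_timestamp(event, stream) == START


class TestMirrorSymmetry:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        speed=st.floats(min_value=10.0, max_value=60.0),
        direction=st.sampled_from([-1, 1]),
        phase=st.floats(min_value=0.0, max_value=0.02),
    )
    def test_time_reversal_flips_direction_keeps_size(self, speed, direction, phase):
        cfg = SensorConfig()
        fish = FishSpec(length=15.0, height=6.0, depth_center=28.0, speed=speed,
                        direction=direction, entry_time=1.0 + phase)
        stream, _ = simulate_passage(fish, cfg, 2.5 + 25.0 / speed)
        reversed_stream = stream.reversed()
        ev = segment_events(stream)[0]
        ev_r = segment_events(reversed_stream)[0]
        est = analyze_candidate(ev, stream=stream)
        est_r = analyze_candidate(ev_r, stream=reversed_stream)
        assert est_r.direction.entry == -est.direction.exit
        assert est_r.direction.exit == -est.direction.entry
        assert est_r.morphometrics.height == pytest.approx(est.morphometrics.height)
        assert est_r.morphometrics.length == pytest.approx(est.morphometrics.length)
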