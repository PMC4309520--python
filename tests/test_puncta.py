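"""Detection, linking, fate classification and the three-criterion event caller."""

import numpy as np
import pandas as pd
import pytest

from chemotirf import puncta, synthgen
from chemotirf.core import TimelapseStack
from chemotirf.puncta import EventCriteria
from chemotirf.synthgen import GeneratorConfig


def _frame_with_puncta(positions, amp=100.0, bg=100.0, noise=10.0,
                       shape=(128, 128), sigma=1.5, seed=0):
    img = np.full(shape, bg)
    for (x, y) in positions:
        synthgen._add_gaussian(img, x, y, amp, sigma)
    img += np.random.default_rng(seed).normal(0, noise, shape)
    return img


class TestDetection:
    def test_blank_noise_frames_yield_almost_no_detections(self):
        n_det = 0
        for seed in range(5):
            img = _frame_with_puncta([], shape=(256, 256), seed=seed)
            n_det += len(puncta.detect_puncta(img, threshold_sigma=5.0))
        assert n_det <= 2      # false-positive rate well under 1 per frame

    def test_single_punctum_localised_within_half_pixel(self):
        img = _frame_with_puncta([(63.3, 40.7)], amp=100.0, seed=1)
        det = puncta.detect_puncta(img)
        assert len(det) == 1
        assert abs(det[0].x_px - 63.3) < 0.5
        assert abs(det[0].y_px - 40.7) < 0.5
        assert det[0].intensity > det[0].background

    def test_two_separated_puncta_both_found(self):
        img = _frame_with_puncta([(50, 50), (60, 50)], seed=2)
        assert len(puncta.detect_puncta(img)) == 2

    def test_saturated_frame_warns_but_proceeds(self):
        img = np.full((64, 64), 4095.0)
        img[30, 30] = 4095.0
        with pytest.warns(UserWarning):
            puncta.detect_puncta(img, saturation=4095.0)

    def test_planted_field_recall_and_precision(self):
        # rendering then detecting must recover >=95% of planted puncta at
        # SNR >= 5 with <= 5% spurious detections
        n_truth = n_matched = n_det = 0
        for seed in (31, 32):
            gc = GeneratorConfig(field_px=512, n_frames=1, n_puncta=60,
                                 snr=5.0, second_channel=False, seed=seed)
            stack, gt = synthgen.make_tirf_timelapse(gc)
            det = puncta.detect_puncta(stack.frame(0, 0))
            truth = gt.initial_positions()
            n_truth += len(truth)
            n_det += len(det)
            for p in det:
                if np.min(np.hypot(truth[:, 0] - p.x_px,
                                   truth[:, 1] - p.y_px)) <= 1.5:
                    n_matched += 1
        assert n_matched / n_truth >= 0.95
        assert (n_det - n_matched) / n_det <= 0.05


class TestLinking:
    def test_stationary_punctum_one_full_track(self):
        rows = [{"frame": t, "x_px": 20.0, "y_px": 30.0,
                 "intensity": 200.0, "background": 100.0} for t in range(20)]
        tracks = puncta.link_puncta(pd.DataFrame(rows))
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_one_frame_dropout_bridged_by_gap_closing(self):
        rows = [{"frame": t, "x_px": 20.0, "y_px": 30.0,
                 "intensity": 200.0, "background": 100.0}
                for t in range(10) if t != 5]
        tracks = puncta.link_puncta(pd.DataFrame(rows), max_gap=2)
        assert len(tracks) == 1
        assert tracks[0].last_frame == 9

    def test_gap_beyond_limit_splits_track(self):
        rows = [{"frame": t, "x_px": 20.0, "y_px": 30.0,
                 "intensity": 200.0, "background": 100.0}
                for t in list(range(5)) + list(range(9, 14))]
        tracks = puncta.link_puncta(pd.DataFrame(rows), max_gap=2)
        assert len(tracks) == 2

    def test_crossing_paths_do_not_swap(self):
        # two puncta whose x-paths cross while staying > max_step apart in y
        rows = []
        for t in range(21):
            rows.append({"frame": t, "x_px": 10.0 + 2 * t, "y_px": 20.0,
                         "intensity": 200.0, "background": 100.0})
            rows.append({"frame": t, "x_px": 50.0 - 2 * t, "y_px": 26.0,
                         "intensity": 200.0, "background": 100.0})
        tracks = puncta.link_puncta(pd.DataFrame(rows), max_step_px=3.0)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.all(tr.y_px == tr.y_px[0])


class TestFateClassification:
    def test_confusion_matrix_accuracy(self, mixed_fate_scene):
        _, gt, _, tracks = mixed_fate_scene
        per_class = {"static": [0, 0], "lateral": [0, 0], "disappearing": [0, 0]}
        for p in gt.puncta:
            if p.reappear_frame is not None or p.fade_frames > 2:
                continue  # designed negatives assessed in the event tests
            cands = [tr for tr in tracks
                     if np.hypot(tr.x_px[0] - p.x_px[0],
                                 tr.y_px[0] - p.y_px[0]) <= 2
                     and tr.frames[0] <= 2]
            if not cands:
                continue
            tr = max(cands, key=len)
            per_class[p.fate][1] += 1
            if tr.fate == p.fate:
                per_class[p.fate][0] += 1
        for fate, (ok, tot) in per_class.items():
            assert tot > 0, fate
            assert ok / tot >= 0.9, (fate, ok, tot)

    def test_planted_lateral_track_is_lateral(self):
        gc = GeneratorConfig(field_px=256, n_frames=20, n_puncta=3,
                             cell_halfaxes_um=(10.0, 6.0),
                             fate_fractions={"lateral": 1.0}, seed=3)
        stack, gt = synthgen.make_tirf_timelapse(gc)
        dets = puncta.detect_stack(stack)
        tracks = puncta.link_puncta(dets, n_frames=stack.n_frames)
        puncta.classify_all(tracks, stack)
        long_tracks = [tr for tr in tracks if len(tr) >= 10]
        assert long_tracks and all(tr.fate == "lateral" for tr in long_tracks)


def _single_punctum_scene(**overrides):
    params = dict(field_px=256, n_frames=40, n_puncta=0,
                  cell_halfaxes_um=(10.0, 6.0), second_channel=False, seed=17)
    params.update(overrides)
    gc = GeneratorConfig(**params)
    stack, gt = synthgen.make_tirf_timelapse(gc)
    dets = puncta.detect_stack(stack)
    tracks = puncta.link_puncta(dets, n_frames=stack.n_frames)
    puncta.classify_all(tracks, stack)
    return stack, gt, dets, tracks


class TestEventCalling:
    def test_clean_step_disappearance_accepted_with_all_flags(self):
        stack, gt, dets, tracks = _single_punctum_scene(
            n_puncta=4, fate_fractions={"disappearing": 1.0})
        events = [puncta.evaluate_disappearance(tr, stack, dets,
                                                cell_mask=gt.cell_mask)
                  for tr in tracks if tr.fate == "disappearing"]
        events = [e for e in events if e is not None]
        assert len(events) == 4
        for ev in events:
            assert ev.rapid and ev.no_reappearance and ev.not_photobleaching
            assert ev.accepted

    def test_reappearance_vetoes_event(self):
        stack, gt, dets, tracks = _single_punctum_scene(n_reappearing=4)
        cands = [tr for tr in tracks if tr.fate == "disappearing"]
        assert cands
        for tr in cands:
            ev = puncta.evaluate_disappearance(tr, stack, dets,
                                               cell_mask=gt.cell_mask)
            if ev is not None:
                assert not ev.no_reappearance
                assert not ev.accepted
            assert puncta.call_disappearance(tr, stack, dets,
                                             cell_mask=gt.cell_mask) is None

    def test_gradual_fade_fails_rapid_criterion(self):
        stack, gt, dets, tracks = _single_punctum_scene(n_gradual=4)
        cands = [tr for tr in tracks if tr.fate == "disappearing"]
        assert cands
        for tr in cands:
            ev = puncta.evaluate_disappearance(tr, stack, dets,
                                               cell_mask=gt.cell_mask)
            if ev is not None:
                assert not ev.rapid
                assert not ev.accepted

    def test_global_bleaching_fadeouts_vetoed(self):
        stack, gt, dets, tracks = _single_punctum_scene(
            n_puncta=5, fate_fractions={"static": 1.0}, bleach_rate=0.08)
        # bleached spots sink below the detection threshold mid-stack; any
        # such candidate, whatever its fate label, must fail the bleach check
        ended = [tr for tr in tracks
                 if tr.last_frame < stack.n_frames - 10 and len(tr) >= 3]
        assert ended, "bleaching should extinguish tracks mid-stack"
        for tr in ended:
            ev = puncta.evaluate_disappearance(tr, stack, dets,
                                               cell_mask=gt.cell_mask)
            if ev is not None:
                assert not ev.not_photobleaching
                assert not ev.accepted

    def test_track_ending_near_stack_end_is_censored(self):
        rows = [{"frame": t, "x_px": 20.0, "y_px": 30.0,
                 "intensity": 200.0, "background": 100.0} for t in range(35)]
        dets = pd.DataFrame(rows)
        tracks = puncta.link_puncta(dets, n_frames=40)
        stack = TimelapseStack(
            np.random.default_rng(0).normal(100, 10, (40, 64, 64)), 0.1, 2.0)
        assert puncta.evaluate_disappearance(tracks[0], stack, dets) is None

    def test_event_set_monotone_in_bleach_tolerance(self, mixed_fate_scene):
        stack, gt, dets, tracks = mixed_fate_scene
        accepted = {}
        for tol in (0.02, 0.10, 0.50):
            crit = EventCriteria(bleach_tolerance=tol)
            evs = puncta.call_events([t for t in tracks], stack, dets,
                                     criteria=crit, cell_mask=gt.cell_mask)
            accepted[tol] = {e.track_id for e in evs}
        assert accepted[0.02] <= accepted[0.10] <= accepted[0.50]


class TestRegionStatistics:
    def test_event_counts_conserved_across_regions(self, mixed_fate_scene,
                                                   ellipse_partition):
        stack, gt, dets, tracks = mixed_fate_scene
        _, part = ellipse_partition
        events = puncta.call_events([t for t in tracks], stack, dets,
                                    cell_mask=gt.cell_mask)
        # scale event positions from the 384 px scene into the partition mask
        scale = 320.0 / 384.0
        for ev in events:
            ev.x_px *= scale
            ev.y_px *= scale
        df = puncta.events_per_region(events, part, 0.1, tracks=tracks)
        in_regions = sum(1 for e in events if e.region in
                         ("front", "middle", "back"))
        assert int(df["count"].sum()) == in_regions

    def test_all_static_dynamic_fraction_zero(self, ellipse_partition):
        _, part = ellipse_partition
        tracks = []
        for i, x in enumerate((600.0, 1600.0, 2600.0)):
            tracks.append(puncta.PunctaTrack(
                id=i, frames=np.arange(5), x_px=np.full(5, x / 10),
                y_px=np.full(5, 120.0), intensity=np.full(5, 200.0),
                background=np.full(5, 100.0), fate="static"))
        df = puncta.dynamic_fraction(tracks, part, 0.1)
        present = df[df["total_spots"] > 0]
        assert (present["dynamic_fraction"] == 0.0).all()

    def test_all_dynamic_fraction_one_and_empty_region_missing(self,
                                                               ellipse_partition):
        _, part = ellipse_partition
        tracks = [puncta.PunctaTrack(
            id=0, frames=np.arange(5), x_px=np.full(5, 290.0),
            y_px=np.full(5, 120.0), intensity=np.full(5, 200.0),
            background=np.full(5, 100.0), fate="disappearing")]
        df = puncta.dynamic_fraction(tracks, part, 0.1).set_index("region")
        assert df.loc["front", "dynamic_fraction"] == 1.0
        assert np.isnan(df.loc["back", "dynamic_fraction"])
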