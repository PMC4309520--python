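"""Adhesion segmentation, disassembly timing and recruitment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chemotirf import adhesions, puncta, synthgen
from chemotirf.core import DisassemblyMeasurement, FocalAdhesion, TimelapseStack
from chemotirf.synthgen import GeneratorConfig


def _fa_frame(centres, shape=(256, 256), amp=300.0, bg=100.0, noise=10.0,
              smaj=5.0, smin=1.25, seed=0):
    img = np.full(shape, bg)
    for (x, y) in centres:
        synthgen._add_aniso_gaussian(img, x, y, amp, smaj, smin, 0.3)
    img += np.random.default_rng(seed).normal(0, noise, shape)
    return TimelapseStack(img, 0.1, 30.0)


def _make_fa(trace, fa_id=0):
    mask = np.zeros((8, 8), dtype=bool)
    mask[3:5, 2:7] = True
    return FocalAdhesion(id=fa_id, centroid_px=(4.0, 3.5), major_axis_px=5.0,
                         minor_axis_px=2.0, orientation_rad=0.0,
                         frames=np.arange(len(trace)),
                         intensity=np.asarray(trace, dtype=float), mask=mask)


class TestDetection:
    def test_blank_frame_no_objects(self):
        stack = TimelapseStack(
            np.random.default_rng(1).normal(100, 10, (64, 64)), 0.1, 30.0)
        assert adhesions.detect_fas(stack) == []

    def test_planted_ellipse_found_with_accurate_centroid(self):
        stack = _fa_frame([(120.0, 80.0)])
        fas = adhesions.detect_fas(stack)
        assert len(fas) == 1
        assert abs(fas[0].centroid_px[0] - 120.0) < 1.0
        assert abs(fas[0].centroid_px[1] - 80.0) < 1.0
        assert fas[0].elongation > 1.5

    def test_two_adhesions_five_microns_apart(self):
        stack = _fa_frame([(100.0, 100.0), (150.0, 100.0)])
        assert len(adhesions.detect_fas(stack)) == 2

    def test_size_filter_excludes_huge_objects(self):
        img = np.full((128, 128), 100.0)
        img[20:110, 20:110] = 400.0           # 81 µm² block, above the cap
        img += np.random.default_rng(0).normal(0, 10, img.shape)
        stack = TimelapseStack(img, 0.1, 30.0)
        assert adhesions.detect_fas(stack) == []


class TestPerRegionCounts:
    def test_all_in_back_region(self, ellipse_partition):
        _, part = ellipse_partition
        fas = [_make_fa([100.0] * 3, fa_id=i) for i in range(4)]
        for fa in fas:
            fa.centroid_px = (40.0, 120.0)    # far -x: the back band
        df = adhesions.count_fas_per_region(fas, part, 0.1).set_index("region")
        assert df.loc["back", "count"] == 4
        assert df.loc["front", "count"] == 0
        assert int(df["count"].sum()) == 4

    def test_uniform_planting_gives_equal_densities(self, ellipse_partition):
        mask, part = ellipse_partition
        rng = np.random.default_rng(5)
        rows, cols = np.nonzero(mask)
        idx = rng.choice(len(rows), size=3000)
        counts = {"front": 0, "middle": 0, "back": 0}
        from chemotirf.regions import assign_region

        for i in idx:
            reg = assign_region((cols[i] * 0.1, rows[i] * 0.1), part)
            if reg in counts:
                counts[reg] += 1
        dens = [counts[n] / part.areas_um2[n] for n in counts]
        assert max(dens) / min(dens) < 1.15


class TestDisassemblyTime:
    def test_step_trace_arithmetic(self):
        # plateau 100 through frame 10, decline, gone at frame 20; 1 min/frame
        trace = np.concatenate([np.full(11, 100.0), np.full(9, 50.0),
                                np.zeros(10)])
        meas = adhesions.disassembly_time(_make_fa(trace), frame_interval_s=60.0)
        assert meas is not None
        assert meas.onset_frame == 10
        assert meas.end_frame == 20
        assert meas.time_min == pytest.approx(10.0)

    def test_constant_trace_censored(self):
        assert adhesions.disassembly_time(_make_fa(np.full(30, 80.0)),
                                          30.0) is None

    def test_scale_invariance(self):
        trace = np.concatenate([np.full(11, 100.0),
                                np.linspace(100, 0, 15), np.zeros(10)])
        a = adhesions.disassembly_time(_make_fa(trace), 30.0)
        b = adhesions.disassembly_time(_make_fa(trace * 7.5), 30.0)
        assert (a.onset_frame, a.end_frame) == (b.onset_frame, b.end_frame)

    def test_measurement_invariants(self):
        with pytest.raises(ValueError):
            DisassemblyMeasurement(fa_id=0, onset_frame=5, end_frame=5,
                                   time_min=0.0)

    def test_planted_linear_decay_recovered(self):
        # oracle: the onset/end definitions applied to the noiseless ramp
        errs = []
        for seed in range(4):
            gc = GeneratorConfig(n_adhesions=6, n_frames=80,
                                 frame_interval_s=30.0, n_puncta=0,
                                 second_channel=False,
                                 fa_disassemble_fraction=1.0, seed=seed)
            stack, gt = synthgen.make_tirf_timelapse(gc)
            for fa in adhesions.detect_fas(stack):
                meas = adhesions.disassembly_time(fa, 30.0)
                if meas is None:
                    continue
                pa = min(gt.adhesions,
                         key=lambda a: np.hypot(a.x_px - fa.centroid_px[0],
                                                a.y_px - fa.centroid_px[1]))
                d = pa.end_frame - pa.onset_frame
                onset = pa.onset_frame + int(np.floor(0.1 * d + 1e-9))
                end = pa.onset_frame + int(np.ceil(0.98 * d - 1e-9))
                errs.append((meas.end_frame - meas.onset_frame) - (end - onset))
        errs = np.abs(errs)
        assert len(errs) >= 20
        assert errs.mean() <= 1.0            # within one frame on average
        assert np.median(errs) <= 1.0


class TestClathrinAtFA:
    def test_puncta_inside_every_adhesion(self):
        fas = [_make_fa(np.full(3, 100.0), fa_id=i) for i in range(3)]
        pts = np.array([[4.0, 3.5]] * 3)
        df = adhesions.clathrin_at_fa(fas, pts, radius_px=2)
        assert df["positive"].all()

    def test_disjoint_layout_fraction_zero(self):
        fas = [_make_fa(np.full(3, 100.0))]
        pts = np.array([[100.0, 100.0]])
        df = adhesions.clathrin_at_fa(fas, pts, radius_px=2)
        assert not df["positive"].any()

    def test_chance_overlap_matches_analytic_level(self):
        # null data: independent puncta at the packaged chance density
        pos = tot = 0
        for seed in range(10):
            gc = GeneratorConfig(n_adhesions=8, n_frames=1, n_puncta=0,
                                 second_channel=True, seed=900 + seed)
            stack, gt = synthgen.make_tirf_timelapse(gc)
            fas = adhesions.detect_fas(stack, channel=0)
            det = puncta.detect_puncta(stack.frame(0, 1))
            xy = np.array([[p.x_px, p.y_px] for p in det]) \
                if det else np.empty((0, 2))
            df = adhesions.clathrin_at_fa(fas, xy, radius_px=2.0)
            pos += int(df["positive"].sum())
            tot += len(df)
        p_exp = 0.07
        se = np.sqrt(p_exp * (1 - p_exp) / tot)
        assert abs(pos / tot - p_exp) < 3 * se

    def test_recruitment_flag_uses_disassembly_window(self):
        fa = _make_fa(np.full(20, 100.0))
        meas = {0: DisassemblyMeasurement(fa_id=0, onset_frame=5,
                                          end_frame=10, time_min=2.5)}
        pts = np.array([[4.0, 3.5], [4.0, 3.5]])
        frames = np.array([2, 7])
        df = adhesions.clathrin_at_fa([fa], pts, radius_px=2,
                                      puncta_frames=frames, measurements=meas)
        assert bool(df.loc[0, "recruited"])
        df2 = adhesions.clathrin_at_fa([fa], pts[:1], radius_px=2,
                                       puncta_frames=frames[:1],
                                       measurements=meas)
        assert not bool(df2.loc[0, "recruited"])


class TestCompareDisassembly:
    @staticmethod
    def _group(times):
        return [DisassemblyMeasurement(fa_id=i, onset_frame=0,
                                       end_frame=max(int(t * 2), 1),
                                       time_min=t)
                for i, t in enumerate(times)]

    def test_identical_groups_not_distinguished(self, rng):
        t = rng.gamma(10, 1.5, 40)
        df = adhesions.compare_disassembly({"nsc": self._group(t),
                                            "kd": self._group(t)})
        assert df.set_index("group").loc["kd", "p_vs_first"] > 0.9
        means = df["mean_min"]
        assert means.iloc[0] == pytest.approx(means.iloc[1])

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(40):
            a = rng.gamma(10, 1.5, 30)
            b = rng.gamma(10, 1.5, 30)
            df = adhesions.compare_disassembly({"a": self._group(a),
                                                "b": self._group(b)})
            if df.set_index("group").loc["b", "p_vs_first"] < 0.05:
                rejections += 1
        assert rejections <= 6   # nominal 2 of 40; generous binomial slack

    def test_power_against_twofold_slower_group(self):
        rng = np.random.default_rng(8)
        detected = 0
        for _ in range(10):
            a = rng.gamma(10, 1.5, 100)
            b = rng.gamma(10, 3.0, 100)
            df = adhesions.compare_disassembly({"a": self._group(a),
                                                "b": self._group(b)})
            if df.set_index("group").loc["b", "p_vs_first"] < 0.05:
                detected += 1
        assert detected >= 9

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            adhesions.compare_disassembly({"a": self._group([5.0, 6.0]),
                                           "b": self._group([5.0] * 5)})

    def test_welch_variant_available(self, rng):
        a = rng.gamma(10, 1.5, 20)
        b = rng.gamma(10, 1.5, 20)
        df = adhesions.compare_disassembly({"a": self._group(a),
                                            "b": self._group(b)},
                                           test="welch")
        assert np.isfinite(df.set_index("group").loc["b", "p_vs_first"])
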