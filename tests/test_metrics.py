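"""Functional readouts: PSNR, soma detection, traces, orientation selectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from mfias import metrics, phantom
from mfias.metrics import (
    TuningCurve,
    detect_somas,
    extract_trace,
    osi,
    psnr,
    trimmed_std,
)


def _sources(xy):
    return pd.DataFrame(xy, columns=["x", "y"])


class TestPSNR:
    def test_pulse_matches_filtered_noise_prediction(self, rng):
        # one bright broad pulse over seeded Gaussian noise: psnr ~ p_filtered
        # over sigma_filtered, with sigma_filtered given by the iid-noise
        # variance reduction of a 2D Gaussian filter, sigma/ (2 sqrt(pi) s)
        t_len, side, s = 120, 160, 10.0
        sigma0 = 3.0
        movie = rng.normal(0, sigma0, (t_len, side, side))
        yy, xx = np.mgrid[0:side, 0:side]
        blob = 40.0 * np.exp(-((yy - 80) ** 2 + (xx - 80) ** 2) / (2 * 6.0**2))
        movie[60] += blob
        report = psnr(
            movie, _sources([(80.0, 80.0)]), filter_sigma_px=s, source_radius_px=20
        )
        sigma_pred = sigma0 / (2 * np.sqrt(np.pi) * s)
        assert report.noise_sigma == pytest.approx(sigma_pred, rel=0.15)
        # the filter shrinks a Gaussian blob's peak by b^2/(b^2+s^2)
        peak_pred = 40.0 * 6.0**2 / (6.0**2 + s**2)
        assert report.table.psnr.iloc[0] == pytest.approx(peak_pred / sigma_pred, rel=0.2)

    def test_doubling_brightness_doubles_psnr(self, rng):
        t_len, side = 60, 128
        base = rng.normal(0, 2.0, (t_len, side, side))
        yy, xx = np.mgrid[0:side, 0:side]
        blob = np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 6.0**2))
        m1, m2 = base.copy(), base.copy()
        m1[30] += 20 * blob
        m2[30] += 40 * blob
        p1 = psnr(m1, _sources([(64.0, 64.0)]), source_radius_px=15).table.psnr.iloc[0]
        p2 = psnr(m2, _sources([(64.0, 64.0)]), source_radius_px=15).table.psnr.iloc[0]
        assert p2 == pytest.approx(2 * p1, rel=0.05)

    def test_static_background_invariance(self, rng):
        t_len, side = 40, 96
        movie = rng.normal(0, 2.0, (t_len, side, side))
        movie[10, 40:56, 40:56] += 30.0
        yy, xx = np.mgrid[0:side, 0:side]
        static = 100.0 + 0.5 * xx + 20.0 * np.exp(-((yy - 20) ** 2) / 50.0)
        r1 = psnr(movie, _sources([(48.0, 48.0)]))
        r2 = psnr(movie + static, _sources([(48.0, 48.0)]))
        assert r1.table.psnr.iloc[0] == pytest.approx(r2.table.psnr.iloc[0], rel=1e-6)

    def test_pure_noise_source_reads_near_unit_baseline(self):
        # a "source" with no signal sits at the O(1) baseline, far below
        # any real source
        vals = []
        for seed in range(8):
            movie = np.random.default_rng(seed).normal(0, 3.0, (80, 96, 96))
            vals.append(psnr(movie, _sources([(48.0, 48.0)])).table.psnr.iloc[0])
        med = np.median(vals)
        assert 1.0 <= med <= 4.0

    def test_zero_noise_flagged(self):
        movie = np.zeros((5, 32, 32))
        with pytest.warns(UserWarning, match="PSNR undefined"):
            report = psnr(movie, _sources([(16.0, 16.0)]))
        assert np.isnan(report.noise_sigma)

    def test_short_movie_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((1, 8, 8)), _sources([(4.0, 4.0)]))


class TestDetectSomas:
    @staticmethod
    def _grid_phantom(cfg, seed, brightness=6000.0, t_len=100):
        r = np.random.default_rng(seed)
        somas = []
        for y in np.linspace(-200, 200, 4):
            for x in np.linspace(-220, 220, 5):
                jx, jy = r.uniform(-10, 10, 2)
                somas.append(
                    phantom.Emitter(x + jx, y + jy, 0.0, 15.0, brightness)
                )
        traces = [
            phantom.CalciumTrace(
                spike_frames=tuple(
                    np.sort(r.choice(np.arange(5, t_len - 10), int(r.integers(2, 5)),
                                     replace=False)).tolist()
                )
            )
            for _ in somas
        ]
        movie, truth, values = phantom.render_time_series(
            somas, traces, cfg, t_len, (256, 256),
            noise=phantom.NoiseModel(), seed=r,
        )
        return movie, truth, values, traces

    def test_blinking_somas_recovered(self, cfg):
        movie, truth, *_ = self._grid_phantom(cfg, seed=5)
        detected = detect_somas(movie)
        tx = truth.x_um / 2 + 127.5
        ty = truth.y_um / 2 + 127.5
        hits, false_pos, used = 0, 0, set()
        for row in detected.itertuples():
            dist = np.hypot(tx - row.x, ty - row.y)
            j = int(dist.idxmin())
            if dist[j] <= 2.0 and j not in used:
                hits += 1
                used.add(j)
            elif dist.min() > 5.0:
                false_pos += 1
        assert hits >= 0.95 * len(truth)
        assert false_pos <= 1

    def test_static_gradient_no_detections(self):
        yy, xx = np.mgrid[0:64, 0:64]
        frame = 50.0 + 0.8 * xx + 0.3 * yy
        movie = np.tile(frame, (40, 1, 1))
        assert detect_somas(movie).empty

    def test_empty_movie_empty_set(self):
        assert detect_somas(np.zeros((20, 32, 32))).empty


class TestExtractTrace:
    def test_constant_movie_zero_dff(self):
        movie = np.full((30, 64, 64), 80.0)
        with pytest.warns(UserWarning, match="F0"):
            tr = extract_trace(movie, 32.0, 32.0)
        # constant raw minus constant background has zero fluctuation, but a
        # vanishing baseline: dF/F is flagged undefined there
        assert np.all((tr.raw - tr.background) == (tr.raw - tr.background)[0])

    def test_recovered_trace_correlates_with_truth(self, cfg):
        movie, truth, values, _ = TestDetectSomas._grid_phantom(cfg, seed=5)
        bg = gaussian_filter(movie, (0, 15, 15))
        cors = []
        for j in range(len(truth)):
            tr = extract_trace(
                movie, float(truth.x_um[j] / 2 + 127.5),
                float(truth.y_um[j] / 2 + 127.5), background_movie=bg,
            )
            cors.append(np.corrcoef(tr.dff, values[j])[0, 1])
        assert np.median(cors) > 0.9

    def test_dff_peaks_track_spike_frames(self, cfg):
        movie, truth, values, traces = TestDetectSomas._grid_phantom(cfg, seed=11)
        bg = gaussian_filter(movie, (0, 15, 15))
        good, total = 0, 0
        for j in range(len(truth)):
            tr = extract_trace(
                movie, float(truth.x_um[j] / 2 + 127.5),
                float(truth.y_um[j] / 2 + 127.5), background_movie=bg,
            )
            for s in traces[j].spike_frames:
                total += 1
                window = tr.dff[max(s - 2, 0) : s + 3]
                good += window.max() >= 0.5
        assert good / total >= 0.90

    def test_uniform_offset_only_moves_f0(self, rng):
        movie = rng.normal(100.0, 2.0, (40, 48, 48))
        movie[:, 24, 24] += 30.0 * np.sin(np.linspace(0, 3, 40)) ** 2
        t1 = extract_trace(movie, 24.0, 24.0)
        t2 = extract_trace(movie + 50.0, 24.0, 24.0)
        # raw-minus-background is offset-free up to filter edge effects, so
        # F0 and dF/F agree closely
        assert t2.f0 == pytest.approx(t1.f0, rel=0.05)
        assert np.allclose(t1.dff, t2.dff, atol=0.05)


class TestOSI:
    @staticmethod
    def _curve(r_pref, r_orth, r_other=0.2, n_trials=5, jitter=0.0, seed=0):
        r = np.random.default_rng(seed)
        means = np.full(8, r_other)
        means[0] = r_pref
        means[2] = r_orth  # 90 deg
        means[6] = r_orth  # 270 deg
        resp = np.tile(means[:, None], (1, n_trials)) + r.normal(0, jitter, (8, n_trials))
        blank = r.normal(0, jitter + 1e-12, n_trials)
        return TuningCurve(np.arange(8) * 45.0, resp, blank)

    @pytest.mark.parametrize(
        "r_pref,r_orth,expected",
        [(2.0, 1.0, 1.0 / 3.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0)],
    )
    def test_printed_formula(self, r_pref, r_orth, expected):
        res = osi(self._curve(r_pref, r_orth, r_other=min(r_orth, 0.2)))
        assert res.osi == pytest.approx(expected, abs=1e-9)

    def test_anova_gate(self):
        responsive = osi(self._curve(2.0, 0.5, jitter=0.05, seed=1))
        assert responsive.responsive and responsive.anova_p < 0.01
        flat = TuningCurve(
            np.arange(8) * 45.0,
            np.random.default_rng(2).normal(0, 1.0, (8, 5)),
            np.random.default_rng(3).normal(0, 1.0, 5),
        )
        assert not osi(flat).responsive

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        base = self._curve(2.0, 0.5, jitter=0.0)
        scaled = TuningCurve(
            base.orientations_deg, scale * base.trial_responses, scale * base.blank_responses
        )
        assert osi(scaled).osi == pytest.approx(osi(base).osi, rel=1e-9)

    def test_swap_symmetry(self):
        # exchanging the preferred and orthogonal response levels moves the
        # preferred direction by 90 deg but leaves the index unchanged
        a = (2.0 - 0.5) / 2.5
        forward = osi(self._curve(2.0, 0.5, r_other=0.5))
        swapped = osi(self._curve(0.5, 2.0, r_other=0.5))
        assert forward.theta_pref_deg == 0.0
        assert swapped.theta_pref_deg in (90.0, 270.0)
        assert forward.osi == pytest.approx(a, abs=1e-9)
        assert swapped.osi == pytest.approx(a, abs=1e-9)

    def test_zero_denominator_flagged(self):
        curve = self._curve(0.0, 0.0, r_other=0.0)
        with pytest.warns(UserWarning, match="undefined"):
            res = osi(curve)
        assert np.isnan(res.osi)

    def test_double_gaussian_fit_reported(self):
        res = osi(self._curve(2.0, 0.8, jitter=0.02, seed=4))
        assert res.fit_params is not None
        assert res.fit_params["theta_pref_deg"] == res.theta_pref_deg
        assert res.fit_params["amp_pref"] > res.fit_params["amp_orth"]

    def test_wrong_orientations_rejected(self):
        with pytest.raises(ValueError):
            TuningCurve(np.arange(8) * 30.0, np.zeros((8, 5)), np.zeros(5))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            TuningCurve(np.arange(8) * 45.0, np.zeros((8, 1)), np.zeros(5))


class TestTrimmedStd:
    def test_equal_trials_zero(self):
        assert trimmed_std(np.full(5, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_extremes_dropped(self):
        # std of {1, 2, 3} after dropping 0 and 100
        assert trimmed_std(np.array([0.0, 1.0, 2.0, 3.0, 100.0])) == pytest.approx(1.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            trimmed_std(np.array([1.0, 2.0]))
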