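import numpy as np
import pytest

from gaitdmo import icd, simgait, sl
from gaitdmo._dsp import G_MPS2
from gaitdmo.exceptions import InsufficientEventsError
from gaitdmo.io import GaitSequence, SubjectInfo
from conftest import make_recording


def _ics(times):
    times = np.asarray(times, dtype=float)
    gs = GaitSequence(max(times[0], 0.01), times[-1] + 0.1)
    return icd.InitialContactList(times, gs)


def _displacement_recording(amp_m=0.02, freq=2.0, total_s=20.0, fs=100.0):
    """acc_v reconstructed analytically from s(t) = amp * sin(2 pi f t)."""
    t = np.arange(0, total_s, 1 / fs)
    acc = -amp_m * (2 * np.pi * freq) ** 2 * np.sin(2 * np.pi * freq * t)
    return make_recording(1.0 + acc / G_MPS2), t


class TestVerticalDisplacement:
    def test_closed_form_amplitude(self):
        rec, t = _displacement_recording(amp_m=0.02, freq=2.0)
        # ICs at the displacement troughs: t = 3/(4f) + k/f
        ics = _ics(3 / 8 + np.arange(4, 24) * 0.5)
        h = sl.vertical_displacement(rec, ics)
        assert np.allclose(h, 0.04, rtol=0.10)

    def test_zero_acc(self):
        rec = make_recording(np.ones(3000))
        h = sl.vertical_displacement(rec, _ics([5.0, 5.5, 6.0, 6.5]))
        assert np.allclose(h, 0.0, atol=1e-9)

    def test_linearity(self):
        rec1, _ = _displacement_recording(amp_m=0.02)
        rec2, _ = _displacement_recording(amp_m=0.04)
        ics = _ics(3 / 8 + np.arange(4, 24) * 0.5)
        h1 = sl.vertical_displacement(rec1, ics)
        h2 = sl.vertical_displacement(rec2, ics)
        assert np.allclose(h2, 2 * h1, rtol=0.02)

    def test_short_step_skipped(self):
        rec, _ = _displacement_recording()
        # raw times: an InitialContactList would already merge the 0.1 s pair
        with pytest.warns(UserWarning, match="skipped"):
            h = sl.vertical_displacement(rec, np.array([5.0, 5.1, 6.0]))
        assert len(h) == 1

    def test_too_few_ics(self):
        rec = make_recording(np.ones(1000))
        with pytest.raises(InsufficientEventsError):
            sl.vertical_displacement(rec, _ics([5.0]))


class TestSlParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            sl.SlParams(k=-1.0)

    def test_cohort_constants(self, subject):
        assert sl.params_for("a", subject).k == pytest.approx(4.739)
        assert sl.params_for("b", subject).k == pytest.approx(4.99)
        ms = SubjectInfo(0.9, 0.25, cohort="MS")
        assert sl.params_for("b", ms).k == pytest.approx(4.587)
        assert sl.params_for("c", subject).t == pytest.approx(0.93)
        assert sl.params_for("d", subject).t == pytest.approx(0.85)


class TestSlPendulum:
    def test_closed_form(self, subject, monkeypatch):
        # k * sqrt(2 l h - h^2) with l = 0.9, h = 0.02, k = 4.739
        monkeypatch.setattr(sl, "vertical_displacement",
                            lambda rec, ics, pad_s=1.0: np.full(4, 0.02))
        rec = make_recording(np.ones(2000))
        res = sl.sl_pendulum(rec, _ics([1, 2, 3, 4, 5]), subject,
                             sl.SlParams(k=4.739))
        expected = 4.739 * np.sqrt(2 * 0.9 * 0.02 - 0.02 ** 2)
        assert res.sl_mean == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.894, abs=0.001)

    def test_zero_displacement_warns(self, subject):
        rec = make_recording(np.ones(2000))
        res = sl.sl_pendulum(rec, _ics([5.0, 6.0, 7.0]), subject)
        assert res.sl_mean == pytest.approx(0.0, abs=1e-6)
        assert res.warning

    def test_linear_in_k(self, subject, monkeypatch):
        monkeypatch.setattr(sl, "vertical_displacement",
                            lambda rec, ics, pad_s=1.0: np.full(4, 0.03))
        rec = make_recording(np.ones(2000))
        r1 = sl.sl_pendulum(rec, _ics([1, 2, 3, 4, 5]), subject, sl.SlParams(k=4.99))
        r2 = sl.sl_pendulum(rec, _ics([1, 2, 3, 4, 5]), subject, sl.SlParams(k=4.587))
        assert r1.sl_mean / r2.sl_mean == pytest.approx(4.99 / 4.587)

    def test_monotone_in_h_and_k(self, subject, monkeypatch):
        rec = make_recording(np.ones(2000))
        means = []
        for h in (0.01, 0.02, 0.04):
            monkeypatch.setattr(sl, "vertical_displacement",
                                lambda rec, ics, pad_s=1.0, h=h: np.full(4, h))
            means.append(sl.sl_pendulum(rec, _ics([1, 2, 3, 4, 5]), subject,
                                        sl.SlParams(k=2.0)).sl_mean)
        assert means[0] < means[1] < means[2]

    def test_recovery_on_generated_signal(self, subject):
        spec = simgait.BoutSpec(5.0, 20, 100, 0.9)
        rec, truth = simgait.generate_recording(simgait.SimProtocol(bouts=(spec,)))
        ics = icd.InitialContactList(truth[0].ic_times_s, truth[0].as_sequence())
        res = sl.sl_pendulum(rec, ics, subject,
                             sl.SlParams(k=simgait.DEFAULT_K_GEN))
        assert res.sl_mean == pytest.approx(0.9, rel=0.10)

    def test_distance_conservation(self, subject):
        spec = simgait.BoutSpec(5.0, 10, 100, 0.9)
        rec, truth = simgait.generate_recording(simgait.SimProtocol(bouts=(spec,)))
        ics = icd.InitialContactList(truth[0].ic_times_s, truth[0].as_sequence())
        res = sl.sl_pendulum(rec, ics, subject)
        assert res.distance_m == pytest.approx(float(np.sum(res.step_lengths_m)))


class TestSlIntensity:
    def test_zero_acc_gives_offset(self, subject):
        rec = make_recording(np.ones(2000))
        res = sl.sl_intensity(rec, _ics([5.0, 6.0, 7.0]), subject,
                              sl.SlParams(t=0.93, p=0.25))
        assert res.sl_mean == pytest.approx(0.25, abs=1e-6)

    def test_formula_value(self, subject):
        # mean |a_v| = 1 m/s^2 -> 0.93 * 1 + 0.25 (the spec-flagged value)
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        tone = (np.pi / 2) * np.cos(2 * np.pi * 5.0 * t) / G_MPS2  # mean|.| = 1
        rec = make_recording(tone)
        res = sl.sl_intensity(rec, _ics([5.0, 6.0, 7.0, 8.0]), subject,
                              sl.SlParams(t=0.93, p=0.25))
        assert res.sl_mean == pytest.approx(1.18, abs=0.02)

    def test_cube_root_homogeneity(self, subject):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        tone = np.cos(2 * np.pi * 5.0 * t)
        ics = _ics([5.0, 6.0, 7.0, 8.0])
        r1 = sl.sl_intensity(make_recording(tone / G_MPS2), ics, subject,
                             sl.SlParams(t=0.93, p=0.25))
        r8 = sl.sl_intensity(make_recording(8 * tone / G_MPS2), ics, subject,
                             sl.SlParams(t=0.93, p=0.25))
        assert (r8.sl_mean - 0.25) == pytest.approx(2 * (r1.sl_mean - 0.25),
                                                    rel=0.02)


class TestSlHybrid:
    def test_degenerate_gives_half_offset(self, subject):
        rec = make_recording(np.ones(2000))   # zero dynamics on both axes
        res = sl.sl_hybrid(rec, _ics([5.0, 6.0, 7.0]), subject,
                           sl.SlParams(t=0.85, p=0.25))
        assert res.sl_mean == pytest.approx(0.125, abs=1e-6)

    def test_geometric_component_arithmetic(self, subject):
        # a_v range 16 m/s^2 -> 0.85 * 2 + 0.25 = 1.95; no AP signal
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        sq = 8.0 * np.cos(2 * np.pi * 5.0 * t) / G_MPS2
        rec = make_recording(sq)
        res = sl.sl_hybrid(rec, _ics([5.0, 6.0, 7.0, 8.0]), subject,
                           sl.SlParams(t=0.85, p=0.25))
        assert res.sl_mean == pytest.approx(1.95 / 2, abs=0.02)

    def test_simgait_error_within_25pct(self, subject):
        spec = simgait.BoutSpec(5.0, 15, 100, 1.0)
        rec, truth = simgait.generate_recording(simgait.SimProtocol(bouts=(spec,)))
        ics = icd.InitialContactList(truth[0].ic_times_s, truth[0].as_sequence())
        res = sl.sl_hybrid(rec, ics, subject)
        assert abs(res.sl_mean - 1.0) <= 0.25


class TestDispatch:
    def test_unknown(self, subject, simple_bout):
        rec, bout = simple_bout
        ics = icd.InitialContactList(bout.ic_times_s, bout.as_sequence())
        with pytest.raises(ValueError):
            sl.estimate_stride_length(rec, ics, subject, "x")

    def test_a_equals_pendulum(self, subject, simple_bout):
        rec, bout = simple_bout
        ics = icd.InitialContactList(bout.ic_times_s, bout.as_sequence())
        r1 = sl.estimate_stride_length(rec, ics, subject, "a")
        r2 = sl.sl_pendulum(rec, ics, subject, sl.SlParams(k=4.739))
        assert r1.sl_mean == pytest.approx(r2.sl_mean)
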