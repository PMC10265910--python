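import numpy as np
import pytest

from gaitdmo import validate
from gaitdmo.exceptions import DataError
from gaitdmo.io import GaitSequence


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def window_oracle(detected, reference, total_s, window_s=0.1):
    """Literal per-window enumeration with the majority-overlap rule."""
    def overlap(intervals, lo, hi):
        return sum(max(0.0, min(s.end_s, hi) - max(s.start_s, lo))
                   for s in intervals)
    n = int(np.floor(total_s / window_s + 1e-9))
    tp = fp = fn = tn = 0
    for i in range(n):
        lo, hi = i * window_s, (i + 1) * window_s
        d = overlap(detected, lo, hi) > window_s / 2
        r = overlap(reference, lo, hi) > window_s / 2
        tp += d and r
        fp += d and not r
        fn += r and not d
        tn += not d and not r
    return tp, fp, fn, tn


def match_oracle(det, ref, tol=0.5):
    """Brute-force nearest-candidate matching, ties to the earlier event."""
    det = sorted(det)
    used = [False] * len(det)
    tp, errors = 0, []
    for r in sorted(ref):
        best, best_d = None, None
        for j, d in enumerate(det):
            if used[j] or abs(d - r) > tol / 2:
                continue
            if best is None or abs(d - r) < best_d:
                best, best_d = j, abs(d - r)
        if best is not None:
            used[best] = True
            tp += 1
            errors.append(best_d)
    return tp, len(det) - tp, len(ref) - tp, errors


def _seqs(pairs):
    return [GaitSequence(a, b) for a, b in pairs]


class TestClassifyGsdWindows:
    def test_worked_example(self):
        c = validate.classify_gsd_windows(_seqs([(0.5, 1.5)]), _seqs([(0.0, 1.0)]),
                                          total_duration_s=2.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 5, 5, 5)

    def test_identity(self):
        ref = _seqs([(1.0, 3.0), (5.0, 8.0)])
        c = validate.classify_gsd_windows(ref, ref, 10.0)
        assert c.fp == 0 and c.fn == 0

    def test_empty_detection(self):
        c = validate.classify_gsd_windows([], _seqs([(0.0, 1.0)]), 2.0)
        assert c.tp == 0 and c.fp == 0 and c.fn == 10 and c.tn == 10

    def test_total_window_count(self):
        c = validate.classify_gsd_windows(_seqs([(0.33, 2.71)]),
                                          _seqs([(1.0, 1.9)]), 7.03)
        assert c.total == int(7.03 / 0.1)

    def test_swap_symmetry(self):
        det, ref = _seqs([(0.7, 2.2)]), _seqs([(1.1, 3.3)])
        a = validate.classify_gsd_windows(det, ref, 5.0)
        b = validate.classify_gsd_windows(ref, det, 5.0)
        assert (a.tp, a.tn) == (b.tp, b.tn)
        assert (a.fp, a.fn) == (b.fn, b.fp)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            total = float(rng.uniform(5, 60))
            def rand_intervals():
                out, t = [], 0.0
                while True:
                    t += rng.uniform(0.3, 5.0)
                    end = t + rng.uniform(0.3, 8.0)
                    if end > total:
                        break
                    out.append((t, end))
                    t = end
                return _seqs(out)
            det, ref = rand_intervals(), rand_intervals()
            c = validate.classify_gsd_windows(det, ref, total)
            assert (c.tp, c.fp, c.fn, c.tn) == window_oracle(det, ref, total)


class TestMatchIcs:
    def test_worked_example(self):
        m = validate.match_ics([1.1, 2.6], [1.0, 2.0, 3.0])
        assert (m.counts.tp, m.counts.fp, m.counts.fn) == (1, 1, 2)
        assert np.allclose(m.abs_errors_s, [0.1])

    def test_identity(self):
        m = validate.match_ics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.counts.tp == 3
        assert np.allclose(m.abs_errors_s, 0.0)

    def test_tie_broken_to_earlier(self):
        m = validate.match_ics([0.9, 1.1], [1.0])
        assert (m.counts.tp, m.counts.fp) == (1, 1)
        # the earlier of the two equidistant candidates is consumed

    def test_tn_not_evaluated(self):
        m = validate.match_ics([1.0], [1.0])
        assert m.counts.tn is None
        assert validate.confusion_measures(m.counts)["specificity"] is None

    def test_relative_errors_use_mean_step(self):
        m = validate.match_ics([1.05, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.allclose(sorted(m.rel_errors_pct), [0.0, 0.0, 5.0])

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            det = np.sort(rng.uniform(0, 20, rng.integers(0, 21)))
            ref = np.sort(rng.uniform(0, 20, rng.integers(1, 21)))
            m = validate.match_ics(det, ref)
            tp, fp, fn, errs = match_oracle(det, ref)
            assert (m.counts.tp, m.counts.fp, m.counts.fn) == (tp, fp, fn)
            assert np.allclose(sorted(m.abs_errors_s), sorted(errs))
            assert m.counts.tp + m.counts.fn == len(ref)
            assert m.counts.tp + m.counts.fp == len(det)


class TestConfusionMeasures:
    def test_worked_example(self):
        c = validate.ConfusionCounts(tp=8, tn=90, fp=1, fn=1)
        out = validate.confusion_measures(c)
        assert out["accuracy"] == pytest.approx(0.98)
        assert out["sensitivity"] == pytest.approx(8 / 9)
        assert out["specificity"] == pytest.approx(90 / 91)
        assert out["ppv"] == pytest.approx(8 / 9)

    def test_perfect(self):
        out = validate.confusion_measures(
            validate.ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in out.values())

    def test_undefined_ppv(self):
        out = validate.confusion_measures(
            validate.ConfusionCounts(tp=0, tn=5, fp=0, fn=1))
        assert out["ppv"] is None

    def test_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = validate.ConfusionCounts(*rng.integers(0, 100, 3),
                                         tn=int(rng.integers(0, 100)))
            for v in validate.confusion_measures(c).values():
                assert v is None or 0.0 <= v <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(DataError):
            validate.ConfusionCounts(tp=-1)


def hand_icc21(x, y):
    """ANOVA mean-squares decomposition, written independently."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = data - data.mean(axis=1)[:, None] - data.mean(axis=0)[None, :] + grand
    ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)


class TestAgreementStats:
    def test_perfect_agreement(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        st = validate.agreement_stats(vals, vals)
        assert st.bias == 0.0
        assert st.loa_low == 0.0 and st.loa_high == 0.0
        assert st.icc == pytest.approx(1.0)

    def test_bland_altman_example(self):
        st = validate.agreement_stats([1, 2, 3], [1, 3, 2])
        assert st.bias == pytest.approx(0.0)
        assert st.loa_low == pytest.approx(-1.96)
        assert st.loa_high == pytest.approx(1.96)

    def test_icc_matches_hand_anova(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            base = rng.normal(10, 3, 50)
            dev = base + rng.normal(0, 1, 50)
            ref = base + rng.normal(0, 1, 50)
            st = validate.agreement_stats(dev, ref)
            assert st.icc == pytest.approx(hand_icc21(dev, ref), abs=1e-10)

    def test_icc_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(10)
        base = rng.normal(5, 2, 30)
        dev = base + rng.normal(0, 0.5, 30)
        ref = base + rng.normal(0, 0.5, 30)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(30), 2),
            "raters": np.repeat(["a", "b"], 30),
            "ratings": np.concatenate([dev, ref])})
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="ratings")
        mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
        row = table[mask].iloc[0]
        icc, ci = validate.icc_2_1(dev, ref)
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert ci[0] == pytest.approx(row[ci_col][0], abs=5e-3)
        assert ci[1] == pytest.approx(row[ci_col][1], abs=5e-3)

    def test_icc_decreases_with_offset(self):
        rng = np.random.default_rng(11)
        base = rng.normal(10, 2, 40)
        dev = base + rng.normal(0, 0.3, 40)
        ref = base + rng.normal(0, 0.3, 40)
        icc0, _ = validate.icc_2_1(dev, ref)
        icc1, _ = validate.icc_2_1(dev + 2.0, ref)
        assert icc1 < icc0

    def test_zero_reference_excluded(self):
        with pytest.warns(UserWarning, match="zero reference"):
            st = validate.agreement_stats([1, 2, 3, 4], [0, 2, 3, 4])
        assert st.rel_error_pct is not None

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            validate.agreement_stats([1, 2], [1, 2, 3])


class TestGsdDurationAgreement:
    def test_identical(self):
        seqs = [_seqs([(0, 10), (20, 25)]) for _ in range(4)]
        st = validate.gsd_duration_agreement(seqs, seqs)
        assert st.bias == 0.0

    def test_constant_overdetection(self):
        ref = [_seqs([(0, 10 + i)]) for i in range(4)]
        det = [_seqs([(0, 10 + i), (50, 110)]) for i in range(4)]
        st = validate.gsd_duration_agreement(det, ref)
        assert st.bias == pytest.approx(60.0)
        assert st.loa_low == pytest.approx(60.0)
        assert st.loa_high == pytest.approx(60.0)

    def test_constructed_bias(self):
        rng = np.random.default_rng(12)
        ref, det, extras = [], [], []
        for _ in range(20):
            dur = rng.uniform(100, 1000)
            extra = rng.uniform(0, 50)
            ref.append(_seqs([(0.0, dur)]))
            det.append(_seqs([(0.0, dur + extra)]))
            extras.append(extra)
        st = validate.gsd_duration_agreement(det, ref)
        assert st.bias == pytest.approx(np.mean(extras), abs=1e-9)


class TestBinnedErrorFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        speeds = rng.uniform(0.1, 1.5, 600)
        errors = 50 * np.exp(-4 * speeds) + rng.normal(0, 0.5, 600)
        curve = validate.binned_error_fit(errors, speeds, bin_width=0.05)
        a, b = curve.fit_params
        assert -4.4 <= b <= -3.6
        assert curve.r2 >= 0.95
        assert curve.weights.sum() == pytest.approx(1.0)

    def test_flat_curve(self):
        speeds = np.linspace(0.2, 1.2, 100)
        curve = validate.binned_error_fit(np.full(100, 10.0), speeds, 0.05)
        a, b = curve.fit_params
        assert a == pytest.approx(10.0, abs=0.5)
        assert b == pytest.approx(0.0, abs=0.05)

    def test_empty_bins_skipped(self):
        cov = np.array([0.1, 0.11, 0.9, 0.91])   # big gap -> empty bins
        curve = validate.binned_error_fit([1, 1, 2, 2], cov, 0.05)
        assert len(curve.bin_centers) == 2
        assert curve.fit_params is None           # < 3 non-empty bins

    def test_contiguous_bin_grid(self):
        cov = np.array([0.12, 0.34, 0.56])
        curve = validate.binned_error_fit([1, 2, 3], cov, 0.1)
        rel = (curve.bin_centers - curve.bin_centers[0]) / 0.1
        assert np.allclose(rel, np.round(rel))
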