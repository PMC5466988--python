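import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecogmap.errors import DegenerateInputError, InvalidInputError
from ecogmap.etam import (
    MRCPTemplate,
    build_template,
    channel_significance,
    correlation_coefficient,
    etam_map,
    grand_average,
    loso_template,
    select_representative,
    signed_r2,
    trial_ccs,
)
from ecogmap.simulate import MrcpParams, mrcp_waveform

from conftest import make_trialset

FS = 100.0  # epoch window 600 samples, template 50 samples at this rate


def template_from(wave, fs=FS):
    zero = int(round(2.0 * fs))
    return MRCPTemplate(waveform=wave[zero : zero + int(0.5 * fs)], fs=fs)


@pytest.fixture
def mrcp_epoch():
    return mrcp_waveform(MrcpParams(amplitude_uv=50.0), FS)


class TestGrandAverage:
    def test_identical_trials(self, mrcp_epoch):
        epochs = np.repeat(mrcp_epoch[None, None, :], 5, axis=0)
        ts = make_trialset(epochs, fs=FS)
        ga = grand_average(ts, "chan_1")
        expected = mrcp_epoch - mrcp_epoch[: int(0.4 * FS)].mean()
        np.testing.assert_allclose(ga.waveform, expected, atol=1e-12)

    def test_noise_averages_out(self, rng, mrcp_epoch):
        sigma, n = 5.0, 200
        epochs = mrcp_epoch[None, None, :] + sigma * rng.standard_normal(
            (n, 1, mrcp_epoch.size)
        )
        ts = make_trialset(epochs, fs=FS)
        ga = grand_average(ts, "chan_1")
        expected = mrcp_epoch - mrcp_epoch[: int(0.4 * FS)].mean()
        # sampling-error bound: 3 sigma / sqrt(n), plus baseline estimate noise
        assert np.abs(ga.waveform - expected).max() < 4 * sigma / np.sqrt(n)

    def test_single_trial(self, rng):
        epoch = rng.standard_normal((1, 1, 600))
        ts = make_trialset(epoch, fs=FS)
        ga = grand_average(ts, "chan_1")
        expected = epoch[0, 0] - epoch[0, 0, : int(0.4 * FS)].mean()
        np.testing.assert_allclose(ga.waveform, expected)
        assert ga.n_trials == 1


class TestBuildTemplate:
    def test_identical_representatives(self, mrcp_epoch):
        epochs = np.repeat(mrcp_epoch[None, None, :], 3, axis=0)
        ts = make_trialset(epochs, fs=FS)
        reps = [grand_average(ts, "chan_1") for _ in range(5)]
        tmpl = build_template(reps)
        zero = int(2.0 * FS)
        np.testing.assert_allclose(
            tmpl.waveform, reps[0].waveform[zero : zero + int(0.5 * FS)]
        )

    def test_length_is_half_second(self, mrcp_epoch):
        wave = mrcp_waveform(MrcpParams(amplitude_uv=10.0), 2000.0)
        epochs = wave[None, None, :]
        ts = make_trialset(epochs, fs=2000.0)
        tmpl = build_template([grand_average(ts, "chan_1")])
        assert tmpl.waveform.size == 1000

    def test_cancelling_representatives_degenerate(self, mrcp_epoch):
        epochs = np.repeat(mrcp_epoch[None, None, :], 2, axis=0)
        ts_pos = make_trialset(epochs, fs=FS)
        ts_neg = make_trialset(-epochs, fs=FS)
        reps = [grand_average(ts_pos, "chan_1"), grand_average(ts_neg, "chan_1")]
        with pytest.raises(DegenerateInputError):
            build_template(reps)

    def test_mixed_rates_rejected(self, mrcp_epoch):
        ga1 = grand_average(make_trialset(mrcp_epoch[None, None, :], fs=FS), "chan_1")
        ga2 = grand_average(make_trialset(mrcp_epoch[None, None, :], fs=FS), "chan_1")
        ga2.fs = 2 * FS
        with pytest.raises(InvalidInputError):
            build_template([ga1, ga2])

    def test_csv_roundtrip(self, tmp_path, mrcp_epoch):
        ts = make_trialset(mrcp_epoch[None, None, :], fs=FS)
        tmpl = build_template([grand_average(ts, "chan_1")])
        tmpl.provenance = [("sub_1", "chan_1")]
        path = tmp_path / "template.csv"
        tmpl.to_csv(path)
        back = MRCPTemplate.from_csv(path)
        np.testing.assert_allclose(back.waveform, tmpl.waveform, atol=1e-9)
        assert back.fs == tmpl.fs
        assert back.provenance == [("sub_1", "chan_1")]


class TestSelectRepresentative:
    def test_finds_embedded_channel(self, rng, mrcp_epoch):
        n_tr, n_ch = 12, 6
        epochs = 0.5 * rng.standard_normal((n_tr, n_ch, mrcp_epoch.size))
        epochs[:, 4, :] += mrcp_epoch
        ts = make_trialset(epochs, fs=FS)
        ch, confident = select_representative(ts)
        assert ch == "chan_5"
        assert confident

    def test_noise_low_confidence_flag(self, rng):
        epochs = 0.01 * rng.standard_normal((5, 3, 600))
        ts = make_trialset(epochs, fs=FS)
        ch, confident = select_representative(ts, amplitude_floor=1.0)
        assert ch in ts.channel_ids
        assert not confident

    def test_tie_goes_to_lower_index(self, mrcp_epoch):
        epochs = np.zeros((2, 3, mrcp_epoch.size))
        epochs[:, 1, :] = mrcp_epoch
        epochs[:, 2, :] = mrcp_epoch  # exact tie with channel 2
        ts = make_trialset(epochs, fs=FS)
        ch, _ = select_representative(ts)
        assert ch == "chan_2"


class TestCorrelationCoefficient:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal(50)
        assert correlation_coefficient(x, x) == pytest.approx(1.0)
        assert correlation_coefficient(x, -x) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        assert correlation_coefficient(3.5 * x + 2.0, x) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # direct evaluation: r((1,2,3),(1,2,4)) = 3 / sqrt(2 * 14/3)
        r = correlation_coefficient([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(3.0 / np.sqrt(2 * 14 / 3), abs=1e-12)
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            correlation_coefficient([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 30))
            assert correlation_coefficient(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12
            )

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30),
        st.floats(0.1, 100.0),
        st.floats(-100.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_affine(self, xs, a, b):
        x = np.asarray(xs)
        y = np.sin(x) + 0.1 * np.arange(len(x))  # deterministic partner
        if np.ptp(x) < 1e-3 or np.ptp(y) < 1e-3:
            return  # avoid spreads near the degeneracy guard
        r = correlation_coefficient(x, y)
        assert -1.0 <= r <= 1.0
        assert correlation_coefficient(a * x + b, y) == pytest.approx(r, abs=1e-6)


class TestTrialCcs:
    def test_task_equals_template(self, mrcp_epoch):
        epochs = np.repeat(mrcp_epoch[None, None, :], 6, axis=0)
        ts = make_trialset(epochs, fs=FS)
        tmpl = template_from(mrcp_epoch)
        q, t, dropped = trial_ccs(ts, "chan_1", tmpl)
        np.testing.assert_allclose(q, 1.0, atol=1e-12)
        assert dropped == 0

    def test_balanced_lengths(self, rng, mrcp_epoch):
        n_tr = 34
        epochs = rng.standard_normal((n_tr, 1, mrcp_epoch.size))
        ts = make_trialset(epochs, fs=FS)
        q, t, _ = trial_ccs(ts, "chan_1", template_from(mrcp_epoch))
        assert q.size == t.size == 34

    def test_white_noise_ccs_zero_mean(self, rng, mrcp_epoch):
        n_tr = 400
        epochs = rng.standard_normal((n_tr, 1, mrcp_epoch.size))
        ts = make_trialset(epochs, fs=FS)
        q, t, _ = trial_ccs(ts, "chan_1", template_from(mrcp_epoch))
        se = q.std(ddof=1) / np.sqrt(n_tr)
        assert abs(q.mean()) < 3 * se + 1e-3
        assert abs(t.mean()) < 3 * t.std(ddof=1) / np.sqrt(n_tr) + 1e-3

    def test_degenerate_trials_dropped_pairwise(self, rng, mrcp_epoch):
        epochs = rng.standard_normal((5, 1, mrcp_epoch.size))
        epochs[2, 0, :] = 3.14  # flat trial: both components degenerate
        ts = make_trialset(epochs, fs=FS)
        q, t, dropped = trial_ccs(ts, "chan_1", template_from(mrcp_epoch))
        assert dropped == 1
        assert q.size == t.size == 4


def pb_oracle(q, t):
    """Squared point-biserial correlation between pooled values and labels."""
    vals = np.concatenate([q, t])
    labels = np.concatenate([np.ones(len(q)), -np.ones(len(t))])
    return stats.pearsonr(vals, labels).statistic ** 2


class TestSignedR2:
    def test_equal_groups_zero(self, rng):
        q = rng.standard_normal(10)
        r2, _ = signed_r2(q, q)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_two_point_extreme(self):
        # direct evaluation: G = 0, numerator = denominator = 4
        r2, g = signed_r2([1.0, 1.0], [-1.0, -1.0])
        assert g == 0.0
        assert r2 == 1.0

    def test_matches_point_biserial_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            q = rng.standard_normal(n)
            t = rng.standard_normal(n) + rng.uniform(-1, 1)
            r2, _ = signed_r2(q, t)
            assert abs(abs(r2) - pb_oracle(q, t)) < 1e-10

    def test_antisymmetric_under_swap(self, rng):
        q, t = rng.standard_normal((2, 15))
        a, _ = signed_r2(q, t)
        b, _ = signed_r2(t, q)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_sign_follows_mean_difference(self, rng):
        q = rng.standard_normal(20) + 2.0
        t = rng.standard_normal(20)
        r2, _ = signed_r2(q, t)
        assert r2 > 0
        r2s, _ = signed_r2(t, q)
        assert r2s < 0

    def test_constant_distinct_groups_saturate(self):
        # two distinct constants: between-group variance is all the variance
        r2, _ = signed_r2([2.0, 2.0], [1.0, 1.0])
        assert r2 == 1.0
        r2, _ = signed_r2([1.0, 1.0], [2.0, 2.0])
        assert r2 == -1.0

    def test_zero_total_variance(self):
        with pytest.raises(DegenerateInputError):
            signed_r2([1.0, 1.0], [1.0, 1.0])


class TestChannelSignificance:
    def test_bonferroni_arithmetic(self, rng):
        # construct q, t with a known raw p, then check the correction rule
        q = np.array([0.5, 0.6, 0.7])
        t = np.array([0.1, 0.2, 0.3])
        p_raw, p_corr, flag = channel_significance(q, t, n_channels=30)
        assert p_corr == pytest.approx(min(1.0, p_raw * 30))
        # the spec's worked arithmetic: 0.0005 * 30 = 0.015 -> not significant
        assert not (0.0005 * 30 < 0.01)

    def test_f_r2_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            q = rng.standard_normal(n)
            t = rng.standard_normal(n) + rng.uniform(-0.5, 0.5)
            r2, _ = signed_r2(q, t)
            f_expected = abs(r2) / (1 - abs(r2)) * (2 * n - 2)
            f_stat = stats.f_oneway(q, t).statistic
            assert f_stat == pytest.approx(f_expected, abs=1e-8 * max(1, f_stat))

    def test_null_calibration_quick(self, rng):
        n_sims, hits = 400, 0
        for _ in range(n_sims):
            q = rng.standard_normal(10)
            t = rng.standard_normal(10)
            p_raw, _, _ = channel_significance(q, t, n_channels=1)
            hits += p_raw < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(hits / n_sims - 0.05) < 3 * se

    def test_too_few_trials(self):
        with pytest.raises(InvalidInputError):
            channel_significance([1.0], [0.0], n_channels=1)


class TestEtamMap:
    def test_recovers_embedded_channels(self, rng, mrcp_epoch):
        n_tr, n_ch = 20, 8
        truth = {1, 4}
        epochs = 10 * rng.standard_normal((n_tr, n_ch, mrcp_epoch.size))
        for c in truth:
            epochs[:, c, :] += mrcp_epoch
        ts = make_trialset(epochs, fs=FS)
        scores = etam_map(ts, template_from(mrcp_epoch))
        flagged = {i for i, s in enumerate(scores) if s.significant}
        assert flagged == truth

    def test_sign_positive_on_mrcp_channels(self, rng, mrcp_epoch):
        epochs = 10 * rng.standard_normal((20, 2, mrcp_epoch.size))
        epochs[:, 0, :] += mrcp_epoch  # negative-going potential
        ts = make_trialset(epochs, fs=FS)
        scores = etam_map(ts, template_from(mrcp_epoch))
        assert scores[0].signed_r2 > 0

    def test_pure_noise_rarely_flagged(self, rng, mrcp_epoch):
        epochs = rng.standard_normal((15, 10, mrcp_epoch.size))
        ts = make_trialset(epochs, fs=FS)
        scores = etam_map(ts, template_from(mrcp_epoch))
        assert sum(s.significant for s in scores) == 0

    def test_matches_per_channel_route(self, rng, mrcp_epoch):
        # the vectorized map must agree with the scalar trial_ccs route
        epochs = rng.standard_normal((10, 4, mrcp_epoch.size))
        epochs[:, 2, :] += 0.5 * mrcp_epoch
        ts = make_trialset(epochs, fs=FS)
        tmpl = template_from(mrcp_epoch)
        scores = etam_map(ts, tmpl)
        for ch, score in zip(ts.channel_ids, scores):
            q, t, _ = trial_ccs(ts, ch, tmpl)
            np.testing.assert_allclose(score.task_cc, q, atol=1e-12)
            np.testing.assert_allclose(score.rest_cc, t, atol=1e-12)


class TestLosoTemplate:
    def make_rep(self, wave, subject):
        ts = make_trialset(wave[None, None, :], fs=FS)
        ga = grand_average(ts, "chan_1")
        ga.subject = subject
        return ga

    def test_holds_out_named_subject(self, mrcp_epoch):
        reps = {f"sub_{i}": self.make_rep((i + 1.0) * mrcp_epoch, f"sub_{i}")
                for i in range(1, 6)}
        tmpl = loso_template(reps, held_out="sub_3")
        included = [1, 2, 4, 5]
        zero = int(2.0 * FS)
        base = mrcp_epoch - mrcp_epoch[: int(0.4 * FS)].mean()
        expected = np.mean([(i + 1.0) * base for i in included], axis=0)
        np.testing.assert_allclose(tmpl.waveform, expected[zero : zero + int(0.5 * FS)])
        assert ("sub_3", "chan_1") not in tmpl.provenance

    def test_identical_subjects_invariant(self, mrcp_epoch):
        reps = {f"s{i}": self.make_rep(mrcp_epoch, f"s{i}") for i in range(3)}
        t1 = loso_template(reps, held_out="s0")
        t2 = loso_template(reps, held_out="s1")
        np.testing.assert_allclose(t1.waveform, t2.waveform)

    def test_two_subjects(self, mrcp_epoch):
        reps = {
            "a": self.make_rep(mrcp_epoch, "a"),
            "b": self.make_rep(2 * mrcp_epoch, "b"),
        }
        tmpl = loso_template(reps, held_out="a")
        zero = int(2.0 * FS)
        base = 2 * (mrcp_epoch - mrcp_epoch[: int(0.4 * FS)].mean())
        np.testing.assert_allclose(tmpl.waveform, base[zero : zero + int(0.5 * FS)])

    def test_single_subject_rejected(self, mrcp_epoch):
        with pytest.raises(InvalidInputError):
            loso_template({"a": self.make_rep(mrcp_epoch, "a")}, held_out="a")
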