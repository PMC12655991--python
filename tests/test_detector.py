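"""Window flagging, majority voting, persistence, and the full detection pipeline."""

import itertools

import numpy as np
import pytest

from szdet.detector import (
    DetectionResult,
    DetectorConfig,
    detect,
    detect_from_features,
    detect_streaming,
    persist,
    vote,
    window_flag,
)
from szdet.exceptions import ConfigurationError, ValidationError
from szdet.features import extract
from szdet.fir import apply as fir_apply

FS = 256.0


def cfg_for(n=8, thr_p=1.0, thr_ll=1.0, k_c=2, **kw):
    return DetectorConfig(thr_p=thr_p, thr_ll=thr_ll, k_c=k_c, window_len_N=n, **kw)


class TestConfig:
    def test_lambda_resolution(self):
        cfg = cfg_for(lambda_frac=0.25)
        assert cfg.resolve_lambda(20) == 5
        assert cfg.resolve_lambda(23) == 6  # ceil(5.75)
        cfg2 = cfg_for(lambda_frac=None, lambda_count=3)
        assert cfg2.resolve_lambda(20) == 3

    def test_exactly_one_lambda_entry_point(self):
        with pytest.raises(ConfigurationError):
            cfg_for(lambda_frac=0.25, lambda_count=5)
        with pytest.raises(ConfigurationError):
            cfg_for(lambda_frac=None, lambda_count=None)

    @pytest.mark.parametrize(
        "kw",
        [
            {"k_c": 0},
            {"k_c": 9},  # exceeds window length 8
            {"lambda_frac": 1.5},
            {"persistence_M": 0},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            cfg_for(**kw)

    def test_yaml_json_round_trip(self, tmp_path):
        cfg = cfg_for(thr_p=123.5, thr_ll=678.0, k_c=4, lambda_frac=0.3)
        for name in ("c.yaml", "c.json"):
            cfg.save(tmp_path / name)
            back = DetectorConfig.load(tmp_path / name)
            assert back.to_dict() == cfg.to_dict()

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectorConfig.from_dict({"thr_p": 1, "thr_ll": 1, "k_c": 1,
                                      "window_len_N": 8, "bogus": 2})


class TestWindowFlag:
    @pytest.mark.parametrize(
        "pd_vals,ll,expect_flag,expect_psec",
        [
            ([5, 5, 0, 0, 0, 0, 0, 0], 0.0, True, 2),    # PSEC path alone
            ([0, 0, 0, 0, 0, 0, 0, 0], 10.0, True, 0),   # LL path alone
            ([0, 0, 0, 0, 0, 0, 0, 0], 0.0, False, 0),   # neither
            ([-5, 5, 0, 0, 0, 0, 0, 0], 0.0, True, 2),   # |PD| is thresholded
            ([1, 1, 0, 0, 0, 0, 0, 0], 0.5, True, 2),    # inclusive >= on both paths
        ],
    )
    def test_or_rule_and_psec_count(self, pd_vals, ll, expect_flag, expect_psec):
        cfg = cfg_for(thr_p=1.0, thr_ll=0.5, k_c=2)
        flag, psec = window_flag(np.array(pd_vals, float), ll, cfg)
        assert flag == expect_flag and psec == expect_psec

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValidationError):
            window_flag(np.zeros(7), 0.0, cfg_for(n=8))


class TestVote:
    def test_brute_force_popcount_enumeration(self):
        for nch in (3, 4, 5):
            for lam in range(1, nch + 1):
                cfg = cfg_for(lambda_frac=None, lambda_count=lam)
                for bits in itertools.product([False, True], repeat=nch):
                    passed, count = vote(np.array(bits), cfg)
                    assert count == sum(bits)
                    assert passed == (sum(bits) >= lam)

    def test_paper_style_20_channel_example(self):
        cfg = cfg_for(lambda_frac=None, lambda_count=5)
        flags = np.zeros(20, bool)
        flags[:5] = True
        assert vote(flags, cfg) == (True, 5)
        assert vote(np.zeros(20, bool), cfg) == (False, 0)

    def test_monotone_in_added_flags(self, rng):
        cfg = cfg_for(lambda_frac=0.4)
        for _ in range(20):
            flags = rng.random(10) < 0.3
            passed, _ = vote(flags, cfg)
            more = flags.copy()
            more[int(rng.integers(10))] = True
            passed_more, _ = vote(more, cfg)
            assert passed_more >= passed


class TestPersist:
    def test_asserts_after_m_consecutive_passes(self):
        cfg = cfg_for(n=256, persistence_M=3)
        asserted, events = persist(np.array([True] * 6), cfg, fs=FS)
        assert list(asserted) == [False, False, True, True, True, True]
        assert len(events) == 1
        assert events[0].assert_window == 2
        assert events[0].assert_time_s == 3.0  # end of the third 1-s window

    def test_broken_runs_never_assert(self):
        cfg = cfg_for(persistence_M=3)
        vp = np.array([True, True, False, True, True, False, True, True, False])
        asserted, events = persist(vp, cfg)
        assert not asserted.any() and events == []

    def test_all_false_no_events(self):
        asserted, events = persist(np.zeros(10, bool), cfg_for())
        assert not asserted.any() and events == []

    def test_release_after_d_failing_windows(self):
        vp = np.array([True, True, True, False, True, True, False, False, False])
        cfg1 = cfg_for(persistence_M=3, release_D=1)
        a1, e1 = persist(vp, cfg1)
        assert e1[0].release_window == 3  # first failing window releases
        cfg2 = cfg_for(persistence_M=3, release_D=2)
        a2, e2 = persist(vp, cfg2)
        # single failing window at 3 survives; run of two at 6-7 releases
        assert list(a2) == [False, False, True, True, True, True, True, False, False]
        assert e2[0].release_window == 7

    def test_reassertion_requires_full_run_again(self):
        vp = np.array([True] * 3 + [False] + [True] * 3)
        asserted, events = persist(vp, cfg_for(persistence_M=3, release_D=1))
        assert len(events) == 2
        assert events[0].release_window == 3
        assert events[1].assert_window == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_each_event_preceded_by_exactly_m_minus_1_passes(self, seed):
        rng = np.random.default_rng(seed)
        vp = rng.random(200) < 0.5
        cfg = cfg_for(persistence_M=3)
        _, events = persist(vp, cfg)
        for e in events:
            w = e.assert_window
            assert w >= 2 and vp[w - 2 : w + 1].all()


class TestDetect:
    def test_vacuous_thresholds_yield_no_events(self, small_recording, filt256):
        cfg = DetectorConfig(thr_p=np.inf, thr_ll=np.inf, k_c=1, window_len_N=256)
        res = detect(small_recording, cfg, filt256)
        assert not res.channel_flags.any() and res.events == []

    def test_zero_thresholds_assert_at_window_m_minus_1(self, small_recording, filt256):
        cfg = DetectorConfig(thr_p=0.0, thr_ll=0.0, k_c=1, window_len_N=256,
                             persistence_M=3)
        res = detect(small_recording, cfg, filt256)
        assert res.channel_flags.all()
        assert res.events[0].assert_window == 2
        assert res.asserted[2:].all() and not res.asserted[:2].any()

    def test_vote_count_conservation(self, small_recording, filt256):
        cfg = DetectorConfig(thr_p=500.0, thr_ll=1500.0, k_c=4, window_len_N=256)
        res = detect(small_recording, cfg, filt256)
        np.testing.assert_array_equal(res.vote_counts, res.channel_flags.sum(axis=0))
        assert res.vote_counts.sum() == res.channel_flags.sum()

    def test_detects_synthetic_seizure_shortly_after_onset(
        self, seizure_recording, filt256
    ):
        rec, ann = seizure_recording
        cfg = DetectorConfig(thr_p=2000.0, thr_ll=3000.0, k_c=16, window_len_N=256)
        res = detect(rec, cfg, filt256)
        assert len(res.events) >= 1
        onset, offset = ann.intervals[0]
        t = res.events[0].assert_time_s
        assert onset <= t <= onset + 3 * 1.0 + 2.0  # persistence delay + recruitment ramp

    def test_threshold_monotonicity(self, seizure_recording, filt256):
        rec, _ = seizure_recording
        filtered = fir_apply(filt256, rec)
        ff = extract(filtered, 256)
        base = DetectorConfig(thr_p=800.0, thr_ll=2000.0, k_c=8, window_len_N=256)
        n_base = detect_from_features(ff, base).asserted.sum()
        for stricter in (
            DetectorConfig(thr_p=1600.0, thr_ll=2000.0, k_c=8, window_len_N=256),
            DetectorConfig(thr_p=800.0, thr_ll=4000.0, k_c=8, window_len_N=256),
            DetectorConfig(thr_p=800.0, thr_ll=2000.0, k_c=16, window_len_N=256),
            DetectorConfig(thr_p=800.0, thr_ll=2000.0, k_c=8, window_len_N=256,
                           lambda_frac=0.5),
        ):
            assert detect_from_features(ff, stricter).asserted.sum() <= n_base

    @pytest.mark.parametrize("chunk", [100, 256, 1000, 4096])
    def test_streaming_equals_batch_bit_exactly(self, seizure_recording, filt256, chunk):
        rec, _ = seizure_recording
        cfg = DetectorConfig(thr_p=1000.0, thr_ll=2500.0, k_c=8, window_len_N=256)
        batch = detect(rec, cfg, filt256)
        stream = detect_streaming(rec, cfg, filt256, chunk_samples=chunk)
        np.testing.assert_array_equal(stream.channel_flags, batch.channel_flags)
        np.testing.assert_array_equal(stream.psec, batch.psec)
        np.testing.assert_array_equal(stream.vote_counts, batch.vote_counts)
        np.testing.assert_array_equal(stream.asserted, batch.asserted)
        assert [e.assert_window for e in stream.events] == [
            e.assert_window for e in batch.events
        ]

    def test_per_channel_threshold_vectors(self, small_recording, filt256):
        scalar = DetectorConfig(thr_p=500.0, thr_ll=1500.0, k_c=4, window_len_N=256)
        vec = DetectorConfig(
            thr_p=np.full(4, 500.0), thr_ll=np.full(4, 1500.0), k_c=4, window_len_N=256
        )
        a = detect(small_recording, scalar, filt256)
        b = detect(small_recording, vec, filt256)
        np.testing.assert_array_equal(a.channel_flags, b.channel_flags)

    def test_result_exports(self, tmp_path, small_recording, filt256):
        import json

        import pandas as pd

        cfg = DetectorConfig(thr_p=0.0, thr_ll=0.0, k_c=1, window_len_N=256)
        res = detect(small_recording, cfg, filt256)
        res.windows_to_csv(tmp_path / "w.csv")
        res.events_to_json(tmp_path / "e.json")
        assert len(pd.read_csv(tmp_path / "w.csv")) == res.n_windows
        doc = json.loads((tmp_path / "e.json").read_text())
        assert doc["fs"] == FS and len(doc["events"]) == len(res.events)

    def test_asserted_samples_expansion(self):
        res = DetectionResult(
            channel_flags=np.zeros((1, 3), bool),
            psec=np.zeros((1, 3), int),
            vote_counts=np.zeros(3, int),
            vote_pass=np.zeros(3, bool),
            asserted=np.array([False, True, False]),
            events=[],
            window_len_N=4,
            fs=4.0,
        )
        np.testing.assert_array_equal(
            res.asserted_samples(14),
            [False] * 4 + [True] * 4 + [False] * 6,
        )
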