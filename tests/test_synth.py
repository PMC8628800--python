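"""Synthetic hypnogram and signal generator."""

import numpy as np
import pytest

from sleepscore.stages import Hypnogram, Stage
from sleepscore.synth import (
    DEFAULT_TRANSITIONS,
    StageParams,
    TransitionConfig,
    read_signals,
    simulate_hypnogram,
    synthesize_signals,
    write_signals,
)


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Independent DFT oracle: total |X_k|^2 over lo <= f_k <= hi."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(spec[(freqs >= lo) & (freqs <= hi)].sum())


class TestSimulateHypnogram:
    def test_empty(self):
        assert len(simulate_hypnogram(0, seed=1)) == 0

    def test_rem_never_follows_wake(self):
        h = simulate_hypnogram(10_000, seed=42)
        codes = h.stages
        pairs = ((codes[:-1] == Stage.WAKE) & (codes[1:] == Stage.REM)).sum()
        assert pairs == 0

    def test_rem_fraction_near_stationary(self):
        # stationary REM fraction of the default chain is 1/21 ~ 0.048
        h = simulate_hypnogram(10_000, seed=42)
        assert 0.02 <= h.fractions()["REM"] <= 0.10

    def test_stationary_is_ten_ten_one(self):
        pi = TransitionConfig().stationary()
        target = np.array([10, 10, 1]) / 21
        assert np.all(np.abs(pi - target) / target < 0.30)

    def test_determinism(self):
        a = simulate_hypnogram(500, seed=7)
        b = simulate_hypnogram(500, seed=7)
        assert np.array_equal(a.stages, b.stages)
        assert not np.array_equal(a.stages, simulate_hypnogram(500, seed=8).stages)

    def test_markov_property_three_sigma(self):
        """Empirical transition frequencies match the chain within 3 SE."""
        h = simulate_hypnogram(100_000, seed=3)
        codes = h.stages
        P = DEFAULT_TRANSITIONS
        for i in range(3):
            mask = codes[:-1] == i
            n = int(mask.sum())
            for j in range(3):
                phat = float((codes[1:][mask] == j).mean())
                se = np.sqrt(P[i, j] * (1 - P[i, j]) / n)
                assert abs(phat - P[i, j]) <= 3 * se + 1e-12, (i, j, phat)

    @pytest.mark.parametrize("bad_row", [0, 1, 2])
    def test_invalid_matrix_names_row(self, bad_row):
        m = DEFAULT_TRANSITIONS.copy()
        m[bad_row, 0] += 0.1
        with pytest.raises(ValueError, match=["WAKE", "NREM", "REM"][bad_row]):
            simulate_hypnogram(10, TransitionConfig(matrix=m), seed=0)

    def test_negative_entry_rejected(self):
        m = DEFAULT_TRANSITIONS.copy()
        m[0, 0] += m[0, 1]
        m[0, 1] = -m[0, 1]
        with pytest.raises(ValueError, match="negative"):
            simulate_hypnogram(10, TransitionConfig(matrix=m), seed=0)


class TestSynthesizeSignals:
    def test_nrem_delta_dominates_theta(self):
        h = Hypnogram(np.full(100, Stage.NREM, dtype=np.int8))
        rec = synthesize_signals(h, seed=1)
        n = rec.samples_per_epoch
        delta = np.mean([band_power(rec.eeg[i*n:(i+1)*n], rec.fs, 1, 4)
                         for i in range(100)])
        theta = np.mean([band_power(rec.eeg[i*n:(i+1)*n], rec.fs, 6, 9)
                         for i in range(100)])
        assert delta > theta

    def test_pure_tone_all_power_at_5hz(self):
        params = StageParams(
            band_weights={Stage.WAKE: (0, 1, 0), Stage.NREM: (2, 1, 0),
                          Stage.REM: (1, 2, 0)},
            noise_level=0.0,
            band_freqs={"delta": (2.0,), "theta": (5.0,), "broadband": (10.0,)},
            freq_jitter_hz=0.0,
        )
        h = Hypnogram(np.full(3, Stage.WAKE, dtype=np.int8))
        rec = synthesize_signals(h, params, seed=2)
        n = rec.samples_per_epoch
        for i in range(3):  # per epoch: constant phase, leakage-free bin
            seg = rec.eeg[i * n:(i + 1) * n]
            total = band_power(seg, rec.fs, 0, rec.fs / 2)
            at5 = band_power(seg, rec.fs, 4.99, 5.01)
            assert at5 / total > 0.999999

    def test_wake_emg_louder_than_nrem(self):
        h = simulate_hypnogram(300, seed=4)
        rec = synthesize_signals(h, seed=4)
        n = rec.samples_per_epoch
        rms = np.array([np.sqrt(np.mean(rec.emg[i*n:(i+1)*n] ** 2))
                        for i in range(len(h))])
        codes = h.stages
        assert rms[codes == Stage.WAKE].mean() > rms[codes == Stage.NREM].mean()

    def test_exact_length_and_determinism(self):
        h = simulate_hypnogram(20, seed=5)
        a = synthesize_signals(h, seed=9)
        b = synthesize_signals(h, seed=9)
        assert len(a.eeg) == 20 * a.samples_per_epoch
        assert np.array_equal(a.eeg, b.eeg) and np.array_equal(a.emg, b.emg)

    def test_epoch_subseeding_survives_slicing(self):
        """Epoch i of a long record equals epoch i synthesized standalone order-independent."""
        h = simulate_hypnogram(10, seed=6)
        rec = synthesize_signals(h, seed=13)
        n = rec.samples_per_epoch
        h2 = Hypnogram(h.stages[:3])  # same first three epochs
        rec2 = synthesize_signals(h2, seed=13)
        assert np.array_equal(rec.eeg[:3 * n], rec2.eeg)

    def test_non_integer_epoch_samples_rejected(self):
        params = StageParams(fs=100.0, epoch_length_s=0.355)
        h = Hypnogram(np.zeros(2, dtype=np.int8), epoch_length_s=0.355)
        with pytest.raises(ValueError, match="integer"):
            synthesize_signals(h, params, seed=0)

    def test_empty_hypnogram_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            synthesize_signals(Hypnogram(np.empty(0, dtype=np.int8)), seed=0)

    def test_invariant_defaults_are_valid(self):
        StageParams().validate()

    def test_bad_params_rejected(self):
        p = StageParams()
        p.band_weights[Stage.NREM] = (1.0, 5.0, 1.0)  # delta < theta
        with pytest.raises(ValueError, match="NREM delta"):
            p.validate()


def test_separability_two_feature_classifier():
    """Delta/theta ratio + EMG RMS separate the stages at >= 95%."""
    from sklearn.tree import DecisionTreeClassifier

    def features(hyp, rec):
        n = rec.samples_per_epoch
        rows = []
        for i in range(len(hyp)):
            eeg = rec.eeg[i*n:(i+1)*n]
            emg = rec.emg[i*n:(i+1)*n]
            d = band_power(eeg, rec.fs, 1, 4)
            t = band_power(eeg, rec.fs, 6, 9)
            rows.append([np.log((d + 1e-9) / (t + 1e-9)),
                         np.sqrt(np.mean(emg ** 2))])
        return np.array(rows)

    h_tr = simulate_hypnogram(1000, seed=21)
    h_te = simulate_hypnogram(1000, seed=22)
    X_tr = features(h_tr, synthesize_signals(h_tr, seed=21))
    X_te = features(h_te, synthesize_signals(h_te, seed=22))
    clf = DecisionTreeClassifier(max_depth=2, random_state=0)
    clf.fit(X_tr, h_tr.stages)
    assert clf.score(X_te, h_te.stages) >= 0.95


def test_signal_csv_roundtrip(tmp_path):
    h = simulate_hypnogram(5, seed=1)
    rec = synthesize_signals(h, seed=1)
    path = write_signals(rec, tmp_path)
    back = read_signals(path)
    assert back.fs == rec.fs and back.n_epochs == rec.n_epochs
    assert np.allclose(back.eeg, rec.eeg, atol=1e-5)
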