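"""Preprocessing, phase-locking, beta-weights, thresholding and the
group comparison."""

import math

import numpy as np
import pytest

from escapenet.eeg_network import (
    BandSpec,
    DEFAULT_BANDS,
    EEGRecord,
    MAUDSLEY_CHANNELS,
    band_decompose,
    beta_weights,
    compare_group_rates,
    load_record,
    plf,
    plf_matrix,
    preprocess,
    save_record,
    threshold_to_mean_degree,
)

FS = 256.0


def sine(freq: float, duration: float = 4.0, fs: float = FS, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * math.pi * freq * t + phase)


def band_power(x: np.ndarray, freq: float, fs: float = FS) -> float:
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    sel = np.abs(f - freq) < 0.5
    return float(spec[sel].sum())


class TestPreprocess:
    def test_constant_signals_removed_by_average_reference(self):
        rec = EEGRecord(np.full((4, 1024), 7.5), FS, ["a", "b", "c", "d"])
        out = preprocess(rec, exclude=())
        assert np.allclose(out.signals, 0.0, atol=1e-9)

    def test_notch_attenuates_mains_by_30db(self, rng):
        # common-mode average referencing would remove identical channels;
        # give the mains different amplitudes per channel
        base = sine(50.0, duration=8.0)
        sig = np.vstack([2.0 * base, 0.5 * base + 0.01 * rng.standard_normal(base.size)])
        rec = EEGRecord(sig, FS, ["x", "y"])
        out = preprocess(rec, exclude=())
        before = band_power(sig[0], 50.0)
        after = band_power(out.signals[0], 50.0)
        assert 10 * math.log10(before / after) >= 30

    def test_montage_exclusion_gives_19_channels(self, rng):
        sig = rng.standard_normal((21, 2048))
        rec = EEGRecord(sig, FS, list(MAUDSLEY_CHANNELS))
        out = preprocess(rec)
        assert out.n_channels == 19
        assert "A1" not in out.channel_labels and "A2" not in out.channel_labels

    def test_band_edges_must_fit_sample_rate(self, rng):
        rec = EEGRecord(rng.standard_normal((2, 1024)), 100.0, ["x", "y"])
        with pytest.raises(ValueError):
            preprocess(rec, exclude=(), band=(0.5, 70.0))  # 70 > Nyquist(100)


class TestBandDecompose:
    def test_alpha_sine_lands_in_alpha_band(self, rng):
        x = sine(10.0, duration=8.0)
        sig = np.vstack([x, 0.3 * rng.standard_normal(x.size)])
        rec = EEGRecord(sig, FS, ["x", "y"])
        out = band_decompose(rec)
        in_alpha = band_power(out["alpha"].signals[0], 10.0)
        in_delta = band_power(out["delta"].signals[0], 10.0)
        assert 10 * math.log10(in_alpha / in_delta) >= 20

    def test_white_noise_band_variances_follow_bandwidth(self, rng):
        """Parseval: variance in each band scales with the band's width."""
        rec = EEGRecord(rng.standard_normal((1, 60 * int(FS))), FS, ["x"])
        out = band_decompose(rec)
        var = {name: out[name].signals.var() for name in out}
        widths = {b.name: b.high - b.low for b in DEFAULT_BANDS}
        for name in ("theta", "alpha", "beta", "gamma"):
            ratio = var[name] / var["delta"]
            expected = widths[name] / widths["delta"]
            assert ratio == pytest.approx(expected, rel=0.25)

    def test_empty_band_list(self, rng):
        rec = EEGRecord(rng.standard_normal((1, 1024)), FS, ["x"])
        assert band_decompose(rec, []) == {}


class TestPLF:
    def test_identical_signals_fully_locked(self, rng):
        x = sine(10.0) + 0.1 * rng.standard_normal(1024)
        assert plf(x, x) == pytest.approx(1.0)

    def test_constant_phase_shift_fully_locked(self):
        x = sine(10.0)
        y = sine(10.0, phase=1.1)
        assert plf(x, y) == pytest.approx(1.0, abs=1e-3)

    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal(5120)
        y = rng.standard_normal(5120)
        assert plf(x, y) < 0.05

    def test_amplitude_invariance(self, rng):
        x = sine(9.0) + 0.2 * rng.standard_normal(1024)
        y = sine(9.0, phase=0.4) + 0.2 * rng.standard_normal(1024)
        assert plf(3.7 * x, 0.01 * y) == pytest.approx(plf(x, y), rel=1e-9)

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            plf(np.zeros(32), np.zeros(32))
        with pytest.raises(ValueError):
            plf(np.zeros(128), np.zeros(256))


class TestPLFMatrix:
    def make_record(self, rng, n=4, duration=8.0):
        sig = rng.standard_normal((n, int(duration * FS)))
        return EEGRecord(sig, FS, [f"c{i}" for i in range(n)])

    def test_symmetric_unit_diagonal_in_range(self, rng):
        p = plf_matrix(self.make_record(rng))
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)
        assert np.all((p >= 0) & (p <= 1))

    def test_duplicated_channel_fully_locked(self, rng):
        rec = self.make_record(rng, n=3)
        sig = np.vstack([rec.signals, rec.signals[1]])
        p = plf_matrix(EEGRecord(sig, FS, ["a", "b", "c", "b2"]))
        assert p[1, 3] == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        rec = self.make_record(rng)
        p = plf_matrix(rec)
        perm = [2, 0, 3, 1]
        rec_p = EEGRecord(rec.signals[perm], FS, [rec.channel_labels[i] for i in perm])
        assert np.allclose(plf_matrix(rec_p), p[np.ix_(perm, perm)])


class TestBetaWeights:
    def test_identity_gives_zeros(self):
        assert np.allclose(beta_weights(np.eye(5)), 0.0)

    def test_two_by_two_closed_form(self):
        rho = 0.6
        w = beta_weights(np.array([[1.0, rho], [rho, 1.0]]))
        assert w[0, 1] == pytest.approx(rho, rel=1e-4)
        assert w[1, 0] == pytest.approx(rho, rel=1e-4)

    def test_zero_diagonal_finite(self, rng):
        a = rng.standard_normal((6, 8))
        p = np.corrcoef(a)
        w = beta_weights(p)
        assert np.all(np.diag(w) == 0)
        assert np.all(np.isfinite(w))

    def test_singular_raises_with_condition_report(self):
        p = np.ones((4, 4))  # rank one
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            beta_weights(p, ridge=1e-16)

    def test_requires_symmetric(self):
        with pytest.raises(ValueError):
            beta_weights(np.array([[1.0, 0.2], [0.4, 1.0]]))


class TestThreshold:
    def test_d10_on_19_channels_gives_190_edges(self, rng):
        w = rng.standard_normal((19, 19))
        np.fill_diagonal(w, 0)
        assert threshold_to_mean_degree(w, 10).n_edges == 190

    def test_full_degree_gives_complete_digraph(self, rng):
        n = 6
        w = rng.standard_normal((n, n))
        g = threshold_to_mean_degree(w, n - 1)
        assert g.n_edges == n * (n - 1)

    @pytest.mark.parametrize("d", [1, 3, 7, 11, 14, 18])
    def test_edge_count_exact_for_all_degrees(self, rng, d):
        w = rng.standard_normal((19, 19))
        assert threshold_to_mean_degree(w, d).n_edges == round(d * 19)

    def test_tie_breaking_deterministic(self):
        w = np.ones((5, 5))
        g1 = threshold_to_mean_degree(w, 2)
        g2 = threshold_to_mean_degree(w, 2)
        assert g1.edges == g2.edges
        # row-major order among equal magnitudes
        assert (0, 1) in g1.edges

    def test_largest_magnitudes_retained(self):
        w = np.zeros((3, 3))
        w[0, 1], w[1, 2], w[2, 0] = 5.0, -4.0, 3.0
        w[0, 2] = 0.5
        g = threshold_to_mean_degree(w, 1)
        assert g.edges == {(0, 1), (1, 2), (2, 0)}

    def test_degree_bounds(self, rng):
        w = rng.standard_normal((4, 4))
        with pytest.raises(ValueError):
            threshold_to_mean_degree(w, 0)
        with pytest.raises(ValueError):
            threshold_to_mean_degree(w, 4)


class TestGroupComparison:
    def test_identical_groups_p_half(self):
        z, p = compare_group_rates([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 0.5

    def test_complete_separation_significant(self, rng):
        b = rng.normal(10, 1, size=20)
        a = b + 50.0
        _, p = compare_group_rates(list(a), list(b))
        assert p < 0.01

    def test_direction_is_one_sided(self, rng):
        lo = list(rng.normal(0, 1, size=15))
        hi = list(rng.normal(5, 1, size=15))
        _, p_correct = compare_group_rates(hi, lo)
        _, p_wrong = compare_group_rates(lo, hi)
        assert p_correct < 0.01
        assert p_wrong > 0.95

    def test_normal_approximation_close_to_permutation_oracle(self, rng):
        """Exact permutation p-value vs the normal approximation at
        n = 10 per group, within 0.02."""
        a = rng.normal(0.6, 1.0, size=10)
        b = rng.normal(0.0, 1.0, size=10)
        _, p_normal = compare_group_rates(list(a), list(b))

        combined = np.concatenate([a, b])
        from scipy.stats import rankdata

        obs = rankdata(combined)[:10].sum()
        perm_rng = np.random.default_rng(0)
        count = 0
        n_perm = 40000
        for _ in range(n_perm):
            perm = perm_rng.permutation(20)
            if rankdata(combined)[perm[:10]].sum() >= obs:
                count += 1
        p_perm = count / n_perm
        assert abs(p_normal - p_perm) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_group_rates([], [1.0])


def test_record_roundtrip(tmp_path, rng):
    rec = EEGRecord(rng.standard_normal((3, 512)), 128.0, ["a", "b", "c"])
    path = tmp_path / "rec.txt"
    save_record(rec, path)
    back = load_record(path)
    assert np.allclose(back.signals, rec.signals)
    assert back.sample_rate == 128.0
    assert back.channel_labels == ["a", "b", "c"]
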