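import numpy as np
import pandas as pd
import pytest

from oracles import parametric_block_gc, var_transfer_and_spectrum
from respsense import connectivity as conn
from respsense.epochs import RoiEpochs
from respsense.synth import CouplingSpec, gen_roi_timeseries

FS = 300.0


def _csd_from_spectrum(S, freqs):
    return conn.CrossSpectralDensity(S=S, freqs=freqs, fs=FS, n_trials=1,
                                     n_tapers=1)


def _random_stable_var(rng, n=3, order=2):
    while True:
        A_list = [rng.uniform(-0.4, 0.4, (n, n)) * 0.5 for _ in range(order)]
        top = np.hstack(A_list)
        comp = np.vstack([top, np.hstack([np.eye(n * (order - 1)),
                                          np.zeros((n * (order - 1), n))])])
        if np.max(np.abs(np.linalg.eigvals(comp))) < 0.9:
            return A_list


class TestRoiBlockComponents:
    def test_subspace_recovery(self):
        rng = np.random.default_rng(0)
        t = np.arange(500) / FS
        basis = np.stack([np.sin(2 * np.pi * f * t) for f in (5, 11, 17)])
        mix = rng.standard_normal((6, 3))
        data = np.repeat((mix @ basis)[None], 4, axis=0)
        comp = conn.roi_block_components(data, 3)
        # components span the same 3-d subspace as the generators
        flat_c = comp.transpose(1, 0, 2).reshape(3, -1)
        flat_b = np.tile(basis, (1, 4))
        flat_b = flat_b - flat_b.mean(axis=1, keepdims=True)  # components are centred
        rank = np.linalg.matrix_rank(np.vstack([flat_c, flat_b]), tol=1e-6)
        assert rank == 3

    def test_variances_non_increasing(self):
        rng = np.random.default_rng(1)
        comp = conn.roi_block_components(rng.standard_normal((10, 5, 200)), 3)
        v = comp.var(axis=(0, 2))
        assert np.all(np.diff(v) <= 1e-12)

    def test_duplicated_channel_adds_nothing(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, 2, 300))
        dup = np.concatenate([x, x[:, :1]], axis=1)
        with pytest.warns(UserWarning, match="rank"):
            comp = conn.roi_block_components(dup, 3)
        assert comp.shape[1] == 2


class TestCsdMultitaper:
    def test_identical_channels_fully_coherent(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 1, 480))
        data = np.concatenate([x, x], axis=1)
        csd = conn.csd_multitaper(data, FS)
        coh = conn.coherence(csd)
        np.testing.assert_allclose(coh[1:-1, 0, 1], 1.0, atol=1e-10)

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((60, 2, 480))
        csd = conn.csd_multitaper(data, FS)
        coh = conn.coherence(csd)
        bound = 4.0 / np.sqrt(60 * csd.n_tapers)
        assert np.median(np.abs(coh[:, 0, 1])) < bound

    def test_matches_analytic_var_spectrum(self):
        rng = np.random.default_rng(5)
        a1, a2 = 0.5, -0.3
        n_tr, n_t = 300, 960
        eps = rng.standard_normal((n_tr, n_t + 200))
        x = np.zeros_like(eps)
        for t in range(2, eps.shape[1]):
            x[:, t] = a1 * x[:, t - 1] + a2 * x[:, t - 2] + eps[:, t]
        data = x[:, 200:][:, None, :]
        csd = conn.csd_multitaper(data, FS, smoothing_hz=2.0)
        _, S_true = var_transfer_and_spectrum(
            [np.array([[a1]]), np.array([[a2]])], np.eye(1), csd.freqs, FS)
        est = np.real(csd.S[:, 0, 0]) * FS
        truth = np.real(S_true[:, 0, 0])
        band = (csd.freqs > 5) & (csd.freqs < 120)
        ratio = est[band] / truth[band]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)


class TestWilsonFactorize:
    def test_identity_spectrum(self):
        freqs = np.fft.rfftfreq(128, 1 / FS)
        S = np.tile(np.eye(3)[None], (freqs.size, 1, 1)).astype(complex)
        H, Sigma = conn.wilson_factorize(_csd_from_spectrum(S, freqs))
        np.testing.assert_allclose(H, np.tile(np.eye(3), (freqs.size, 1, 1)),
                                   atol=1e-7)
        np.testing.assert_allclose(Sigma, np.eye(3), atol=1e-7)

    def test_var_innovation_recovery(self):
        rng = np.random.default_rng(6)
        A_list = _random_stable_var(rng, n=3)
        Sigma_true = np.diag([1.0, 0.5, 2.0])
        freqs = np.fft.rfftfreq(512, 1 / FS)
        _, S = var_transfer_and_spectrum(A_list, Sigma_true, freqs, FS)
        H, Sigma = conn.wilson_factorize(_csd_from_spectrum(S, freqs),
                                         max_iter=200, diag_load=0.0)
        assert np.max(np.abs(Sigma - Sigma_true)) / np.max(Sigma_true) < 0.05

    def test_reconstruction_residual_on_random_var_spectra(self):
        rng = np.random.default_rng(7)
        freqs = np.fft.rfftfreq(256, 1 / FS)
        for _ in range(3):
            A_list = _random_stable_var(rng, n=2)
            L = rng.standard_normal((2, 2)) * 0.3 + np.eye(2)
            Sigma_true = L @ L.T
            _, S = var_transfer_and_spectrum(A_list, Sigma_true, freqs, FS)
            H, Sigma = conn.wilson_factorize(_csd_from_spectrum(S, freqs),
                                             max_iter=200, diag_load=0.0)
            recon = H @ Sigma[None] @ np.conj(H.transpose(0, 2, 1))
            resid = np.max(np.abs(recon - S)) / np.max(np.abs(S))
            assert resid < 1e-6


class TestBlockGc:
    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((80, 6, 480))
        csd = conn.csd_multitaper(data, FS)
        H, Sigma = conn.wilson_factorize(csd)
        gc = conn.block_gc(csd, H, Sigma, [0, 1, 2], [3, 4, 5])
        bound = 6 * 3 / (80 * csd.n_tapers)  # rough sampling-error scale
        assert np.median(gc.f_ab) < bound
        assert np.median(gc.f_ba) < bound

    def test_directional_var_matches_parametric_oracle(self):
        freqs = np.fft.rfftfreq(256, 1 / FS)
        w = 2 * np.pi * 20 / FS
        ar1, ar2 = 2 * 0.9 * np.cos(w), -0.81
        A1 = np.array([[ar1, 0.0], [0.5, ar1]])
        A2 = np.array([[ar2, 0.0], [0.0, ar2]])
        Sigma_true = np.eye(2)
        _, S = var_transfer_and_spectrum([A1, A2], Sigma_true, freqs, FS)
        H, Sigma = conn.wilson_factorize(_csd_from_spectrum(S, freqs),
                                         max_iter=200, diag_load=0.0)
        gc = conn.block_gc(_csd_from_spectrum(S, freqs), H, Sigma, [0], [1])
        oracle = parametric_block_gc([A1, A2], Sigma_true, [0], [1], freqs, FS)
        pk = np.argmax(oracle)
        assert gc.f_ab[pk] == pytest.approx(oracle[pk], rel=0.10)
        assert gc.f_ba.max() < 0.01 * gc.f_ab[pk]


class TestDai:
    def test_identities(self):
        gc = conn.GCSpectra(freqs=np.arange(3.0),
                            f_ab=np.array([0.3, 0.2, 1.0]),
                            f_ba=np.array([0.1, 0.2, 0.0]))
        out = conn.dai(gc)
        np.testing.assert_allclose(out, [0.5, 0.0, 1.0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        f = np.arange(50.0)
        d1 = conn.dai(conn.GCSpectra(f, a, b))
        d2 = conn.dai(conn.GCSpectra(f, b, a))
        np.testing.assert_allclose(d1, -d2, atol=1e-12)
        assert np.nanmax(np.abs(d1)) <= 1.0

    def test_zero_denominator_is_missing(self):
        gc = conn.GCSpectra(freqs=np.arange(2.0),
                            f_ab=np.array([0.0, 0.5]),
                            f_ba=np.array([0.0, 0.5]))
        out = conn.dai(gc)
        assert np.isnan(out[0]) and out[1] == 0.0


@pytest.fixture(scope="module")
def coupled_session():
    rng = np.random.default_rng(10)
    n = 480
    sched = pd.DataFrame({"trial": np.arange(n)})
    phases = rng.uniform(-np.pi, np.pi, n)
    coup = CouplingSpec(roi_a="INS", roi_b="TPJ", direction="a->b",
                        f0=20.0, gain_phase=0.0)
    ep, truth = gen_roi_timeseries(sched, phases, coupling=coup,
                                   rois=("INS", "TPJ"), seed=11)
    return ep, phases, coup


class TestPhaseResolvedGc:
    def test_modulated_direction_recovered(self, coupled_session):
        ep, phases, coup = coupled_session
        prgc = conn.phase_resolved_gc(ep, phases, "INS", "TPJ", min_trials=10)
        freqs, mods, dai_mod = conn.gc_phase_regression(prgc)
        band = (freqs >= 15) & (freqs <= 25)
        assert np.nanmean(dai_mod[band]) > 0.5
        # modulation profile follows gain(theta) = 1 + cos(theta)
        i_pk = np.nanargmax(np.where(band, mods[:, 0], -np.inf))
        ok = np.isfinite(prgc.gc_ab[i_pk])
        r = np.corrcoef(prgc.gc_ab[i_pk, ok], np.cos(prgc.bin_centres[ok]))[0, 1]
        assert r > 0.7

    def test_direction_swap_flips_dai(self, coupled_session):
        ep, phases, _ = coupled_session
        prgc = conn.phase_resolved_gc(ep, phases, "INS", "TPJ", min_trials=10)
        swapped = conn.phase_resolved_gc(ep, phases, "TPJ", "INS", min_trials=10)
        _, _, d1 = conn.gc_phase_regression(prgc)
        _, _, d2 = conn.gc_phase_regression(swapped)
        np.testing.assert_allclose(d1, -d2, atol=0.02)

    def test_undersized_bins_skipped(self, coupled_session):
        ep, phases, _ = coupled_session
        prgc = conn.phase_resolved_gc(ep, phases, "INS", "TPJ", min_trials=17)
        skipped = prgc.n_per_bin < 17
        assert skipped.any()
        assert np.all(np.isnan(prgc.gc_ab[:, skipped]))
        assert np.all(np.isfinite(prgc.gc_ab[:, ~skipped]))

    def test_phase_count_mismatch(self, coupled_session):
        ep, phases, _ = coupled_session
        with pytest.raises(ValueError):
            conn.phase_resolved_gc(ep, phases[:-1], "INS", "TPJ")


class TestGcPhaseRegression:
    def test_constant_gc_no_modulation(self):
        freqs = np.linspace(0, 40, 20)
        centres = np.linspace(-np.pi, np.pi, 30, endpoint=False)
        prgc = conn.PhaseResolvedGC(
            freqs=freqs, bin_centres=centres,
            gc_ab=np.full((20, 30), 0.7), gc_ba=np.full((20, 30), 0.3),
            n_per_bin=np.full(30, 20))
        _, mods, _ = conn.gc_phase_regression(prgc)
        np.testing.assert_allclose(mods, 0.0, atol=1e-12)
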