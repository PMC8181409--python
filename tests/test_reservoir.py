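"""Error-driven Fourier-decomposition reservoir."""

import logging

import numpy as np
import pytest

from hopfnet import (LearningConfig, SpectrumSpec, TeachingSignal,
                     TrainedReservoir, gen_multisine, regenerate,
                     spectrum_report, train_reservoir)

logging.getLogger("hopfnet").setLevel(logging.ERROR)

TRIPLE = [(2.0, 4.0, np.pi / 2), (1.5, 8.0, np.pi / 5), (1.8, 12.0, np.pi / 12)]
FAST = LearningConfig(tau_w=1e4, eta_omega=0.1, eta_alpha=3e-3)


def _train(sig, N=3, mode="real", **kw):
    kw.setdefault("learning", FAST)
    kw.setdefault("omega_init", (4.0, 9.0, 14.0)[:N])
    kw.setdefault("A_lateral", 0.0)
    kw.setdefault("eps", 0.5)
    kw.setdefault("duration", 6000.0)
    kw.setdefault("theta_consolidation", 0.0)
    return train_reservoir(sig, N, mode=mode, **kw)


class TestTrainingBasics:
    def test_zero_signal_leaves_alphas_at_zero(self):
        sig = TeachingSignal(samples=np.zeros(2000), dt=1e-3)
        trained, traj = train_reservoir(sig, 2, learning=FAST, mode="real",
                                        omega_init=(4.0, 9.0), A_lateral=0.0,
                                        epochs=2, theta_consolidation=0.0)
        assert np.all(trained.alphas == 0.0)
        assert np.max(np.abs(traj.error)) < 1e-9

    def test_complex_mode_rejects_nothing_real_requires_real(self):
        sig = gen_multisine(SpectrumSpec(components=TRIPLE), 2.0, 1e-3,
                            domain="complex")
        with pytest.raises(ValueError):
            train_reservoir(sig, 3, mode="real")

    def test_epoch_error_non_increasing_after_first(self):
        comps = [(1.2, 4.0, np.pi / 3), (0.8, 8.78, np.pi / 7),
                 (1.0, 12.35, np.pi / 5)]
        sig = gen_multisine(SpectrumSpec(components=comps), 20.0, 1e-3)
        learning = LearningConfig(tau_w=1e4, eta_omega=0.1, eta_alpha=1e-4)
        _, traj = train_reservoir(sig, 3, learning=learning, mode="real",
                                  epochs=6, omega_init=(5.0, 9.0, 13.0),
                                  A_lateral=0.1, eps=0.5)
        e = traj.epoch_error
        assert all(e[k + 1] <= e[k] * 1.05 for k in range(1, len(e) - 1))


class TestParameterRecovery:
    def test_randomized_three_component_recovery(self):
        """Over-complete reservoir (N=5) recovers frequencies and amplitudes
        of random three-component signals; recovered amplitude of a line is
        the summed readout weight of the oscillators locking it."""
        rng = np.random.default_rng(42)
        ok = 0
        for _ in range(20):
            while True:
                w = np.sort(rng.uniform(3.0, 15.0, 3))
                if np.all(np.diff(w) >= 2.0):
                    break
            a = rng.uniform(0.5, 2.5, 3)
            ph = rng.uniform(0.0, 2 * np.pi, 3)
            sig = gen_multisine(SpectrumSpec(components=list(zip(a, w, ph))),
                                20.0, 1e-3)
            trained, _ = _train(sig, N=5,
                                omega_init=(3.0, 6.0, 9.0, 12.0, 15.0))
            good = True
            for wt, at in zip(w, a):
                sel = np.abs(trained.omegas - wt) < 0.1
                if not np.any(sel) or abs(trained.alphas[sel].sum() - at) > 0.1:
                    good = False
            ok += good
        assert ok >= 18

    def test_real_and_complex_modes_agree(self):
        comps = [(2.0, 4.0, np.pi / 2), (1.5, 8.7, np.pi / 5),
                 (1.8, 12.4, np.pi / 12)]
        res = {}
        for mode in ("real", "complex"):
            sig = gen_multisine(SpectrumSpec(components=comps), 20.0, 1e-3,
                                domain="complex" if mode == "complex" else "real")
            trained, _ = _train(sig, mode=mode)
            order = np.argsort(trained.omegas)
            res[mode] = (trained.omegas[order], trained.alphas[order])
        assert np.allclose(res["real"][0], res["complex"][0], atol=0.05)
        assert np.allclose(res["real"][1], res["complex"][1], atol=0.05)


class TestRegenerate:
    def test_zero_alphas_give_zero_output(self):
        trained = TrainedReservoir(omegas=np.array([4.0, 8.0]),
                                   alphas=np.zeros(2),
                                   A=np.zeros((2, 2)), theta=np.zeros((2, 2)))
        _, P = regenerate(trained, duration=1.0)
        assert np.all(P == 0.0)

    def test_single_oscillator_closed_form(self):
        a, w0 = 1.3, 6.0
        trained = TrainedReservoir(omegas=np.array([w0]),
                                   alphas=np.array([a]),
                                   A=np.zeros((1, 1)), theta=np.zeros((1, 1)))
        t, P = regenerate(trained, duration=5.0)
        assert np.max(np.abs(P - a * np.cos(w0 * t))) < 1e-2


class TestSpectrumReport:
    def test_sorted_rows_and_offsets(self):
        trained = TrainedReservoir(omegas=np.array([12.0, 4.0, 8.0]),
                                   alphas=np.array([1.8, 2.0, 1.5]),
                                   A=np.full((3, 3), 0.1),
                                   theta=np.zeros((3, 3)))
        df = spectrum_report(trained)
        assert df["omega"].tolist() == [4.0, 8.0, 12.0]
        assert df["alpha"].tolist() == [2.0, 1.5, 1.8]
        assert not df.attrs["degenerate"]

    def test_single_oscillator_report(self):
        trained = TrainedReservoir(omegas=np.array([4.0]),
                                   alphas=np.array([2.0]),
                                   A=np.zeros((1, 1)), theta=np.zeros((1, 1)))
        df = spectrum_report(trained)
        assert len(df) == 1
        assert df.attrs["normalized_offsets"] == {}

    def test_degenerate_frequencies_flagged(self):
        trained = TrainedReservoir(omegas=np.array([4.0, 4.05]),
                                   alphas=np.array([1.0, 1.0]),
                                   A=np.zeros((2, 2)), theta=np.zeros((2, 2)))
        df = spectrum_report(trained)
        assert df.attrs["degenerate"] == [(4.0, 4.05)]


class TestFullTripleTone:
    """Assertions on the shared full-length decomposition runs."""

    def test_real_mode_recovery(self, fig11_report):
        assert np.allclose(fig11_report["omegas"], [4.0, 8.0, 12.0], atol=0.05)
        assert np.allclose(fig11_report["alphas"], [2.0, 1.5, 1.8], atol=0.05)

    def test_real_mode_theta_relation(self, fig11_report):
        errs = list(fig11_report["theta_identity_errors"].values())
        assert max(errs) < 0.1

    def test_real_mode_regeneration(self, fig11_report):
        assert fig11_report["regeneration_rel_mse"] < 0.05

    def test_complex_mode_recovery(self, fig12_report):
        assert np.allclose(fig12_report["omegas"], [4.0, 8.0, 12.0], atol=0.05)
        assert np.allclose(fig12_report["alphas"], [2.0, 1.5, 1.8], atol=0.05)
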