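"""Adversarial transfer: multilinear map, loss terms, gradient reversal."""

import numpy as np
import pytest

import mhc2learn as m
from mhc2learn import nn
from mhc2learn.cdan import multilinear_map, cdan_losses, CdanConfig


class TestMultilinearMap:
    def test_small_outer_product(self):
        h = multilinear_map(np.array([[1.0, 0.0]]),
                            np.array([[0.5, 0.5]]), max_dim=16)
        assert np.allclose(h.data, [[0.5, 0.5, 0.0, 0.0]])

    def test_zero_features_give_zero_map(self):
        h = multilinear_map(np.zeros((3, 4)),
                            np.full((3, 2), 0.5), max_dim=16)
        assert (h.data == 0).all()

    def test_randomized_projection_width_and_determinism(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((2, 64))
        g = rng.dirichlet(np.ones(32), size=2)
        h1 = multilinear_map(f, g, max_dim=1024, seed=3)
        h2 = multilinear_map(f, g, max_dim=1024, seed=3)
        assert h1.shape == (2, 1024)
        assert np.array_equal(h1.data, h2.data)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            multilinear_map(np.ones((1, 2)), np.array([[0.9, 0.3]]),
                            max_dim=16)


class TestCdanLosses:
    def _setup(self, seed=0):
        cfg = m.SimConfig.separable(n_pos=40, n_neg=40,
                                    domain_shift_strength=0.6, seed=seed)
        antigenic, immunogenic, _ = m.simulate_dataset(cfg)
        el_cfg = m.ElConfig(epochs=1, d_model=24, lr=3e-3, seed=seed)
        el = m.ElPresentationModel(antigenic, antigenic.alleles,
                                   el_cfg).fit()
        transfer = m.CdanTransfer(el, antigenic, immunogenic,
                                  CdanConfig(seed=seed, epochs=1))
        return transfer

    def test_indifferent_discriminator_loss_is_ln2(self):
        """Force D to output 0.5 for every input: the domain
        cross-entropy must equal ln 2 exactly."""
        t = self._setup()
        res = t.fit(adversarial=False)  # cheap: epochs overridden below
        # zero out the discriminator's final layer -> sigmoid(0) = 0.5
        final = res.D.mlp.fcs[-1]
        final.w.data[:] = 0.0
        final.b.data[:] = 0.0
        _, _, L_adv = cdan_losses(
            res.F, res.G, res.D,
            t._pep_a[:8], t._hla_a[:8], t._y_a[:8],
            t._pep_i[:8], t._hla_i[:8], t._y_i[:8], t.config)
        assert float(L_adv.data) == pytest.approx(np.log(2), abs=1e-9)

    def test_single_domain_batch_rejected(self):
        t = self._setup()
        res = t.fit(adversarial=False)
        with pytest.raises(ValueError):
            cdan_losses(res.F, res.G, res.D,
                        t._pep_a[:4], t._hla_a[:4], t._y_a[:4],
                        t._pep_i[:0], t._hla_i[:0], t._y_i[:0], t.config)

    def test_omega_zero_equals_plain_fine_tuning(self):
        """With omega=0 the feature extractor receives no adversarial
        gradient: training must match a run without the coupling."""
        t1 = self._setup(seed=1)
        t1.config = CdanConfig(seed=1, epochs=2, omega=1.0)
        r_adv_off = t1.fit(adversarial=False)     # omega forced to 0
        t2 = self._setup(seed=1)
        t2.config = CdanConfig(seed=1, epochs=2, omega=0.0)
        r_omega0 = t2.fit(adversarial=True)
        for a, b in zip(r_adv_off.F.state_arrays(),
                        r_omega0.F.state_arrays()):
            assert np.allclose(a, b)

    def test_divergence_aborts_with_diagnostics(self):
        t = self._setup(seed=2)
        t.config = CdanConfig(seed=2, epochs=1, lr=1e-2)
        res = t.fit()
        # poison the decoder to force NaN on the next run
        t.config = CdanConfig(seed=2, epochs=1)
        t._pep_a[:] = np.nan
        with pytest.raises(RuntimeError, match="divergence"):
            t.fit()


class TestGradientReversal:
    def test_identity_forward(self):
        x = nn.Tensor(np.array([[1.0, -2.0]]), requires_grad=True)
        y = nn.grad_reverse(x, 0.7)
        assert np.array_equal(y.data, x.data)

    def test_reversed_gradient_matches_finite_differences(self):
        """Two-parameter toy: feature w, discriminator v.  The gradient
        reaching w through the reversal layer must equal -omega times
        the finite-difference derivative of the adversarial loss."""
        omega = 0.8
        x = np.array([1.3, -0.4, 2.1])
        dom = np.array([1.0, 0.0, 1.0])

        def adv_loss(wv, vv, reverse):
            w = nn.Tensor(np.array(wv), requires_grad=True)
            v = nn.Tensor(np.array(vv), requires_grad=True)
            f = nn.Tensor(x) * w
            if reverse:
                f = nn.grad_reverse(f, omega)
            p = (f * v).sigmoid()
            return w, v, nn.binary_cross_entropy(p, dom)

        w0, v0 = 0.6, -1.1
        w, v, loss = adv_loss(w0, v0, reverse=True)
        loss.backward()
        grad_w_reversed = float(w.grad.sum())
        eps = 1e-6
        _, _, lp = adv_loss(w0 + eps, v0, reverse=False)
        _, _, lm = adv_loss(w0 - eps, v0, reverse=False)
        fd = (float(lp.data) - float(lm.data)) / (2 * eps)
        assert grad_w_reversed == pytest.approx(-omega * fd, abs=1e-6)
        # the discriminator's own gradient is NOT reversed
        w2, v2, loss2 = adv_loss(w0, v0, reverse=True)
        loss2.backward()
        _, vp, lp = adv_loss(w0, v0 + eps, reverse=False)
        _, vm, lm = adv_loss(w0, v0 - eps, reverse=False)
        fd_v = (float(lp.data) - float(lm.data)) / (2 * eps)
        assert float(v2.grad.sum()) == pytest.approx(fd_v, abs=1e-6)


class TestTransferBehaviour:
    def test_identical_domains_leave_discriminator_confused(self):
        """No domain shift: after adversarial training the
        discriminator cannot beat chance by much."""
        accs = []
        for seed in range(2):
            cfg = m.SimConfig.separable(n_pos=60, n_neg=60,
                                        domain_shift_strength=0.0,
                                        seed=seed)
            antigenic, immunogenic, _ = m.simulate_dataset(cfg)
            el = m.ElPresentationModel(
                antigenic, antigenic.alleles,
                m.ElConfig(epochs=2, d_model=24, lr=3e-3, seed=seed)).fit()
            res = m.CdanTransfer(
                el, antigenic, immunogenic,
                CdanConfig(seed=seed, epochs=6, lr=3e-3)).fit()
            accs.append(res.discriminator_accuracy())
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_predictions_flag_unknown_alleles(self, trained_el):
        antigenic, el = trained_el
        immunogenic = antigenic  # reuse as a stand-in target domain
        res = m.CdanTransfer(el, antigenic, immunogenic,
                             CdanConfig(seed=0, epochs=1)).fit()
        from mhc2learn.io import Dataset, PeptideRecord
        good = antigenic.records[0]
        bad = PeptideRecord(peptide="ACDEFGHIKLMN",
                            allele="DRB1*01:99", label=1)
        scores, flagged = res.predict(Dataset([good, bad]))
        assert np.isfinite(scores[0]) and np.isnan(scores[1])
        assert flagged == [(1, "DRB1*01:99")]

    def test_im_checkpoint_round_trip(self, trained_el, tmp_path):
        antigenic, el = trained_el
        res = m.CdanTransfer(el, antigenic, antigenic,
                             CdanConfig(seed=0, epochs=1)).fit()
        path = tmp_path / "im.npz"
        res.save(path, el_hash="abc123")
        loaded = m.ImResults.load(path)
        assert loaded.el_checkpoint_hash == "abc123"
        sub = antigenic.subset(np.arange(6))
        s1, _ = res.predict(sub)
        s2, _ = loaded.predict(sub)
        assert np.allclose(s1, s2)
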