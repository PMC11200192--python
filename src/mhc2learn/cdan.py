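"""Conditional domain-adversarial transfer to the immunogenicity domain.

The presentation model's feature extractor F (sequence encoders plus
bilinear attention) is transferred to the immunogenicity task by
adversarial alignment: a decoder G (two dense layers, softmax)
classifies records in both domains, while a three-layer domain
discriminator D tries to tell the antigenic (presentation) domain from
the immunogenic (T-cell assay) domain using the multilinear conditional
representation h = f (x) g.  F and G are trained to minimize the
classification losses while confusing D; D minimizes the domain
cross-entropy.  The coupling is a gradient-reversal layer of weight
omega with linear warm-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, balanced_accuracy_score

from . import nn
from .io import Dataset, DOMAIN_ANTIGENIC, DOMAIN_IMMUNOGENIC
from .el import ElResults, _predict_probs

__all__ = ["CdanConfig", "multilinear_map", "cdan_losses",
           "CdanTransfer", "ImResults"]


@dataclass
class CdanConfig:
    """Hyperparameters of the adversarial transfer stage."""

    omega: float = 1.0              # adversarial weight (> 0)
    epochs: int = 30
    batch_size: int = 32
    max_dim: int = 1024             # randomized multilinear width cap
    lr: float = 1e-3
    decoder_hidden: int = 32        # G: two dense layers
    disc_hidden: tuple[int, int] = (64, 32)   # D: three-layer FC
    target_supervised: bool = True  # add supervised loss on IM labels
    warmup_frac: float = 0.1        # linear omega warm-up fraction
    seed: int = 0

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def multilinear_map(f: nn.Tensor | np.ndarray, g: nn.Tensor | np.ndarray,
                    max_dim: int = 1024, seed: int = 0) -> nn.Tensor:
    """Multiplicative interaction h between features f and class
    probabilities g.

    The flattened outer product f (x) g when its dimension fits in
    ``max_dim``; otherwise the seed-fixed randomized multilinear map
    ``(f R_f) * (g R_g) / sqrt(max_dim)`` of width ``max_dim``.
    """
    f = f if isinstance(f, nn.Tensor) else nn.Tensor(f)
    g = g if isinstance(g, nn.Tensor) else nn.Tensor(g)
    if f.shape[-1] == 0 or g.shape[-1] == 0:
        raise ValueError("f and g must be non-empty")
    gsum = g.data.sum(axis=-1)
    if np.abs(gsum - 1.0).max() > 1e-6:
        raise ValueError("g must lie on the probability simplex")
    df, dg = f.shape[-1], g.shape[-1]
    B = f.shape[0]
    if df * dg <= max_dim:
        # outer product, flattened: h[b, i*dg + j] = f[b,i] * g[b,j]
        fo = f.reshape(B, df, 1)
        go = g.reshape(B, 1, dg)
        return (fo * go).reshape(B, df * dg)
    rng = np.random.default_rng(seed)
    rf = nn.Tensor(rng.standard_normal((df, max_dim)))
    rg = nn.Tensor(rng.standard_normal((dg, max_dim)))
    return (f @ rf) * (g @ rg) * (1.0 / np.sqrt(max_dim))


class _Discriminator(nn.Module):
    def __init__(self, d_in: int, hidden: tuple[int, int], rng):
        self.mlp = nn.MLP([d_in, *hidden, 1], rng)

    def __call__(self, h: nn.Tensor) -> nn.Tensor:
        return self.mlp(h).sigmoid().reshape(-1)


def cdan_losses(F, G, D, pep_a, hla_a, y_a, pep_i, hla_i, y_i,
                cfg: CdanConfig, omega_t: float | None = None,
                target_supervised: bool | None = None):
    """The three loss terms on a two-domain batch.

    Returns (L_a, L_i, L_adv) as graph tensors: antigenic
    classification loss of G with presentation labels, immunogenic
    classification loss of G (zero tensor when target supervision is
    off), and the domain cross-entropy of D on the reversed multilinear
    representations of both domains.
    """
    if len(y_a) == 0 or len(y_i) == 0:
        raise ValueError("both domains must be present in every batch")
    omega_t = cfg.omega if omega_t is None else omega_t
    sup = cfg.target_supervised if target_supervised is None \
        else target_supervised
    f_a = F.features(nn.Tensor(pep_a), nn.Tensor(hla_a))
    f_i = F.features(nn.Tensor(pep_i), nn.Tensor(hla_i))
    logits_a, logits_i = G(f_a), G(f_i)
    L_a = nn.cross_entropy(logits_a, y_a)
    L_i = nn.cross_entropy(logits_i, y_i) if sup \
        else nn.Tensor(0.0)
    g_a = logits_a.softmax(axis=-1)
    g_i = logits_i.softmax(axis=-1)
    h_a = multilinear_map(f_a, g_a, cfg.max_dim, cfg.seed)
    h_i = multilinear_map(f_i, g_i, cfg.max_dim, cfg.seed)
    h = nn.concat([nn.grad_reverse(h_a, omega_t),
                   nn.grad_reverse(h_i, omega_t)], axis=0)
    d_out = D(h)
    domain = np.concatenate([np.zeros(len(y_a)), np.ones(len(y_i))])
    L_adv = nn.binary_cross_entropy(d_out, domain)
    return L_a, L_i, L_adv


class CdanTransfer:
    """Adversarial transfer model built from a fitted presentation model.

    Parameters
    ----------
    el_results : ElResults
        The trained presentation model; its feature extractor
        initializes F.
    antigenic, immunogenic : Dataset
        Labelled records of the two domains.
    config : CdanConfig
    """

    def __init__(self, el_results: ElResults, antigenic: Dataset,
                 immunogenic: Dataset, config: CdanConfig | None = None):
        self.el_results = el_results
        self.config = config or CdanConfig()
        self.antigenic = antigenic
        self.immunogenic = immunogenic
        m = el_results.model
        self._pep_a = m._encode_peptides(antigenic)
        self._hla_a = m._encode_alleles(antigenic)
        self._y_a = antigenic.labels()
        self._pep_i = m._encode_peptides(immunogenic)
        self._hla_i = m._encode_alleles(immunogenic)
        self._y_i = immunogenic.labels()

    def fit(self, adversarial: bool = True) -> "ImResults":
        """Run the minimax optimization; returns the fitted IM model.

        ``adversarial=False`` trains D on the evolving features without
        coupling its gradient back into F and G (the no-transfer
        control used to verify that the adversarial signal, not
        capacity, confuses the discriminator).
        """
        cfg = self.config
        import copy
        F = copy.deepcopy(self.el_results.net)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        rank = self.el_results.config.bilinear_rank
        G = nn.MLP([rank, cfg.decoder_hidden, 2], rng)
        h_dim = min(rank * 2, cfg.max_dim)
        D = _Discriminator(h_dim, cfg.disc_hidden, rng)
        opt_fg = nn.AdamW(F.parameters() + G.parameters(), lr=cfg.lr)
        opt_d = nn.AdamW(D.parameters(), lr=cfg.lr)
        n_a, n_i = len(self._y_a), len(self._y_i)
        steps_per_epoch = max(n_a, n_i) // cfg.batch_size or 1
        total = cfg.epochs * steps_per_epoch
        history = []
        step = 0
        for epoch in range(cfg.epochs):
            order_a = rng.permutation(n_a)
            order_i = rng.permutation(n_i)
            for s in range(steps_per_epoch):
                ba = order_a[(s * cfg.batch_size) % n_a:][:cfg.batch_size]
                bi = order_i[(s * cfg.batch_size) % n_i:][:cfg.batch_size]
                if len(ba) == 0 or len(bi) == 0:
                    continue
                warm = min(1.0, (step + 1) / max(1, cfg.warmup_frac * total))
                omega_t = cfg.omega * warm if adversarial else 0.0
                L_a, L_i, L_adv = cdan_losses(
                    F, G, D, self._pep_a[ba], self._hla_a[ba], self._y_a[ba],
                    self._pep_i[bi], self._hla_i[bi], self._y_i[bi],
                    cfg, omega_t=omega_t)
                loss = L_a + L_i + L_adv
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"divergence at epoch {epoch}, step {s}: "
                        f"L_a={L_a.data}, L_i={L_i.data}, L_adv={L_adv.data}")
                opt_fg.zero_grad()
                opt_d.zero_grad()
                loss.backward()
                opt_fg.step()
                opt_d.step()
                history.append((float(L_a.data), float(L_i.data),
                                float(L_adv.data)))
                step += 1
        return ImResults(self, F, G, D, pd.DataFrame(
            history, columns=["L_a", "L_i", "L_adv"]))


class ImResults:
    """Fitted immunogenicity model."""

    def __init__(self, model: CdanTransfer, F, G, D,
                 loss_history: pd.DataFrame):
        self.model = model
        self.F = F
        self.G = G
        self.D = D
        self.loss_history = loss_history

    def _probs(self, pep: np.ndarray, hla: np.ndarray,
               batch: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(pep), batch):
            f = self.F.features(nn.Tensor(pep[lo:lo + batch]),
                                nn.Tensor(hla[lo:lo + batch]))
            out.append(self.G(f).softmax(axis=-1).data[:, 1])
        return np.concatenate(out)

    def predict(self, data: Dataset
                ) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """Immunogenicity probability per record.

        Records whose allele has no pseudosequence are flagged (NaN
        score) and reported in the second return value.
        """
        m = self.model.el_results.model
        scores = np.full(len(data), np.nan)
        flagged: list[tuple[int, str]] = []
        ok = []
        for i, rec in enumerate(data.records):
            if rec.allele in m.alleles:
                ok.append(i)
            else:
                flagged.append((i, rec.allele))
        if ok:
            sub = data.subset(ok)
            scores[np.array(ok)] = self._probs(
                m._encode_peptides(sub), m._encode_alleles(sub))
        return scores, flagged

    def discriminator_accuracy(self) -> float:
        """Domain accuracy of D over both full domains (0.5 = fully
        confused)."""
        mdl = self.model
        preds = []
        domains = []
        for pep, hla, dom in ((mdl._pep_a, mdl._hla_a, 0),
                              (mdl._pep_i, mdl._hla_i, 1)):
            for lo in range(0, len(pep), 256):
                f = self.F.features(nn.Tensor(pep[lo:lo + 256]),
                                    nn.Tensor(hla[lo:lo + 256]))
                g = self.G(f).softmax(axis=-1)
                h = multilinear_map(f, g, mdl.config.max_dim,
                                    mdl.config.seed)
                preds.append(self.D(h).data)
                domains.append(np.full(len(preds[-1]), dom))
        preds = np.concatenate(preds)
        domains = np.concatenate(domains)
        return float(((preds > 0.5) == (domains > 0.5)).mean())

    def _frozen_h(self) -> tuple[np.ndarray, np.ndarray]:
        mdl = self.model
        hs, ds = [], []
        for pep, hla, dom in ((mdl._pep_a, mdl._hla_a, 0),
                              (mdl._pep_i, mdl._hla_i, 1)):
            for lo in range(0, len(pep), 256):
                f = self.F.features(nn.Tensor(pep[lo:lo + 256]),
                                    nn.Tensor(hla[lo:lo + 256]))
                g = self.G(f).softmax(axis=-1)
                h = multilinear_map(f, g, mdl.config.max_dim,
                                    mdl.config.seed)
                hs.append(h.data)
                ds.append(np.full(len(h.data), dom, dtype=float))
        return np.concatenate(hs), np.concatenate(ds)

    def probe_discriminator_accuracy(self, epochs: int = 200,
                                     lr: float = 3e-3,
                                     hidden: tuple[int, int] = (128, 64),
                                     seed: int = 0) -> float:
        """Accuracy of a fresh domain discriminator trained to
        convergence on the *frozen* conditional representations.

        This is the appropriate readout for a model trained without
        adversarial coupling: its features are stationary, so the
        discriminator is given a full optimization rather than the
        moving-target schedule of the minimax game.
        """
        H, dom = self._frozen_h()
        rng = np.random.default_rng(seed)
        D = _Discriminator(H.shape[1], hidden, rng)
        opt = nn.AdamW(D.parameters(), lr=lr)
        for _ in range(epochs):
            order = rng.permutation(len(H))
            for lo in range(0, len(H), 64):
                b = order[lo:lo + 64]
                loss = nn.binary_cross_entropy(D(nn.Tensor(H[b])), dom[b])
                opt.zero_grad()
                loss.backward()
                opt.step()
        pred = D(nn.Tensor(H)).data
        return float(((pred > 0.5) == (dom > 0.5)).mean())

    def target_metrics(self, data: Dataset) -> dict[str, float]:
        scores, _ = self.predict(data)
        y = data.labels()
        mask = np.isfinite(scores)
        return {
            "auc": float(roc_auc_score(y[mask], scores[mask])),
            "balanced_acc": float(balanced_accuracy_score(
                y[mask], scores[mask] > 0.5)),
        }

    # -- persistence -----------------------------------------------------
    def save(self, path, el_hash: str = "") -> None:
        """Checkpoint F and G (npz) with the config, allele table and
        the hash of the presentation checkpoint F was initialized from."""
        import json as _json
        cfg = self.model.config
        el = self.model.el_results
        f_arrays = self.F.state_arrays()
        g_arrays = self.G.state_arrays()
        meta = {
            "cdan_config": {"omega": cfg.omega, "epochs": cfg.epochs,
                            "batch_size": cfg.batch_size,
                            "max_dim": cfg.max_dim, "lr": cfg.lr,
                            "decoder_hidden": cfg.decoder_hidden,
                            "disc_hidden": list(cfg.disc_hidden),
                            "target_supervised": cfg.target_supervised,
                            "warmup_frac": cfg.warmup_frac,
                            "seed": cfg.seed},
            "el_config": {"n_encoders": el.config.n_encoders,
                          "n_heads": el.config.n_heads,
                          "d_model": el.config.d_model,
                          "head_units": list(el.config.head_units),
                          "bilinear_rank": el.config.bilinear_rank,
                          "lr": el.config.lr, "epochs": el.config.epochs,
                          "batch_size": el.config.batch_size,
                          "pad_to": el.config.pad_to,
                          "seed": el.config.seed},
            "alleles": {n: [a.short_seq, a.full_seq]
                        for n, a in el.model.alleles.items()},
            "n_f": len(f_arrays),
            "el_checkpoint_hash": el_hash,
            "format_version": 1,
        }
        payload = {f"f{i}": a for i, a in enumerate(f_arrays)}
        payload.update({f"g{i}": a for i, a in enumerate(g_arrays)})
        np.savez(path, meta=np.frombuffer(
            _json.dumps(meta).encode(), dtype=np.uint8), **payload)

    @staticmethod
    def load(path) -> "ImResults":
        import json as _json
        from .el import (ElConfig, ElPresentationModel, ElResults, _ElNet)
        from .io import AllelePseudosequence
        with np.load(path) as z:
            meta = _json.loads(bytes(z["meta"]).decode())
            f_arrays = [z[f"f{i}"] for i in range(meta["n_f"])]
            g_arrays = [z[f"g{i}"]
                        for i in range(len(z.files) - 1 - meta["n_f"])]
        elc = meta["el_config"]
        el_cfg = ElConfig(**{**elc, "head_units": tuple(elc["head_units"])})
        alleles = {n: AllelePseudosequence(n, s, f)
                   for n, (s, f) in meta["alleles"].items()}
        el_model = ElPresentationModel.__new__(ElPresentationModel)
        el_model.config = el_cfg
        el_model.alleles = alleles
        el_model.data = None
        F = _ElNet(el_cfg, 42, np.random.default_rng(0))
        F.load_state_arrays(f_arrays)
        el_res = ElResults(el_model, F, pd.DataFrame())
        cc = meta["cdan_config"]
        cfg = CdanConfig(**{**cc, "disc_hidden": tuple(cc["disc_hidden"])})
        transfer = CdanTransfer.__new__(CdanTransfer)
        transfer.el_results = el_res
        transfer.config = cfg
        rng = np.random.default_rng(0)
        G = nn.MLP([el_cfg.bilinear_rank, cfg.decoder_hidden, 2], rng)
        G.load_state_arrays(g_arrays)
        h_dim = min(el_cfg.bilinear_rank * 2, cfg.max_dim)
        D = _Discriminator(h_dim, cfg.disc_hidden, rng)
        res = ImResults(transfer, F, G, D, pd.DataFrame(
            columns=["L_a", "L_i", "L_adv"]))
        res.el_checkpoint_hash = meta["el_checkpoint_hash"]
        return res

    def summary(self) -> str:
        if self.loss_history.empty:
            return "Immunogenicity model (loaded checkpoint)"
        tail = self.loss_history.tail(20).mean()
        return "\n".join([
            "Immunogenicity model (adversarial transfer)",
            f"  omega={self.model.config.omega}, "
            f"epochs={self.model.config.epochs}, "
            f"batch_size={self.model.config.batch_size}",
            f"  final losses: L_a={tail['L_a']:.4f} "
            f"L_i={tail['L_i']:.4f} L_adv={tail['L_adv']:.4f}",
            f"  discriminator domain accuracy: "
            f"{self.discriminator_accuracy():.3f}",
        ])
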