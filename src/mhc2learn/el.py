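"""Presentation (eluted-ligand) model.

A peptide branch and an HLA-pseudosequence branch — each three pre-norm
transformer encoder blocks with 12-head self-attention — are coupled by
a low-rank bilinear attention module whose pooled joint representation
feeds a 128-64-32 dense head with a two-unit softmax output.  The
positive-class probability is the sequence score; it is fused with
expression, cleavage and binding-core-offset branch scores under fixed
contribution weights (60/12/12/16 %), and optionally calibrated to a
percentile rank against a random proteome background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .io import Dataset, AllelePseudosequence
from .encodings import (encode_peptide, encode_allele_short, PEPTIDE_PAD_TO,
                        SHORT_PSEUDO_LEN)

logger = logging.getLogger(__name__)


@dataclass
class ElConfig:
    """Hyperparameters of the presentation network."""

    n_encoders: int = 3
    n_heads: int = 12
    d_model: int = 96
    head_units: tuple[int, int, int] = (128, 64, 32)
    bilinear_rank: int = 32
    lr: float = 1e-3            # searched within [1e-5, 1e-2]
    epochs: int = 10
    batch_size: int = 32
    pad_to: int = PEPTIDE_PAD_TO
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError(
                f"n_heads={self.n_heads} must divide d_model={self.d_model}")
        if not 1e-5 <= self.lr <= 1e-2:
            raise ValueError("lr outside the searched range [1e-5, 1e-2]")
        self.head_units = tuple(self.head_units)
        if len(self.head_units) != 3:
            raise ValueError("head_units must be a triple")


@dataclass
class FusionWeights:
    """Fixed contribution weights of the four predictor branches."""

    w_seq: float = 0.60
    w_expr: float = 0.12
    w_cleave: float = 0.12
    w_core: float = 0.16

    def __post_init__(self):
        w = (self.w_seq, self.w_expr, self.w_cleave, self.w_core)
        if any(x < 0 for x in w):
            raise ValueError("fusion weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"fusion weights must sum to 1, got {sum(w)}")


@dataclass
class FusionScore:
    """Per-branch scores and their fused combination."""

    s_seq: float
    s_expr: float | None
    s_cleave: float
    s_core: float
    fused: float = field(default=np.nan)
    percentile_rank: float | None = None


def fuse(score: FusionScore, w: FusionWeights = FusionWeights()) -> float:
    """Weighted fusion of branch scores.

    A missing expression branch (``s_expr is None``) renormalizes the
    remaining weights to sum to one (logged once per call site).
    """
    branches = [("seq", score.s_seq, w.w_seq),
                ("expr", score.s_expr, w.w_expr),
                ("cleave", score.s_cleave, w.w_cleave),
                ("core", score.s_core, w.w_core)]
    live = [(name, s, wt) for name, s, wt in branches if s is not None]
    for name, s, _ in live:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"branch {name} score {s} outside [0, 1]")
    total_w = sum(wt for _, _, wt in live)
    if len(live) < 4:
        logger.info("fuse: %d branch(es) missing; renormalizing weights",
                    4 - len(live))
    fused = sum(s * wt for _, s, wt in live) / total_w
    score.fused = fused
    return fused


def percentile_rank(score: float, background: np.ndarray) -> float:
    """Percentile rank in [0, 100]: percentage of the allele's random
    background scoring strictly higher.  Lower is stronger."""
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background sample is empty")
    return float(100.0 * (background > score).mean())


class _ElNet(nn.Module):
    def __init__(self, cfg: ElConfig, d_in: int, rng):
        self.pep_enc = nn.SequenceEncoder(
            d_in, cfg.d_model, cfg.n_heads, cfg.n_encoders, cfg.pad_to, rng)
        self.hla_enc = nn.SequenceEncoder(
            d_in, cfg.d_model, cfg.n_heads, cfg.n_encoders,
            SHORT_PSEUDO_LEN, rng)
        self.ban = nn.BilinearAttention(cfg.d_model, cfg.bilinear_rank, rng)
        self.head = nn.MLP([cfg.bilinear_rank, *cfg.head_units, 2], rng)

    def __call__(self, pep: nn.Tensor, hla: nn.Tensor) -> nn.Tensor:
        joint = self.ban(self.pep_enc(pep), self.hla_enc(hla))
        return self.head(joint)          # logits (B, 2)

    def features(self, pep: nn.Tensor, hla: nn.Tensor) -> nn.Tensor:
        """Joint bilinear-attention representation (B, rank)."""
        return self.ban(self.pep_enc(pep), self.hla_enc(hla))


class ElPresentationModel:
    """Presentation model over a labelled peptide x allele dataset.

    Parameters
    ----------
    data : Dataset
        Records with 0/1 presentation labels; if
        ``data.split_assignments`` is set, training iterates the
        (repeat, fold) grid, otherwise a single 4:1 train/validation
        split is drawn.
    alleles : dict
        Pseudosequence per normalized allele name.
    config : ElConfig
    """

    def __init__(self, data: Dataset,
                 alleles: dict[str, AllelePseudosequence],
                 config: ElConfig | None = None):
        self.data = data
        self.alleles = alleles
        self.config = config or ElConfig()
        labels = data.labels()
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("presentation training needs 0/1 labels")
        self._pep = self._encode_peptides(data)
        self._hla = self._encode_alleles(data)
        self._y = labels

    def _encode_peptides(self, data: Dataset) -> np.ndarray:
        return np.stack([encode_peptide(r.peptide, self.config.pad_to)
                         for r in data.records])

    def _encode_alleles(self, data: Dataset) -> np.ndarray:
        cache: dict[str, np.ndarray] = {}
        rows = []
        for r in data.records:
            if r.allele not in cache:
                if r.allele not in self.alleles:
                    raise KeyError(f"no pseudosequence for {r.allele}")
                cache[r.allele] = encode_allele_short(self.alleles[r.allele])
            rows.append(cache[r.allele])
        return np.stack(rows)

    # -- training --------------------------------------------------------
    def fit(self, repeats: int | None = None,
            folds: int | None = None) -> "ElResults":
        """Train the network; returns fitted results with fold metrics.

        Uses the dataset's split assignments when present (optionally
        restricted to the first `repeats` x `folds`); otherwise a
        single seeded 4:1 split.  The best-validation-loss epoch's
        parameters are kept per fold; the last fold's best network is
        carried in the results for prediction.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        metrics = []
        net = None
        if self.data.split_assignments is not None:
            sa = self.data.split_assignments
            n_rep = min(repeats or sa.shape[0], sa.shape[0])
            n_folds = int(sa.max()) + 1
            use_folds = min(folds or n_folds, n_folds)
            for rep in range(n_rep):
                for fold in range(use_folds):
                    test = sa[rep] == fold
                    train = ~test
                    net, row = self._fit_fold(np.flatnonzero(train), rng)
                    row.update(repeat=rep, fold=fold)
                    metrics.append(row)
        else:
            net, row = self._fit_fold(np.arange(len(self._y)), rng)
            row.update(repeat=0, fold=0)
            metrics.append(row)
        return ElResults(self, net, pd.DataFrame(metrics))

    def _fit_fold(self, idx: np.ndarray, rng) -> tuple[_ElNet, dict]:
        cfg = self.config
        # 4:1 train/validation split within the fold, at peptide level
        peps = sorted({self.data.records[i].peptide for i in idx})
        perm = rng.permutation(len(peps))
        val_peps = {peps[j] for j in perm[:max(1, len(peps) // 5)]}
        val_mask = np.array([self.data.records[i].peptide in val_peps
                             for i in idx])
        tr, va = idx[~val_mask], idx[val_mask]
        if len(np.unique(self._y[tr])) < 2:
            raise ValueError("training fold contains a single class")
        net_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, int(idx[0]), len(idx)]))
        net = _ElNet(cfg, self._pep.shape[2], net_rng)
        opt = nn.AdamW(net.parameters(), lr=cfg.lr)
        best = (np.inf, net.state_arrays())
        history = []
        for epoch in range(cfg.epochs):
            order = net_rng.permutation(len(tr))
            for lo in range(0, len(tr), cfg.batch_size):
                b = tr[order[lo:lo + cfg.batch_size]]
                logits = net(nn.Tensor(self._pep[b]), nn.Tensor(self._hla[b]))
                loss = nn.cross_entropy(logits, self._y[b])
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_loss, val_auc = self._evaluate(net, va)
            history.append((val_loss, val_auc))
            if val_loss < best[0]:
                best = (val_loss, [a.copy() for a in net.state_arrays()])
        net.load_state_arrays(best[1])
        val_loss, val_auc = self._evaluate(net, va)
        return net, {"n_train": len(tr), "n_val": len(va),
                     "val_loss": val_loss, "val_auc": val_auc,
                     "epochs": cfg.epochs,
                     "val_auc_history": [a for _, a in history]}

    def _evaluate(self, net: _ElNet, idx: np.ndarray,
                  batch: int = 256) -> tuple[float, float]:
        probs = _predict_probs(net, self._pep[idx], self._hla[idx], batch)
        y = self._y[idx]
        eps = 1e-12
        loss = float(-np.mean(y * np.log(probs + eps)
                              + (1 - y) * np.log(1 - probs + eps)))
        auc = roc_auc_score(y, probs) if len(np.unique(y)) == 2 else np.nan
        return loss, float(auc)


def _predict_probs(net: _ElNet, pep: np.ndarray, hla: np.ndarray,
                   batch: int = 256) -> np.ndarray:
    out = []
    for lo in range(0, len(pep), batch):
        logits = net(nn.Tensor(pep[lo:lo + batch]),
                     nn.Tensor(hla[lo:lo + batch]))
        out.append(logits.softmax(axis=-1).data[:, 1])
    return np.concatenate(out)


class ElResults:
    """Fitted presentation model: predictions, fusion, calibration and
    attention export."""

    def __init__(self, model: ElPresentationModel, net: _ElNet,
                 fold_metrics: pd.DataFrame):
        self.model = model
        self.net = net
        self.fold_metrics = fold_metrics
        self.percentile_backgrounds: dict[str, np.ndarray] = {}

    @property
    def config(self) -> ElConfig:
        return self.model.config

    # -- scoring ---------------------------------------------------------
    def predict(self, data: Dataset) -> np.ndarray:
        """Positive-class (presented) probability per record."""
        pep = self.model._encode_peptides(data)
        hla = self.model._encode_alleles(data)
        return _predict_probs(self.net, pep, hla)

    def predict_pairs(self, peptides: list[str],
                      allele: str) -> np.ndarray:
        pep = np.stack([encode_peptide(p, self.config.pad_to)
                        for p in peptides])
        enc = encode_allele_short(self.model.alleles[allele])
        hla = np.broadcast_to(enc, (len(peptides),) + enc.shape)
        return _predict_probs(self.net, pep, np.ascontiguousarray(hla))

    def calibrate_percentiles(self, allele: str,
                              background_peptides: list[str]) -> None:
        """Store an allele's random-background score sample for
        percentile-rank conversion."""
        self.percentile_backgrounds[allele] = self.predict_pairs(
            background_peptides, allele)

    def percentile(self, score: float, allele: str) -> float:
        if allele not in self.percentile_backgrounds:
            raise KeyError(f"no percentile background for {allele}")
        return percentile_rank(score, self.percentile_backgrounds[allele])

    # -- interpretability ------------------------------------------------
    def attention_map(self, peptide: str, allele: str,
                      out_tsv=None) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear attention over (peptide position, HLA residue).

        Returns (map, marginal): the map's rows are normalized over HLA
        residues, and the per-residue marginal sums to one.  Optionally
        written as TSV.
        """
        pep = encode_peptide(peptide, self.config.pad_to)[None]
        hla = encode_allele_short(self.model.alleles[allele])[None]
        self.net(nn.Tensor(pep), nn.Tensor(hla))
        att = self.net.ban.last_attention[0]          # (Lp, La)
        att = att[:len(peptide)]
        rows = att / att.sum(axis=1, keepdims=True)
        marginal = att.sum(axis=0)
        marginal = marginal / marginal.sum()
        if out_tsv is not None:
            df = pd.DataFrame(rows, index=list(peptide),
                              columns=[f"hla_{i}" for i in
                                       range(rows.shape[1])])
            df.to_csv(out_tsv, sep="\t")
        return rows, marginal

    # -- persistence -----------------------------------------------------
    def save(self, path) -> str:
        """Write a checkpoint (npz: parameters + embedded config and
        allele table).  Returns the parameter hash."""
        import json as _json
        import hashlib
        arrays = {f"p{i}": a for i, a in
                  enumerate(self.net.state_arrays())}
        digest = hashlib.sha256(
            b"".join(a.tobytes() for a in arrays.values())).hexdigest()[:16]
        cfg = self.config
        meta = {
            "config": {"n_encoders": cfg.n_encoders, "n_heads": cfg.n_heads,
                       "d_model": cfg.d_model,
                       "head_units": list(cfg.head_units),
                       "bilinear_rank": cfg.bilinear_rank, "lr": cfg.lr,
                       "epochs": cfg.epochs, "batch_size": cfg.batch_size,
                       "pad_to": cfg.pad_to, "seed": cfg.seed},
            "alleles": {n: [a.short_seq, a.full_seq]
                        for n, a in self.model.alleles.items()},
            "param_hash": digest,
            "format_version": 1,
        }
        np.savez(path, meta=np.frombuffer(
            _json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return digest

    @staticmethod
    def load(path) -> "ElResults":
        import json as _json
        with np.load(path) as z:
            meta = _json.loads(bytes(z["meta"]).decode())
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        cfg = ElConfig(**{**meta["config"],
                          "head_units": tuple(meta["config"]["head_units"])})
        alleles = {n: AllelePseudosequence(n, s, f)
                   for n, (s, f) in meta["alleles"].items()}
        model = ElPresentationModel.__new__(ElPresentationModel)
        model.config = cfg
        model.alleles = alleles
        model.data = None
        net = _ElNet(cfg, 42, np.random.default_rng(0))
        net.load_state_arrays(arrays)
        res = ElResults(model, net, pd.DataFrame())
        res.param_hash = meta["param_hash"]
        return res

    def summary(self) -> str:
        fm = self.fold_metrics
        if fm.empty:
            return ("Presentation model (loaded checkpoint, "
                    f"{self.net.n_parameters()} parameters)")
        lines = [
            "Presentation model "
            f"({self.config.n_encoders} encoders/branch, "
            f"{self.config.n_heads} heads, d_model={self.config.d_model}, "
            f"bilinear rank {self.config.bilinear_rank})",
            f"  parameters : {self.net.n_parameters()}",
            f"  folds run  : {len(fm)}",
            f"  mean val loss: {fm['val_loss'].mean():.4f}",
            f"  mean val AUC : {fm['val_auc'].mean():.4f}",
        ]
        return "\n".join(lines)
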