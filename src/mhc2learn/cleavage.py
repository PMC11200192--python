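"""Proteolytic cleavage-site windows and the cleavage scorer.

Class II ligands are excised by proteases whose specificity leaves a
compositional signature (notably proline/alanine enrichment) in the
residues flanking the peptide termini.  Each terminus contributes a
6-residue window — three residues upstream and three downstream of the
cut site, in N-to-C order — and a small dense network maps the two
windows to a cleavage propensity in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .io import AA_ALPHABET, PAD_CHAR, Dataset, PeptideRecord
from .encodings import AA_INDEX, N_CHANNELS

logger = logging.getLogger(__name__)

WINDOW = 6          # residues per terminus window
N_POSITIONS = 12    # two windows concatenated N-to-C


@dataclass
class CleavageWindows:
    n_window: str   # 3 upstream residues + first 3 of the peptide
    c_window: str   # last 3 of the peptide + 3 downstream residues

    def __post_init__(self):
        if len(self.n_window) != WINDOW or len(self.c_window) != WINDOW:
            raise ValueError("both windows must be exactly 6 residues")

    @property
    def combined(self) -> str:
        return self.n_window + self.c_window


def _pad_slice(protein: str, lo: int, hi: int) -> str:
    """protein[lo:hi] padded with X where the range leaves the protein."""
    left = PAD_CHAR * max(0, -lo)
    right = PAD_CHAR * max(0, hi - len(protein))
    return left + protein[max(lo, 0):min(hi, len(protein))] + right


def extract_windows(protein: str, start: int, end: int) -> CleavageWindows:
    """Windows around the peptide occupying protein[start:end).

    ``n_window`` spans [start-3, start+3), ``c_window`` spans
    [end-3, end+3); positions outside the protein are X-padded.
    """
    if start >= end:
        raise ValueError(f"start={start} must be < end={end}")
    if start < 0 or end > len(protein):
        raise ValueError("peptide range outside protein")
    return CleavageWindows(_pad_slice(protein, start - 3, start + 3),
                           _pad_slice(protein, end - 3, end + 3))


def windows_from_record(rec: PeptideRecord) -> CleavageWindows:
    """Build windows from a record's own flanks (X-padded to 3)."""
    nf = (rec.n_flank or "")[-3:].rjust(3, PAD_CHAR)
    cf = (rec.c_flank or "")[:3].ljust(3, PAD_CHAR)
    pep = rec.peptide
    return CleavageWindows(nf + pep[:3].ljust(3, PAD_CHAR),
                           pep[-3:].rjust(3, PAD_CHAR) + cf)


def encode_windows(w: CleavageWindows) -> np.ndarray:
    """One-hot encode the 12 window positions, flattened to (12*21,)."""
    m = np.zeros((N_POSITIONS, N_CHANNELS))
    for i, aa in enumerate(w.combined):
        m[i, AA_INDEX.get(aa, 20)] = 1.0
    return m.ravel()


def locate_in_proteome(peptide: str, proteome: dict[str, str],
                       gene: str = "") -> tuple[str, int] | None:
    """Find (sequence, start) of a peptide, preferring its source gene."""
    if gene and gene in proteome:
        pos = proteome[gene].find(peptide)
        if pos >= 0:
            return proteome[gene], pos
    for seq in proteome.values():
        pos = seq.find(peptide)
        if pos >= 0:
            return seq, pos
    return None


def windows_for_dataset(data: Dataset,
                        proteome: dict[str, str] | None = None
                        ) -> tuple[list[CleavageWindows], int]:
    """Windows per record, from flanks or proteome lookup.

    Returns (windows, n_skipped); records that carry no flanks and
    cannot be located in the proteome fall back to X-padded windows
    when no proteome is given, or are skipped when lookup fails.
    """
    out: list[CleavageWindows] = []
    skipped = 0
    for rec in data.records:
        if rec.n_flank or rec.c_flank or proteome is None:
            out.append(windows_from_record(rec))
            continue
        hit = locate_in_proteome(rec.peptide, proteome, rec.gene)
        if hit is None:
            skipped += 1
            continue
        seq, pos = hit
        out.append(extract_windows(seq, pos, pos + len(rec.peptide)))
    if skipped:
        logger.warning("windows_for_dataset: %d records unlocatable", skipped)
    return out, skipped


def cleavage_background(decoys: Dataset,
                        proteome: dict[str, str] | None = None) -> np.ndarray:
    """Per-position amino-acid frequencies over decoy windows.

    Returns a (12, 21) table whose rows sum to 1 — the background
    composition against which cleavage enrichment is measured.
    """
    windows, _ = windows_for_dataset(decoys, proteome)
    if not windows:
        raise ValueError("no decoy windows available")
    counts = np.zeros((N_POSITIONS, N_CHANNELS))
    for w in windows:
        for i, aa in enumerate(w.combined):
            counts[i, AA_INDEX.get(aa, 20)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


class CleavageScorer:
    """Dense scorer of cleavage propensity from terminal windows.

    Two fully connected layers of 32 units over the one-hot encoded
    12-position window pair, logistic output in [0, 1].  Fit by AdamW
    on binary cross-entropy against length-matched decoys.
    """

    def __init__(self, hits: Dataset, decoys: Dataset,
                 proteome: dict[str, str] | None = None, seed: int = 0):
        if len(hits) == 0 or len(decoys) == 0:
            raise ValueError("need both hit and decoy records")
        hw, _ = windows_for_dataset(hits, proteome)
        dw, _ = windows_for_dataset(decoys, proteome)
        self.x = np.stack([encode_windows(w) for w in hw + dw])
        self.y = np.concatenate([np.ones(len(hw)), np.zeros(len(dw))])
        self.background = cleavage_background(decoys, proteome)
        self.seed = seed

    def fit(self, epochs: int = 30, lr: float = 1e-3,
            batch_size: int = 64) -> "CleavageResults":
        rng = np.random.default_rng(self.seed)
        net = nn.MLP([self.x.shape[1], 32, 32, 1], rng)
        opt = nn.AdamW(net.parameters(), lr=lr)
        n = len(self.y)
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                xb = nn.Tensor(self.x[idx])
                p = net(xb).sigmoid()
                loss = nn.binary_cross_entropy(p, self.y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            losses.append(epoch_loss / n)
        return CleavageResults(net, self.background, losses, self)


class CleavageResults:
    """Fitted cleavage scorer."""

    def __init__(self, net: nn.MLP, background: np.ndarray,
                 losses: list[float], model: CleavageScorer):
        self.net = net
        self.background = background
        self.loss_history = losses
        self.model = model

    def score_windows(self, windows: list[CleavageWindows]) -> np.ndarray:
        x = nn.Tensor(np.stack([encode_windows(w) for w in windows]))
        return self.net(x).sigmoid().data.ravel()

    def score_records(self, data: Dataset,
                      proteome: dict[str, str] | None = None) -> np.ndarray:
        windows, _ = windows_for_dataset(data, proteome)
        return self.score_windows(windows)

    def training_accuracy(self) -> float:
        x = nn.Tensor(self.model.x)
        p = self.net(x).sigmoid().data.ravel()
        return float(((p > 0.5) == (self.model.y > 0.5)).mean())

    def summary(self) -> str:
        lines = [
            "Cleavage scorer (2 x 32 dense, logistic output)",
            f"  training samples : {len(self.model.y)}",
            f"  final BCE loss   : {self.loss_history[-1]:.4f}",
            f"  training accuracy: {self.training_accuracy():.3f}",
        ]
        return "\n".join(lines)
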