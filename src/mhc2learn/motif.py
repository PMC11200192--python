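"""Binding-core motif deconvolution.

Class II ligands of mixed length are modelled as a mixture of K
position-weight-matrix (PWM) motifs of core length 9, each with an
offset-preference prior over where the core sits inside the flank-
extended peptide, plus a flat background component.  Fitting is by
expectation-maximization over the joint (motif, offset) assignment;
the best of several random restarts is kept.

Peptides are extended with three residues of flanking context on each
side before deconvolution, so the admissible core offsets cover both
the peptide body and its immediate processing context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .io import AA_ALPHABET, PAD_CHAR, Dataset
from .cleavage import locate_in_proteome

CORE_LEN = 9
FLANK = 3
BACKGROUND_ID = -1

_IDX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_IDX[PAD_CHAR] = 20

PSEUDOCOUNT = 0.1       # Dirichlet smoothing per PWM cell
OFFSET_FLOOR = 1e-3     # floor on offset-prior mass
TOL = 1e-6              # per-sequence convergence tolerance
MAX_ITER = 500


def extend_peptides(data: Dataset,
                    proteome: dict[str, str] | None = None) -> list[str]:
    """Extend each peptide with 3 residues of N- and C-flank context.

    Flanks come from the record fields, then from a proteome lookup,
    and are X-padded to exactly three residues when unknown.
    """
    out = []
    for rec in data.records:
        nf, cf = rec.n_flank, rec.c_flank
        if not (nf and cf) and proteome is not None:
            hit = locate_in_proteome(rec.peptide, proteome, rec.gene)
            if hit is not None:
                seq, pos = hit
                nf = nf or seq[max(0, pos - FLANK):pos]
                cf = cf or seq[pos + len(rec.peptide):
                               pos + len(rec.peptide) + FLANK]
        nf = (nf or "")[-FLANK:].rjust(FLANK, PAD_CHAR)
        cf = (cf or "")[:FLANK].ljust(FLANK, PAD_CHAR)
        out.append(nf + rec.peptide + cf)
    return out


def _as_indices(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode sequences, X-padded to max length.

    Returns (S, lengths): S is (n, Lmax) with padding index 20.
    """
    lengths = np.array([len(s) for s in seqs])
    S = np.full((len(seqs), lengths.max()), 20, dtype=np.int64)
    for i, s in enumerate(seqs):
        for j, aa in enumerate(s):
            try:
                S[i, j] = _IDX[aa]
            except KeyError:
                raise ValueError(f"invalid residue {aa!r} in {s!r}") from None
    return S, lengths


def _background_freqs(S: np.ndarray) -> np.ndarray:
    counts = np.bincount(S[S < 20].ravel(), minlength=20).astype(float)
    counts += 1.0  # Laplace; keeps rare residues finite
    return counts / counts.sum()


@dataclass
class CoreAssignment:
    """Maximum-responsibility core placement for one peptide."""

    peptide: str
    motif_id: int           # BACKGROUND_ID for the flat component
    offset: int | None      # 0-based start of the 9-mer core
    responsibility: float


class MotifMixtureResults:
    """Fitted motif mixture: PWMs, offset priors, weights, diagnostics."""

    def __init__(self, n_motifs, pwms, offset_priors, mixture_weights,
                 background, loglik, loglik_trace, n_sequences, n_iter,
                 em_segments=None):
        self.n_motifs = n_motifs
        self.pwms = pwms                      # (K, 9, 20)
        self.offset_priors = offset_priors    # (K, O)
        self.mixture_weights = mixture_weights  # (K+1,), last = background
        self.background = background          # (20,)
        self.loglik = loglik                  # penalized EM objective
        self.loglik_trace = loglik_trace      # final EM run's trace
        # every EM run (initial + register-refinement restarts), each
        # individually monotone non-decreasing
        self.em_segments = em_segments if em_segments is not None \
            else [loglik_trace]
        self.n_sequences = n_sequences
        self.n_iter = n_iter

    # -- inference -------------------------------------------------------
    def responsibilities(self, extended: list[str]) -> np.ndarray:
        """(n, K, O) core responsibilities plus (n,) background mass.

        Returns the flattened (n, K*O + 1) table; rows sum to 1.
        """
        S, lengths = _as_indices(extended)
        if (lengths < CORE_LEN).any():
            raise ValueError(f"all sequences must be >= {CORE_LEN} residues")
        log_joint = _log_joint(S, lengths, self.pwms, self.offset_priors,
                               self.mixture_weights, self.background)
        n = S.shape[0]
        flat = log_joint.reshape(n, -1)
        return np.exp(flat - logsumexp(flat, axis=1, keepdims=True))

    def assign_cores(self, extended: list[str]) -> list[CoreAssignment]:
        """Maximum-responsibility (motif, offset) per peptide."""
        resp = self.responsibilities(extended)
        K = self.n_motifs
        O = self.offset_priors.shape[1] if K else 0
        out = []
        for i, seq in enumerate(extended):
            j = int(np.argmax(resp[i]))
            if K == 0 or j == K * O:          # background cell is last
                out.append(CoreAssignment(seq, BACKGROUND_ID, None,
                                          float(resp[i, -1])))
            else:
                out.append(CoreAssignment(seq, j // O, j % O,
                                          float(resp[i, j])))
        return out

    def offset_feature(self, assignment: CoreAssignment) -> float:
        """Offset-branch score in [0, 1]: the assigned offset's prior
        probability normalized by the motif's modal offset prior.

        Background assignments carry no offset preference and score 1.
        """
        if assignment.motif_id == BACKGROUND_ID:
            return 1.0
        prior = self.offset_priors[assignment.motif_id]
        return float(prior[assignment.offset] / prior.max())

    def consensus(self, motif_id: int) -> str:
        return "".join(AA_ALPHABET[a]
                       for a in self.pwms[motif_id].argmax(axis=1))

    # -- reporting -------------------------------------------------------
    def information_content(self, motif_id: int) -> np.ndarray:
        """Per-position IC (bits) of a motif relative to uniform."""
        p = self.pwms[motif_id]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return np.log2(20) + plogp.sum(axis=1)

    def export_logos(self, out_dir) -> list[str]:
        """Write one information-content logo (PNG) and one PWM TSV per
        motif; a background composition bar chart when K=0."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        if self.n_motifs == 0:
            fig, ax = plt.subplots(figsize=(6, 3))
            ax.bar(list(AA_ALPHABET), self.background)
            ax.set_ylabel("background frequency")
            path = out_dir / "background_composition.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            return [str(path)]
        for k in range(self.n_motifs):
            pwm = self.pwms[k]
            tsv = out_dir / f"motif_{k}_pwm.tsv"
            header = "pos\t" + "\t".join(AA_ALPHABET)
            rows = [f"{j + 1}\t" + "\t".join(f"{v:.6f}" for v in pwm[j])
                    for j in range(CORE_LEN)]
            tsv.write_text(header + "\n" + "\n".join(rows) + "\n")
            written.append(str(tsv))
            written.append(self._draw_logo(k, out_dir, plt))
        return written

    def _draw_logo(self, k: int, out_dir, plt) -> str:
        from matplotlib.textpath import TextPath
        from matplotlib.patches import PathPatch
        from matplotlib.transforms import Affine2D
        from matplotlib.font_manager import FontProperties

        ic = self.information_content(k)
        pwm = self.pwms[k]
        fp = FontProperties(family="monospace", weight="bold")
        fig, ax = plt.subplots(figsize=(6, 3))
        for j in range(CORE_LEN):
            y = 0.0
            for a in np.argsort(pwm[j]):
                h = pwm[j, a] * ic[j]
                if h < 1e-3:
                    continue
                tp = TextPath((0, 0), AA_ALPHABET[a], size=1.0, prop=fp)
                bb = tp.get_extents()
                tr = (Affine2D()
                      .translate(-bb.x0, -bb.y0)
                      .scale(0.9 / bb.width, h / bb.height)
                      .translate(j + 0.05, y))
                ax.add_patch(PathPatch(tr.transform_path(tp), lw=0,
                                       color=plt.cm.tab20(a % 20)))
                y += h
        ax.set_xlim(0, CORE_LEN)
        ax.set_ylim(0, max(np.log2(20), ic.max() + 0.1))
        ax.set_xticks(np.arange(CORE_LEN) + 0.5,
                      [str(j + 1) for j in range(CORE_LEN)])
        ax.set_ylabel("bits")
        ax.set_title(f"motif {k} ({self.consensus(k)})")
        path = out_dir / f"motif_{k}_logo.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return str(path)

    def summary(self) -> str:
        lines = [f"Motif mixture: K={self.n_motifs}, "
                 f"n={self.n_sequences}, iterations={self.n_iter}",
                 f"  objective (penalized loglik): {self.loglik:.3f}"]
        for k in range(self.n_motifs):
            lines.append(
                f"  motif {k}: weight={self.mixture_weights[k]:.3f} "
                f"consensus={self.consensus(k)} "
                f"modal offset={int(self.offset_priors[k].argmax())}")
        lines.append(f"  background weight={self.mixture_weights[-1]:.3f}")
        return "\n".join(lines)


def _log_joint(S, lengths, pwms, offset_priors, mixture_weights, background):
    """Per-sequence log joint over (motif, offset) cells + background.

    Returns (n, K*O + 1); inadmissible offsets are -inf.  The shared
    whole-sequence background term is included in every cell, so rows
    exponentiate to unnormalized posteriors.
    """
    n, Lmax = S.shape
    K = pwms.shape[0] if pwms is not None else 0
    # neutral emission for padding/X
    bg21 = np.append(background, 1.0)
    logbg = np.log(bg21)
    bg_total = logbg[S].sum(axis=1)                     # (n,)
    if K == 0:
        return (bg_total + np.log(1.0))[:, None]
    O = offset_priors.shape[1]
    theta21 = np.concatenate([pwms, np.ones((K, CORE_LEN, 1))], axis=2)
    logtheta = np.log(theta21)                          # (K, 9, 21)
    admissible = lengths[:, None] - CORE_LEN >= np.arange(O)[None, :]
    logw = np.log(mixture_weights)
    logprior = np.log(offset_priors)
    out = np.full((n, K * O + 1), -np.inf)
    for k in range(K):
        for o in range(O):
            if o + CORE_LEN > Lmax:
                continue
            win = S[:, o:o + CORE_LEN]
            bg_win = logbg[win].sum(axis=1)
            core = logtheta[k, np.arange(CORE_LEN), win].sum(axis=1)
            cell = bg_total - bg_win + core + logw[k] + logprior[k, o]
            out[:, k * O + o] = np.where(admissible[:, o], cell, -np.inf)
    out[:, -1] = bg_total + logw[K]
    return out


class MotifMixture:
    """Mixture-of-PWMs deconvolution model over extended peptides.

    Parameters
    ----------
    extended : list of str
        Flank-extended peptides (see :func:`extend_peptides`); every
        sequence must be at least 9 residues.
    n_motifs : int
        Number of PWM components K (>= 0); a flat background component
        is always included.
    """

    def __init__(self, extended: list[str], n_motifs: int):
        if not extended:
            raise ValueError("no sequences to deconvolve")
        if n_motifs < 0:
            raise ValueError("n_motifs must be >= 0")
        self.sequences = list(extended)
        self.S, self.lengths = _as_indices(self.sequences)
        if (self.lengths < CORE_LEN).any():
            raise ValueError(f"all sequences must be >= {CORE_LEN} residues")
        self.n_motifs = n_motifs
        self.background = _background_freqs(self.S)
        n_distinct = len(set(self.sequences))
        if n_motifs > n_distinct:
            import warnings
            warnings.warn(
                f"K={n_motifs} exceeds {n_distinct} distinct sequences; "
                "fit proceeds but components may be degenerate")

    @classmethod
    def from_dataset(cls, data: Dataset, n_motifs: int,
                     proteome: dict[str, str] | None = None
                     ) -> "MotifMixture":
        return cls(extend_peptides(data, proteome), n_motifs)

    # -- EM --------------------------------------------------------------
    def fit(self, restarts: int = 10, seed: int = 0,
            tol: float = TOL, max_iter: int = MAX_ITER
            ) -> MotifMixtureResults:
        """Run EM from `restarts` random initializations; keep the best
        penalized log-likelihood.  Deterministic given `seed`."""
        if restarts < 1:
            raise ValueError("restarts must be >= 1")
        best: MotifMixtureResults | None = None
        for r in range(restarts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
            res = self._fit_once(rng, tol, max_iter)
            if best is None or res.loglik > best.loglik:
                best = res
        return best

    def _fit_once(self, rng, tol, max_iter) -> MotifMixtureResults:
        n = self.S.shape[0]
        K = self.n_motifs
        O = int(self.lengths.max()) - CORE_LEN + 1
        if K == 0:
            lj = _log_joint(self.S, self.lengths, np.empty((0, CORE_LEN, 20)),
                            None, np.array([1.0]), self.background)
            ll = float(lj[:, -1].sum())
            return MotifMixtureResults(0, np.empty((0, CORE_LEN, 20)),
                                       np.empty((0, 0)), np.array([1.0]),
                                       self.background, ll, [ll], n, 0)
        pwms = self._init_pwms(rng, K)
        priors = np.full((K, O), 1.0 / O)
        weights = np.full(K + 1, 1.0 / (K + 1))
        params, obj, trace, iters = self._em(pwms, priors, weights,
                                             tol, max_iter)
        segments = [trace]
        # register refinement: motif EM often converges with the core
        # phase-shifted; try column-shifted restarts and keep gains
        improved = True
        while improved:
            improved = False
            for shift in (-3, -2, -1, 1, 2, 3):
                shifted = self._shift_params(*params, shift)
                if shifted is None:
                    continue
                p2, o2, t2, i2 = self._em(*shifted, tol, max_iter)
                if o2 > obj + tol * n:
                    params, obj, iters = p2, o2, iters + i2
                    segments.append(t2)
                    improved = True
        pwms, priors, weights = params
        return MotifMixtureResults(K, pwms, priors, weights, self.background,
                                   obj, segments[-1], n, iters,
                                   em_segments=segments)

    def _em(self, pwms, priors, weights, tol, max_iter):
        n = self.S.shape[0]
        K = self.n_motifs
        O = priors.shape[1]
        trace: list[float] = []
        prev = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            lj = _log_joint(self.S, self.lengths, pwms, priors, weights,
                            self.background)
            norm = logsumexp(lj, axis=1, keepdims=True)
            obj = float(norm.sum()) + self._penalty(pwms, priors)
            trace.append(obj)
            resp = np.exp(lj - norm)                    # (n, K*O+1)
            if abs(obj - prev) < tol * n:
                prev = obj
                break
            prev = obj
            pwms, priors, weights = self._m_step(resp, K, O)
        return (pwms, priors, weights), prev, trace, it

    def _shift_params(self, pwms, priors, weights, shift):
        """Shift every PWM's columns by `shift` positions (vacated
        columns become background) with the matching offset-prior
        shift; None when the prior support would vanish."""
        K, O = priors.shape
        new_pwms = np.empty_like(pwms)
        for j in range(CORE_LEN):
            src = j - shift
            if 0 <= src < CORE_LEN:
                new_pwms[:, j] = pwms[:, src]
            else:
                new_pwms[:, j] = self.background
        new_priors = np.full((K, O), OFFSET_FLOOR)
        for o in range(O):
            src = o + shift
            if 0 <= src < O:
                new_priors[:, o] += priors[:, src]
        total = new_priors.sum(axis=1, keepdims=True)
        if (total <= 0).any():
            return None
        new_priors /= total
        return new_pwms, new_priors, weights.copy()

    def _init_pwms(self, rng, K) -> np.ndarray:
        """Seed each component from a random data 9-mer: a moderately
        peaked PWM around an observed window escapes the flat local
        optima that uninformative initialization falls into."""
        n = self.S.shape[0]
        pwms = np.full((K, CORE_LEN, 20), 0.6 / 19)
        for k in range(K):
            i = int(rng.integers(n))
            o = int(rng.integers(self.lengths[i] - CORE_LEN + 1))
            win = self.S[i, o:o + CORE_LEN]
            for j in range(CORE_LEN):
                if win[j] < 20:
                    pwms[k, j, win[j]] = 0.4
                else:
                    pwms[k, j, :] = 1.0 / 20
            pwms[k] /= pwms[k].sum(axis=1, keepdims=True)
        return pwms

    def _penalty(self, pwms, priors) -> float:
        return (PSEUDOCOUNT * np.log(pwms).sum()
                + OFFSET_FLOOR * np.log(priors).sum())

    def _m_step(self, resp, K, O):
        n, Lmax = self.S.shape
        r = resp[:, :-1].reshape(n, K, O)
        pwm_counts = np.full((K, CORE_LEN, 20), PSEUDOCOUNT)
        for o in range(O):
            if o + CORE_LEN > Lmax:
                continue
            win = self.S[:, o:o + CORE_LEN]             # (n, 9)
            w = r[:, :, o]                              # (n, K)
            valid = win < 20                            # X emits nothing
            for j in range(CORE_LEN):
                v = valid[:, j]
                if not v.any():
                    continue
                for k in range(K):
                    np.add.at(pwm_counts[k, j], win[v, j], w[v, k])
        pwms = pwm_counts / pwm_counts.sum(axis=2, keepdims=True)
        prior_counts = r.sum(axis=0) + OFFSET_FLOOR     # (K, O)
        priors = prior_counts / prior_counts.sum(axis=1, keepdims=True)
        mass = np.concatenate([r.sum(axis=(0, 2)), [resp[:, -1].sum()]])
        weights = mass / mass.sum()
        return pwms, priors, weights


def fit_motifs(extended: list[str], n_motifs: int, restarts: int = 10,
               seed: int = 0) -> MotifMixtureResults:
    """Convenience wrapper: build and fit a :class:`MotifMixture`."""
    return MotifMixture(extended, n_motifs).fit(restarts=restarts, seed=seed)
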