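"""Synthetic two-domain ligandome generator.

Every pipeline stage gets a statistically controlled test bed: peptides
are built by embedding 9-mer cores sampled from planted per-allele PWMs
at offsets drawn from a decaying offset-preference prior, inside
background flanks; presentation positives carry proline/alanine
cleavage enrichment within two residues of their termini; source genes
get log-normal TPM values; and the immunogenicity domain is shifted
away from the presentation domain by blending the planted PWM and the
background composition with perturbed versions, at a controlled
strength.

What this emulates: the compositional structure of eluted-ligand data
(core motif + offset preference + flank signature) and a label/covariate
shift between domains.  What it does not: mass-spectrometry acquisition
bias, real allele-specific anchor chemistry, or peptide abundance
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (AA_ALPHABET, Dataset, PeptideRecord, AllelePseudosequence,
                 DOMAIN_ANTIGENIC, DOMAIN_IMMUNOGENIC, write_peptide_table)
from .motif import CORE_LEN, FLANK

N_AA = 20
_AA = np.array(list(AA_ALPHABET))


@dataclass
class SimConfig:
    """Study conditions of the synthetic ligandome."""

    n_alleles: int = 1
    motifs_per_allele: int = 1
    pwm_sharpness: float = 0.1       # Dirichlet concentration; lower=sharper
    offset_decay: float = 0.6        # geometric decay of the offset prior
    n_pos: int = 250                 # positives per domain
    n_neg: int = 250                 # negatives per domain
    domain_shift_strength: float = 0.5   # in [0, 1]
    cleavage_enrichment: float = 0.6     # P/A boost near hit termini
    tpm_mu: float = 1.5              # log-normal TPM, natural-log scale
    tpm_sigma: float = 1.0
    length_range: tuple[int, int] = (12, 19)
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_alleles) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.domain_shift_strength <= 1.0:
            raise ValueError("domain_shift_strength must be in [0, 1]")
        lo, hi = self.length_range
        if lo > hi or lo < CORE_LEN:
            raise ValueError(
                f"length_range {self.length_range} incompatible with a "
                f"{CORE_LEN}-mer core")

    @classmethod
    def separable(cls, **overrides) -> "SimConfig":
        """The cleanly separable presentation task: near-deterministic
        anchor residues, offsets concentrated at the N-terminal
        register, mid-range lengths, no label noise.  Used for training
        smoke checks where the signal itself must not be the limiting
        factor."""
        base = dict(pwm_sharpness=0.02, offset_decay=0.3,
                    length_range=(13, 17), label_noise=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Generative parameters, for recovery tests."""

    pwms: np.ndarray                 # (n_alleles, K, 9, 20)
    im_pwms: np.ndarray              # shifted PWMs of the IM domain
    offset_prior: np.ndarray         # (O,)
    background: np.ndarray           # (20,)
    im_background: np.ndarray
    core_offsets: dict[str, list[int]] = field(default_factory=dict)
    generative_scores: dict[str, np.ndarray] = field(default_factory=dict)


def _sample_pwms(rng, cfg: SimConfig) -> np.ndarray:
    return rng.dirichlet(np.full(N_AA, cfg.pwm_sharpness),
                         size=(cfg.n_alleles, cfg.motifs_per_allele,
                               CORE_LEN))


def _offset_prior(cfg: SimConfig) -> np.ndarray:
    O = cfg.length_range[1] + 2 * FLANK - CORE_LEN + 1
    p = cfg.offset_decay ** np.arange(O)
    return p / p.sum()


def _shift_pwm(pwm: np.ndarray, s: float, rng) -> np.ndarray:
    """Blend each motif with a residue-permuted copy, weight s."""
    perm = rng.permutation(N_AA)
    return (1 - s) * pwm + s * pwm[..., perm]


def _random_seq(rng, freqs: np.ndarray, n: int) -> str:
    return "".join(_AA[rng.choice(N_AA, size=n, p=freqs)])


def _pwm_loglik(extended: str, pwm: np.ndarray, prior: np.ndarray,
                background: np.ndarray) -> float:
    """Best-offset log-odds of a sequence under one motif.

    Positions outside the 20-letter alphabet (X padding) are neutral.
    """
    idx = [AA_ALPHABET.index(a) if a in AA_ALPHABET else -1
           for a in extended]
    best = -np.inf
    for o in range(len(idx) - CORE_LEN + 1):
        ll = np.log(prior[o]) if o < len(prior) else -np.inf
        for j in range(CORE_LEN):
            a = idx[o + j]
            if a >= 0:
                ll += np.log(max(pwm[j, a], 1e-12) / background[a])
        best = max(best, ll)
    return best


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[Dataset, Dataset, GroundTruth]:
    """Generate (antigenic, immunogenic, ground_truth).

    Both domains contain ``n_pos`` positives and ``n_neg`` negatives
    per allele.  At ``domain_shift_strength=0`` the two domains follow
    identical generative rules.
    """
    rng = np.random.default_rng(cfg.seed)
    pwms = _sample_pwms(rng, cfg)
    prior = _offset_prior(cfg)
    # skewed like real proteome composition (Leu-rich, Trp/Cys-poor)
    background = rng.dirichlet(np.full(N_AA, 3.0))
    s = cfg.domain_shift_strength
    im_pwms = np.stack([
        np.stack([_shift_pwm(pwms[a, k], s, rng)
                  for k in range(cfg.motifs_per_allele)])
        for a in range(cfg.n_alleles)])
    bg_perm = rng.permutation(N_AA)
    im_background = (1 - s) * background + s * background[bg_perm]

    truth = GroundTruth(pwms=pwms, im_pwms=im_pwms, offset_prior=prior,
                        background=background, im_background=im_background)
    alleles = {}
    for a in range(cfg.n_alleles):
        name = f"DRB1*{90 + a:02d}:01"
        alleles[name] = AllelePseudosequence(
            name=name,
            short_seq=_random_seq(rng, background, 34),
            full_seq=_random_seq(rng, background, 269))
    allele_names = sorted(alleles)

    def make_domain(domain: str, dom_pwms, dom_bg) -> Dataset:
        records = []
        offsets = []
        gen_scores = []
        for a, name in enumerate(allele_names):
            for i in range(cfg.n_pos + cfg.n_neg):
                positive = i < cfg.n_pos
                L = int(rng.integers(cfg.length_range[0],
                                     cfg.length_range[1] + 1))
                ext_len = L + 2 * FLANK
                seq = list(_random_seq(rng, dom_bg, ext_len))
                offset = None
                if positive:
                    k = int(rng.integers(cfg.motifs_per_allele))
                    O_s = ext_len - CORE_LEN + 1
                    p = prior[:O_s] / prior[:O_s].sum()
                    offset = int(rng.choice(O_s, p=p))
                    for j in range(CORE_LEN):
                        seq[offset + j] = _AA[
                            rng.choice(N_AA, p=dom_pwms[a, k, j])]
                seq = "".join(seq)
                nf, pep, cf = seq[:FLANK], seq[FLANK:-FLANK], seq[-FLANK:]
                if positive and rng.random() < cfg.cleavage_enrichment:
                    # P/A within two residues of each terminus
                    nf = nf[:2] + rng.choice(["P", "A"])
                    cf = rng.choice(["P", "A"]) + cf[1:]
                label = int(positive)
                if rng.random() < cfg.label_noise:
                    label = 1 - label
                gene = f"GENE{rng.integers(0, 500):04d}"
                records.append(PeptideRecord(
                    peptide=pep, allele=name, label=label, gene=gene,
                    n_flank=nf, c_flank=cf, domain=domain,
                    source="simulated"))
                offsets.append(offset)
                gen_scores.append(_pwm_loglik(nf + pep + cf, dom_pwms[a, 0],
                                              prior, background))
        truth.core_offsets[domain] = offsets
        truth.generative_scores[domain] = np.array(gen_scores)
        return Dataset(records, alleles=alleles)

    antigenic = make_domain(DOMAIN_ANTIGENIC, pwms, background)
    immunogenic = make_domain(DOMAIN_IMMUNOGENIC, im_pwms, im_background)
    return antigenic, immunogenic, truth


def simulate_proteome(n_proteins: int = 100, length: int = 400,
                      seed: int = 0,
                      background: np.ndarray | None = None
                      ) -> dict[str, str]:
    """Random protein sequences for decoy generation and flank lookup."""
    rng = np.random.default_rng(seed)
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    return {f"PROT{i:04d}": _random_seq(rng, background, length)
            for i in range(n_proteins)}


def simulate_expression_table(genes: set[str], cfg: SimConfig,
                              seed: int | None = None) -> dict[str, float]:
    """Log-normal TPM per gene."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return {g: float(rng.lognormal(cfg.tpm_mu, cfg.tpm_sigma))
            for g in sorted(genes)}


def write_fasta(proteome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(proteome):
            fh.write(f">{name}\n")
            seq = proteome[name]
            for lo in range(0, len(seq), 60):
                fh.write(seq[lo:lo + 60] + "\n")


def emit_files(cfg: SimConfig, out_dir) -> dict[str, str]:
    """Run the generator and write the module-standard files.

    Writes antigenic.tsv, immunogenic.tsv, pseudosequences.tsv,
    proteome.fasta and expression.tsv; returns their paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    antigenic, immunogenic, truth = simulate_dataset(cfg)
    paths = {
        "antigenic": str(out / "antigenic.tsv"),
        "immunogenic": str(out / "immunogenic.tsv"),
        "pseudosequences": str(out / "pseudosequences.tsv"),
        "proteome": str(out / "proteome.fasta"),
        "expression": str(out / "expression.tsv"),
    }
    write_peptide_table(antigenic, paths["antigenic"])
    write_peptide_table(immunogenic, paths["immunogenic"])
    with open(paths["pseudosequences"], "w") as fh:
        fh.write("allele\tshort_seq\tfull_seq\n")
        for name, ap in sorted(antigenic.alleles.items()):
            fh.write(f"{name}\t{ap.short_seq}\t{ap.full_seq}\n")
    write_fasta(simulate_proteome(seed=cfg.seed), paths["proteome"])
    genes = {r.gene for r in antigenic.records + immunogenic.records}
    table = simulate_expression_table(genes, cfg)
    with open(paths["expression"], "w") as fh:
        fh.write("gene\ttpm\n")
        for g, t in table.items():
            fh.write(f"{g}\t{t:.6f}\n")
    return paths
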