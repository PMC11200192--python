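# mhc2learn

Modelling of HLA class II epitope **presentation** and
**immunogenicity** from peptide x allele data: PWM-mixture motif
deconvolution of variable-length ligands, an attention-based
presentation model fused with processing features, and conditional
domain-adversarial transfer to the T-cell immunogenicity domain, with
a decoy-based PPVn evaluation protocol and a fully synthetic test bed.

It is written for computational immunologists who want the machinery of
modern class II epitope predictors — binding-core deconvolution,
sequence encoders with bilinear attention, cleavage and expression
branches, adversarial domain transfer — as an inspectable, CPU-friendly
library rather than a black-box service.

## The models

**Motif deconvolution.** Class II ligands of length 12–19 are extended
with 3 residues of flanking context and modelled as a mixture of K
position weight matrices (9-mer binding cores) with offset-preference
priors plus a flat background:

    P(s) = sum_k pi_k sum_o rho_k(o) prod_j theta_k(j, s[o+j])
           prod_{i not in core} b(s[i])  +  pi_bg prod_i b(s[i])

fitted by restarted EM with register refinement. The per-peptide
maximum-responsibility (motif, offset) pair yields the binding-core
offset feature.

**Presentation (EL) model.** Peptide and allele-pseudosequence branches
(three pre-norm transformer encoders each, 12-head attention) are
coupled by low-rank bilinear attention; a 128-64-32 dense head outputs
the presentation probability. The final score fuses four branches with
fixed weights — sequence 0.60, expression 0.12, cleavage 0.12, core
offset 0.16 — and can be calibrated to a percentile rank against a
random proteome background.

**Immunogenicity (IM) model.** The presentation feature extractor F is
transferred with a fresh decoder G under a conditional
domain-adversarial objective: a discriminator D sees the multilinear
map h = f (x) g and learns the domain, while F and G are trained
through a gradient-reversal layer (weight omega) to confuse it:

    min_D max_{F,G} -( L_cls(F,G) - omega * L_adv(F,G,D) )

i.e. D minimizes the domain cross-entropy, F and G minimize the
classification losses minus omega times it.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```sh
mhc2learn simulate --out sim --seed 1 --n-pos 150 --n-neg 150 --separable
mhc2learn train-el --data sim/antigenic.tsv \
    --pseudosequences sim/pseudosequences.tsv \
    --epochs 3 --d-model 24 --lr 3e-3 --seed 1 --out el
```

prints

```
Presentation model (3 encoders/branch, 12 heads, d_model=24, bilinear rank 32)
  parameters : 48826
  folds run  : 1
  mean val loss: 0.0897
  mean val AUC : 0.9938
```

— the model separates planted-motif ligands from background peptides
almost perfectly (validation AUC 0.99) on the cleanly separable
simulated task. Transferring to the (compositionally shifted)
immunogenicity domain:

```sh
mhc2learn train-im --antigenic sim/antigenic.tsv \
    --immunogenic sim/immunogenic.tsv \
    --el-checkpoint el/el_checkpoint.npz --epochs 4 --seed 1 --out im
```

```
Immunogenicity model (adversarial transfer)
  omega=1.0, epochs=4, batch_size=32
  final losses: L_a=0.1326 L_i=0.3091 L_adv=0.6696
  discriminator domain accuracy: 0.575
```

A domain accuracy near 0.5 means the discriminator can no longer tell
which domain a representation came from — the features have been
aligned. `mhc2learn predict` then scores records (optionally fusing an
expression table and appending proteome decoys) and
`mhc2learn evaluate` writes AUC/AUPR/F1/B.Acc and PPVn with locus and
length strata. The same classes are available as a library
(`ElPresentationModel(...).fit()`, `CdanTransfer(...).fit()`,
`MotifMixture(...).fit()`), each returning a results object with
`summary()`.

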