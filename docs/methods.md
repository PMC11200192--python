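# Methods

`mhc2learn` models HLA class II epitope presentation and immunogenicity
as a two-stage pipeline: a presentation model trained on eluted-ligand
style peptide x allele observations, transferred to the immunogenicity
domain by conditional domain-adversarial training. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic test bed does and does not establish.

## Data model

An observation is a peptide (11–19 residues over the 20-letter amino
acid alphabet) paired with a normalized class II allele, a binary
label, an optional source gene and up to three residues of flanking
context on each side, tagged with its domain: `antigenic`
(mass-spectrometry presentation evidence) or `immunogenic` (T-cell
assay evidence). Allele names are canonicalized to `LOCUS*GG:PP`;
DQ and DP heterodimers are written as `alpha/beta` pairs joined by
"/". Records without explicit four-digit typing cannot be matched to
a pseudosequence and are dropped by the curation step.

Immunogenicity curation applies, in order: four-digit-typing filter,
peptide length restriction to [11, 19] (inclusive; the presentation
side uses [12, 19], both configurable), removal of records whose label
lacks assay support (only when an `assay_supported` column exists),
removal of beta-chain-only DP entries, and collapse of duplicate
peptide x allele groups — conflicting labels collapse to a single
positive, reflecting the one-sided reliability of T-cell assays: a
reproducible positive outweighs a failed replicate.

Cross-validation assigns folds at the level of unique peptide strings,
so a peptide never appears on both sides of a fold boundary; within
each training fold a 4:1 train/validation split (also peptide-level)
drives epoch selection.

## Encodings

Peptides: one-hot over 21 channels (20 residues + padding X) and
BLOSUM62 rows (20 scores + padding indicator), channel-concatenated to
42 features per position, padded to 19 positions. Alleles: the
34-residue contact pseudosequence, same 42-channel encoding. The
269-residue groove sequence supports an optional preferential-
interaction encoding: per residue, `exp(-d/sigma)` over a fixed panel
of 34 anchor positions of a residue-pair C-alpha distance table
(`sigma` = 8 A — the scale of a contact shell), concatenated with the
residue's BLOSUM62 row. The distance table is an input, not code; a
synthetic table is generated in tests.

## Presentation model

Each branch (peptide, allele) is three pre-norm transformer encoder
blocks with 12-head self-attention and learned positional embeddings;
widths are `d_model` (default 96 = 12 x 8). The branches are coupled
by low-rank bilinear attention (rank 32): projected, tanh-squashed
position features form a pairwise interaction map, softmax-normalized
jointly over (peptide position, HLA residue) cells, which pools a
rank-sized joint representation. The map itself is retained and
exported for interpretability (row-normalized per peptide position,
plus a per-HLA-residue marginal). A 128-64-32 dense head with a
two-unit softmax yields the presentation probability. Training:
AdamW on cross-entropy, learning rate within [1e-5, 1e-2] (3e-3 at
desk scale), batch size 32, best-validation-loss epoch kept.

### Branch fusion

The final score is a fixed convex combination of four branch scores,
each in [0, 1]: sequence 60%, gene expression 12%, cleavage 12%,
binding-core offset 16%. A missing branch renormalizes the remaining
weights. Percentile ranks are computed against an allele-specific
random-background score sample (fraction scoring strictly higher;
lower = stronger); the fused score is the ranked quantity.

The expression branch transforms TPM as `log10(X + 10^6)` (so 0 TPM
maps to exactly 6.0); note this compresses all biological TPM ranges
into roughly [6, 6.3] — it is implemented exactly as specified, with
the conventional `log10(X + 1)` available behind a flag as documented
non-default behaviour. For fusion, which needs [0, 1], the branch
score is the saturating `X / (X + 50)` with its half-point at the
50-TPM vaccine reference (0 at no expression, 0.5 at the vaccine
reference, approaching 1 for abundant transcripts). Genes without
expression values exclude the record; vaccine-candidate scoring fixes
TPM at 50.

The cleavage branch scores two 6-residue windows (three residues either
side of each peptide terminus, N-to-C order, X-padded at protein ends)
with a two-layer 32-unit dense network and logistic output, trained
against length-matched decoy windows by AdamW/BCE. Background
composition is the per-position decoy frequency table.

## Motif deconvolution

Extended peptides (3-residue flanks on both sides, X-padded when
unknown) are modelled as a mixture of K PWM motifs of core length 9
with per-motif offset-preference priors, plus a flat background
component. Offsets are 0-based from the start of the extended
sequence; the prior is a single distribution over the global offset
range, restricted per sequence to admissible offsets. Emission of X is
neutral (probability 1 under both motif and background), so unknown
context neither favours nor penalizes any component.

EM details: pseudocount 0.1 per PWM cell and offset-prior floor 1e-3
(MAP-EM; the reported objective is the penalized log-likelihood, which
is guaranteed non-decreasing per iteration — the raw likelihood can in
principle dip under MAP smoothing). Convergence at |delta| <
1e-6 x n or 500 iterations. Each restart seeds its PWMs from a random
observed 9-mer window (0.4 on the observed residue, rest uniform);
uninformative Dirichlet starts were found to lock onto flat local
optima. After convergence, register refinement tries column-shifted
restarts (±1..3 positions, vacated columns filled with background, the
offset prior shifted to match) and keeps improvements — motif EM's
classic phase ambiguity is otherwise a frequent local optimum. Default
10 restarts at desk scale (configurable to the 250 a production
deconvolution run would use). K is chosen by the caller; fitting
K = 1..Kmax and comparing AIC is supported through the reported
objective.

The binding-core-offset branch score of a peptide is its assigned
motif's prior probability at the assigned offset, normalized by that
motif's modal prior (so the modal offset scores 1); background
assignments carry no offset preference and score 1. The offset
preference is per-motif rather than per-allele: motif-to-allele
annotation is left to caller metadata.

## Adversarial transfer (immunogenicity model)

The presentation model's feature extractor F (encoders + bilinear
attention) is copied and fine-tuned with a fresh immunogenicity
decoder G (one hidden layer of 32, softmax) under a conditional
domain-adversarial objective: a three-layer discriminator D receives
the multilinear conditional representation `h = f (x) g` (flattened
outer product up to a width cap of 1024, beyond which a seed-fixed
randomized multilinear projection is used) and is trained to classify
the domain; F and G receive the discriminator's gradient through a
reversal layer with weight `omega` (default 1.0, linear warm-up over
the first 10% of steps). D minimizes the domain cross-entropy while
F, G minimize classification losses minus `omega` times it — the
standard minimax direction. Because the immunogenicity set is
labelled, a target-supervised term is included by default
(`target_supervised=True`). Batches always contain both domains
(32 records each); training runs 30 epochs by default. Divergence
(non-finite loss) aborts with the three loss terms in the message.

Diagnostics: `discriminator_accuracy()` reads the jointly trained D at
the adversarial equilibrium (0.5 = fully confused);
`probe_discriminator_accuracy()` trains a fresh discriminator to
convergence on the *frozen* final representations — the appropriate
readout for a model trained without the adversarial coupling, whose
features are stationary. The no-coupling control (`fit(adversarial=
False)`) still trains D alongside F and G, but its gradient never
reaches them.

## Evaluation protocol

AUC, AUPR, F1 and balanced accuracy use the standard definitions
(threshold 0.5 on the probability scale for the thresholded metrics).
PPVn ranks the pooled hit + decoy set, takes the top `ceil(fraction x
n)` (ties broken by stable record order) and reports, by default, the
precision reading — the fraction of the top-k that are true hits; the
recall reading (fraction of all hits recovered) is available and
labelled in output headers. Precision is the default because it is
the only reading under which performance can fall as the fraction
grows, matching how the metric is used in practice. Decoys are
length-matched uniform random proteome substrings, 98 per hit by
default, never equal to any hit sequence and never containing
non-standard residues. The neoantigen core scan scores every 9-mer
window of an 18-mer oligomer (exactly 10 windows) and returns the
argmax, ties to the smallest offset. Stratified reports break metrics
down by locus (DR vs DQ&DP; the pan stratum is the overall row) and
peptide length; single-class strata report NaN, never zero.

## Synthetic test bed

The generator plants one or more 9-mer PWMs per allele (per-position
Dirichlet with concentration `pwm_sharpness`; 0.1 by default — peaked
but not deterministic anchors), samples core offsets from a truncated
geometric prior (decay 0.6), embeds cores in background sequence
(Dirichlet(3) composition — skewed like real proteomes), and draws
peptide lengths uniformly on [12, 19]. Positives get proline/alanine
enrichment within two residues of their termini with probability
`cleavage_enrichment` (0.6). Labels follow the construction with a 5%
flip rate. TPM values are log-normal (mu=1.5, sigma=1.0 on the natural
log scale — median ~4.5 TPM with a heavy right tail). The
immunogenicity domain is shifted by blending both the planted PWMs and
the background with residue-permuted copies at weight
`domain_shift_strength`; at 0 the domains follow identical rules, at 1
the compositions are fully permuted. A `separable()` preset (sharpness
0.02, offset decay 0.3, lengths 13–17, no label noise) provides the
cleanly learnable presentation task used for training smoke checks,
where the signal itself must not be the limiting factor.

What passing on this bed shows: the estimators recover planted
structure, the losses optimize what they claim, the transfer stage
aligns what it claims to align. What it does not show: performance on
real ligandomes — the generator has no mass-spectrometry acquisition
bias, no shared anchor chemistry across alleles, no peptide-abundance
or multi-allele deconvolution effects, and its domain shift is a
clean compositional permutation rather than the messy biological shift
between presentation and T-cell recognition.

## Problem sizes and numerical choices

Desk-scale runs use `d_model=24` (12 heads x 2), 150–1000 records per
class, 3–12 epochs; these keep every check on a single CPU core in
minutes while exercising the full architecture. The printed defaults
(`d_model=96`, 30 epochs) are what a production run would use.
All randomness flows from explicit integer seeds through
`numpy.random.Generator`; training is shuffle-invariant given the
seed because batch order is drawn from the seeded generator, never
from input order. Floating point is float64 throughout the network
stack — gradient checks against finite differences hold to ~1e-7.

## Known limitations

- The full-269-residue distance encoding is optional and off the
  default path; no curated distance table ships with the package.
- Motif-to-allele assignment is metadata-driven; multi-allele samples
  are not deconvolved per allele.
- The randomized multilinear map is only exercised above the width
  cap, which desk-scale models do not reach.
- PWM mixture EM is seeded and restarted but, like all EM, not
  guaranteed to find the global optimum; the register-refinement step
  removes the most common failure mode, not all of them.
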