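# Methods

## The model

CLIP tag density on a transcript scales with the transcript's abundance in
the profiled cell type, so raw tag counts conflate binding with expression.
The analysis assumes a log-linear relation between CLIP and
ribosome-associated abundance,

    y_gr = a_r + b_r * x_gc + beta_g + eps_gr,     eps_gr ~ N(0, sigma^2)

where `y_gr` is log2 CLIP TPM of transcript *g* in CLIP replicate *r*,
`x_gc` is the mean log2 RiboTag TPM of the matching condition *c*, `(a_r,
b_r)` are fitted per replicate by ordinary least squares, and `beta_g` is
the transcript's binding offset — the quantity of interest. The CLIP score
estimates `beta_g` up to a replicate constant:

* `as_printed` (default): `score = y − b·x + a`, the form in which the
  score is conventionally written; it equals the OLS residual **plus 2a**.
  Because the
  tier thresholds (2 / 1 / 0) are fixed, the 2a offset shifts all
  transcripts relative to the tiers; with real data the fitted intercept is
  part of the measurement, so the published thresholds embed it.
* `residual`: `score = y − (b·x + a)`, exactly mean-centered per replicate.
  Planted offsets are commensurate with the thresholds only under this
  convention, so the recovery analyses use it. The two conventions never
  reorder transcripts within a replicate.

Tiers are strict: stringent means score > 2 (in every replicate under
`per_replicate`, the default; on the replicate mean under `mean` — both
definitions are in use in the field and the mode is configurable), high means
mean score in (1, 2], low in (0, 1]; a transcript whose mean exceeds 2 but
which fails replicate-level stringency is reported as high. Transcripts
with zero CLIP TPM in a replicate are excluded from that replicate's fit
and carry a missing score there; a missing replicate score blocks
per-replicate stringency.

Differential binding uses the Smyth empirical-Bayes moderated t on
per-replicate scores: per-transcript pooled variances `s_g^2` (df `d_g`)
are shrunk toward a scaled-F prior whose parameters `(d0, s0^2)` come from
closed-form moments of `log s_g^2` (trigamma inversion by Newton's method,
d0 capped at 1e6). The implementation reproduces Bioconductor limma
(`lmFit` + `eBayes`, no trend, no robustification) to ~1e-14 on the same
input; the test suite uses limma through `Rscript` as the independent
oracle. FMRP-Down/Up are called at raw p < 0.05 by default (the padj
variant is configurable), while RiboTag calls use BH padj < 0.05.

Differential ribosome association is a deliberately minimal two-group NB
Wald test: DESeq2-style median-of-ratios size factors (log-space median,
rescaled to geometric mean 1), gene-wise method-of-moments dispersion
(floor 1e-8, no trend shrinkage), group means from normalized counts, and
a delta-method SE for the log2 fold change with two-sided normal p. Fold
changes agree with pydeseq2 to < 0.05 on well-covered genes; small-sample
raw p-values are anticonservative (a known property without dispersion
shrinkage at n = 3), which is why significance is called on BH-adjusted
p-values. Genes with an all-zero group get a pseudo-mean (0.5 normalized
counts) and are flagged rather than dropped.

The quadrant model joins the two differentials on the
one-transcript-per-gene universe and cross-classifies by direction
(FMRP down/up/unchanged x ribosome up/down/unchanged); there is no
fold-change floor on RiboTag calls by default (`ribo_lfc_floor = 0`).

Tag annotation assigns each genome-mapped tag one label by maximal
strand-matched base overlap, precedence CDS > 3'UTR > 5'UTR >
noncoding_exon > intron > intergenic on exact ties. Biological complexity
collapses tags to sites by exact 5'-end match on the same strand (a merge
window is configurable) and counts supporting replicates; gene-level BC
counts replicates with >= 5 tags on the gene.

## Synthetic data

The generator emulates the processed-level structure of the study design:
2 conditions x 4 CLIP replicates and 2 conditions x 3 RiboTag replicates
(IP + Input). Defaults (all in `GeneratorParams`):

| parameter | default | rationale |
|---|---|---|
| n_genes | 5000 | desk-scale while keeping per-transcript counts realistic |
| slope b / intercept a | 1.0 / −2.0 | a unit log-log relation with CLIP efficiency below RiboTag |
| clip_noise_sd sigma | 0.5 log2 units | free choice; no empirical dispersion is published for the score |
| clip/ribo library size | 2e6 | ~400 tags per transcript, matching low-input CLIP depth |
| nb_dispersion | 0.05 | typical biological-replicate overdispersion for bulk counts |
| frac stringent / fmrp_down / fmrp_up | 0.06 / 0.05 / 0.01 | mirrors the reported class proportions (roughly 900/700/130 of 14k) |
| binding_offset, binding_shift | 3.0 | clears the stringent threshold by 1 score unit |
| ribo_effect | 1.0 | a twofold ribosome-association change |
| p(ribo change given FMRP-Down) | 0.125 up / 0.096 down | ribosome changes concentrate among FMRP-Down transcripts |

RiboTag Input counts are NB around length-weighted TPM shares; IP means
add a ±2 log2 cell-type enrichment for the CA1 marker panel
(excitatory markers up, inhibitory/OPC/oligodendrocyte/astrocyte markers
down) and the Opto IP means carry the planted ribosome fold changes. CLIP
expected log2 TPM follows the model above with `x` taken from the
*realized* RiboTag counts, so the downstream regression estimand is
exactly `(a, b)`; CLIP counts are then drawn multinomially to the library
size from the implied TPM composition, which preserves the column-sum
identity.

Two consequences of compositionality are worth stating. First,
renormalizing counts to TPM shifts every log2 value by a per-sample
constant, so the intercept `a` is recoverable only from the generator's
emitted log2-TPM table — the count route recovers the slope but maps the
intercept to a compositional constant (~−sigma^2·ln2/2 at b = 1). Second,
condition-specific planted binding mass shifts the two conditions' score
distributions by slightly different constants, so a global change in
binding is partially absorbed by normalization and partially smeared over
null transcripts in the differential — the same identifiability limit the
real assay has (a global binding decrease cannot be separated from a
normalization shift).

What the generator does **not** emulate: raw reads, crosslink sequence
bias, positional tag distributions along transcripts (emitted tags are
uniform over the mature transcript), isoform-level expression inference,
GC/length biases in library preparation, and correlated replicate
structure. Passing tests therefore demonstrate correctness of the
estimators under the model's assumptions, not robustness to these real
data features.

## Numerical and policy choices

* Pseudocount 0.01 TPM before every log2; zero-TPM transcripts are
  excluded from regression fits rather than pseudocounted into them.
* Representative transcript: highest mean TPM across all RiboTag IP
  replicates of both conditions; exact ties break to the
  lexicographically smallest transcript id; "expressed" means mean TPM
  strictly > 0 (configurable floor).
* BH adjustment is the literal step-up with suffix minima, validated
  against an exhaustive oracle and statsmodels.
* All randomness flows from a single seed; outputs embed a config hash
  and are byte-identical across reruns.
* Recovery analyses (`analysis/`, `scripts/acceptance.py`) use
  `score_convention="residual"` and `stringency_mode="mean"`; problem
  sizes are 5000 genes for recovery/classification, 10,000 transcripts
  for moderated-t calibration, and 2000 genes (3v3) for the NB checks.
  The NB bias check passes unit size factors because the simulated
  libraries are depth-matched by construction; the size-factor estimator
  is validated separately and, like any median-of-ratios scheme, absorbs
  part of an asymmetric planted signal into normalization.

## Limitations

The headline counts of the motivating study derive from deposited raw
sequencing and upstream read processing that are out of scope here; this
package reproduces the analysis logic on synthetic data with known truth.
The moderated t assumes approximately normal scores with shared
within-condition variance; the NB test supports exactly two groups with
no covariates or paired designs; annotation rules are an explicit
reimplementation (maximal overlap + precedence), not a bit-exact copy of
any particular annotation script.
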