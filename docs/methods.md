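# Methods

## The model

`pftp` is a partially labeled, supervised topic model for multi-label
protein function prediction.  The observable data are (i) proteins as
bags of amino acid blocks — overlapping k-mers (default length 2,
stride 1) over the 20-residue alphabet — and (ii) per-protein GO-term
annotations.  The `K` global topics are partitioned into disjoint
subsets: `m` topics per label (default 3) and `B` background topics
(default 1) owned by a latent background label that is active in every
protein.  The background captures word usage common to all functions;
per-label subsets capture function-specific sub-structure.  Setting
`m=1, B=0` recovers Labeled-LDA exactly, and the package tests that
degeneracy against an independently coded Labeled-LDA sampler.

Generative process: `π_l ~ Dir(α)` on each label's subset,
`θ_k ~ Dir(λ)` on the vocabulary, and per protein `ψ_d ~ Dir(β)` over
its admissible labels, then per token `l ~ ψ_d`, `z ~ π_l`,
`w ~ θ_z`.  All three Dirichlet priors are symmetric.

A deliberate reading choice: the topic conditional's normalizer uses
the label's own subset size (`α·K_l + N_l`), i.e. each `π_l` is
supported on `𝕂_l` only.  The unrestricted alternative (a global
`α·K` denominator) would let labels place mass on other labels' topics
and make the partition vacuous.  One visible consequence: with all
counts zero the conditional is uniform over *labels* (each label's
mass split over its subset), not uniform over (label, topic) pairs
unless subsets have equal size.  The test-suite oracle (the collapsed
joint in log-Gamma form) uses the same restricted support, so the
conditional/joint pair is self-consistent and is verified to < 1e-12
by brute-force enumeration.

## Inference

Training is collapsed Gibbs sampling: `π, θ, ψ` are integrated out and
each token's (label, topic) pair is drawn jointly from one categorical
over the `Σ_l K_l` admissible candidates — a blocked draw rather than
label-then-topic, matching the joint form of the conditional.  Tokens
are visited in fixed document-major order; all randomness comes from
one seeded NumPy generator per chain, so results are bit-reproducible
from (seed, config).  The numerically heavy sweep is a Numba kernel;
the uniform variates are drawn outside it so the kernel is a pure
function of (state, uniforms).

Estimates are posterior means, e.g. `θ̂_kw = (λ + N_kw)/(λW + N_k)`,
averaged arithmetically over thinned post-burn-in states of a single
chain.  Within one chain the label→subset identity is pinned by the
partition, so label switching cannot occur across samples; topics
*within* one label's subset are exchangeable, which is why comparisons
to ground truth go through within-subset optimal matching (exhaustive
permutations up to size 6, Hungarian assignment above — identical
optima for this additive objective).  Multiple chains, if requested,
are run independently and never averaged.

Prediction is fold-in: a new protein gets every label (plus
background) as admissible, `π̂` and `θ̂` stay frozen, and only its own
label counts are resampled (`p(l,k) ∝ (β + N_dl)·π̂_lk·θ̂_kw`).  The
reported score vector is the averaged `ψ̂_d` renormalized over the real
labels, with the background mass reported separately.  Freezing point
estimates (rather than counts-plus-priors) keeps new data from
mutating the model.  Empty proteins (no in-vocabulary token) receive
prior-only uniform scores and are flagged.

Convergence is not adaptively detected: schedules are fixed
(conventionally 2000/1000/50 for training, 1000/500/50 for
prediction), and the collapsed log joint is logged every 100 sweeps as
an inspection-only diagnostic.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| k (block length) | 2 | k-mer size; `--mixed-lengths` adds 1..k |
| stride | 1 | sliding-window step |
| m | 3 | topics per label |
| B | 1 | background topics |
| α | 50/K | label→topic concentration |
| λ | 200/W | topic→word concentration |
| β | 0.01 | document→label concentration (no conventional value exists; a weak prior keeps label weights data-driven) |
| τ | 1/L | binarization threshold for Hamming loss (uniform baseline; ties included) |

Blocks containing letters outside the 20-residue alphabet (ambiguity
codes such as `X`) are dropped by default; `--keep-ambiguous` retains
them.  Sequences are upper-cased; `*` stop characters are stripped at
FASTA parsing.  Training proteins without any observed label are
rejected unless explicitly allowed onto the background label alone.

## The simulator and what passing tests show

`pftp.simulate` draws models and corpora from the generative process
itself.  The default fixture — D=300 proteins, L=4 labels, m=2, B=1,
W=60 blocks, 2 labels and 120 tokens per protein, α=0.5, β=0.5, λ=0.1
— is small enough for seconds-scale training yet structured enough for
recovery experiments: λ=0.1 gives sparse, nearly disjoint topics, and
2-of-4 label sets give informative label co-occurrence.  Experiment
problem sizes (500 training sweeps with 250 burn-in; N_d grids of
30/120/480) are chosen so the whole verification battery runs in
minutes on one CPU.

The simulator targets the model's own assumptions, not real proteome
statistics: real k-mer frequencies are Zipf-like and autocorrelated
along the sequence, annotations follow the GO hierarchy, and label
frequencies are heavy-tailed.  Passing recovery tests therefore
demonstrates correctness of the inference machinery, not expected
accuracy on real proteomes.

## Identifiability of within-label topics

One property deserves emphasis.  The topic draw `z ~ π_l` uses a
*global* `π_l`: there is no per-document topic mixture within a label.
Consequently the likelihood of a label's tokens depends only on the
label's word marginal `Σ_k π_lk θ_kw`, and the decomposition of that
marginal into the label's `m` topics is identified solely through the
priors — a sparse `λ` favors decompositions into sparse components,
but many splits of a sparse marginal are themselves sparse.  The
posterior over `θ` within a subset therefore stays diffuse: in the
fixture experiments, even a chain initialized at the true assignments
drifts to a matched total-variation distance of ≈0.35 from the true
topics, and random-initialization chains settle at ≈0.4 while reaching
comparable or better collapsed log-joints.  Label-level quantities are
unaffected: background-topic recovery reaches TV ≈0.02, per-label word
marginals TV ≈0.03–0.04, and held-out prediction (which uses only the
marginals) reaches Average Precision ≈0.96.  Users interpreting
individual within-label topics should treat them as one representative
sparse decomposition, not a uniquely recovered structure.

## Numerical choices

- Conditionals are computed as products of count ratios (no log-space
  needed: factors are bounded away from 0 by the positive priors);
  inverse-CDF sampling on the unnormalized cumulative sum.
- Ranking metrics break score ties deterministically by label index;
  PR curves come from an exhaustive threshold sweep (predict positive
  at score ≥ τ) with trapezoidal integration over recall, the first
  point's precision extended to recall 0; labels without test
  positives are excluded from macro/weighted areas and logged.
- Model matrices are serialized as `%.17g` text, which round-trips
  float64 exactly; a vocabulary hash guards against predicting with a
  mismatched BoW.
- Internal indices are 0-based; serialized topic indices are 1-based
  with the background block first (so the background topic is topic 1,
  and with L=319, m=3 the 288th label owns topics 863–865 of K=958).

## Known limitations

- Within-label topic decompositions are weakly identified (above).
- No GO-hierarchy awareness: labels are flat; no true-path-rule
  propagation or hierarchy-aware evaluation.
- No label-space reduction: very large label sets (thousands of GO
  terms) are computationally heavy; external label-space reduction can
  be applied before training and inverted afterwards.
- Fixed schedules; no convergence diagnostics beyond the logged
  log-joint, and no variational or online alternative.
- The bag-of-words step ignores residue order beyond the k-mer window
  and offers no reduced alphabets or gapped k-mers.
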