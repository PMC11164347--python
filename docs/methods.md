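# Methods

## Risk model

For a query protein with features `X` and true level-4 EC label set `Y`
(non-empty), a base model supplies per-label scores `f_k(X) ∈ [0, 1]` and the
prediction set at threshold `λ` is `C_λ(X) = {k : f_k(X) ≥ λ}` (inclusive
comparison; tied labels enter together). The per-protein loss is the false
discovery proportion

    l_FDR(C, Y) = 1 − |C ∩ Y| / |C|,    l_FDR(∅, Y) = 0.

The empty-set convention means abstention is always safe: a model that
predicts nothing incurs no risk. The controlled quantity is the expected
loss over the test distribution, and the guarantee is

    P( E[l_FDR(C_λ*(X), Y)] ≤ α ) ≥ 1 − δ,

valid whenever calibration and test pairs are i.i.d. (exchangeability is
what the probability is taken over; nothing is assumed about the score
model's quality — a bad model just forces larger sets or abstention).

## Calibration

Candidate thresholds are `N` evenly spaced values on [0, 1] (default
`N = 100`, endpoints included). For each `λ_i`, the empirical risk
`R̂(λ_i)` is the mean per-protein loss on the `n_c` calibration proteins,
and the null hypothesis "true risk at `λ_i` exceeds `α`" gets the Hoeffding
p-value

    p_i = exp(−2 n_c ((α − R̂(λ_i))₊)²).

Fixed-sequence testing exploits the near-monotonicity of FDR in `λ`: walk
from `λ_N` (where sets are smallest and risk lowest) downward, rejecting
nulls while `p_i ≤ δ`, and stop at the first acceptance. The rejection set
`Λ̂` is therefore a contiguous suffix of the grid; every `λ ∈ Λ̂` controls
the risk, and `λ* = min Λ̂` is returned because the smallest certified
threshold yields the largest prediction sets (most discoveries, lowest
FNR). No multiplicity correction is needed: the sequential scheme controls
the family-wise error at `δ` by construction.

Because the p-value has the hinge form, certification requires
`R̂(λ) ≤ α − sqrt(ln(1/δ) / (2 n_c))`. Two practical consequences:

* **Conservativeness.** The realized failure rate over replicates is far
  below `δ` (typically 0), and the realized FDR sits visibly below `α`.
* **Small calibration sets.** With `n_c = 100` and `δ = 0.1` the margin is
  ≈ 0.107, so tolerances `α ≤ 0.107` can only be certified at thresholds
  with exactly zero empirical risk — and possibly not at all.

When no threshold is certified (`Λ̂ = ∅`) the calibrator **abstains**: the
result carries an `ABSTAIN` sentinel, `FDRController.lambda_` is NaN, a
`UserWarning` is raised at fit time, and prediction emits empty sets for
every protein, which trivially satisfies the guarantee. Abstention is a
value, not an error.

An optional Hoeffding–Bentkus p-value is provided,
`min(exp(−n_c·KL(min(R̂, α) ‖ α)), e·P(Bin(n_c, α) ≤ ⌈n_c R̂⌉))`, clipped
into (0, 1] against float underflow. It is never larger than the plain
Hoeffding p-value, so it certifies at least as many thresholds; the default
stays Hoeffding for its closed form.

Tunable parameters: `alpha` (the FDR tolerance, the scientific choice),
`delta = 0.1` (conventional failure budget), `n_grid = 100`. All thresholds,
risks and p-values are retained in `CalibrationResult` for inspection.

## Embedding scorer

The nearest-cluster scorer transfers labels through an embedding space in
which functional similarity is distance. For each EC number `γ` with at
least one embedded training member, the cluster embedding is the mean

    z_γ = (1 / |{p : γ ∈ EC(p)}|) Σ_{p : γ ∈ EC(p)} x_p,

with promiscuous proteins contributing to every one of their clusters. A
query is scored against all clusters by distance (Euclidean by default,
cosine available); smaller distance means the label is more likely.

The conformal grid lives on [0, 1], so distances are mapped to scores by
`s = exp(−d / τ)`. The scale `τ` is the median of the positive-control
distances (all true protein–EC pairs in the training set, excluding exact
zeros), making the map scale-free and rank-preserving: thresholding scores
at `λ` is identical to thresholding distances at `−τ ln λ`. Degenerate fits
(every training protein exactly on its centroid) fall back to a tiny
positive `τ`.

Cutoff baselines on the raw distances: top-1 (closest cluster, ties to
label order); max-separation (sort ascending, cut at the first largest gap
between adjacent distances, predict everything before it; all-equal
distances fall back to top-1); σ-threshold (predict all labels with
distance strictly below `μ + 2σ`, where `μ`, `σ` are the mean and
population SD of the positive-control distances). The triplet sampler
draws, for an anchor protein, one of its EC numbers uniformly, a positive
sharing that EC and a negative sharing none of the anchor's ECs; anchors
with no eligible positive or negative raise a skip signal. The full
hierarchical negative-difficulty schedule of contrastive trainers is
deliberately reduced to the shares-no-EC filter.

## Cascade

Level-4 EC numbers are the informative ones, but a model should not output
a more specific code than its confidence supports. The cascade calibrates
two controllers — one on level-4 scores against level-4 truth, one on
level-3 scores against truncated (deduplicated) level-3 truth, both at the
same `α` by default — and per protein emits the level-4 set when non-empty,
else the level-3 set, else nothing. Outcomes partition into HIT4 (fine set
contains a true level-4 code), HIT3 (fell back; coarse set contains a true
level-3 code), INCORRECT_BOTH (something emitted, nothing correct at its
own level) and NOT_CALLED. Since the fallback only fires when the fine set
is empty, the combined hit rate can never fall below the fine-only hit
rate. Level-3 scores can be supplied by a separate coarse model or derived
from the fine matrix by max-pooling over each level-3 prefix's children (a
coarse claim is as plausible as its most plausible refinement).

## Metrics

Sample-averaged precision (`|C∩Y|/|C|`, 0 for empty sets), recall
(`|C∩Y|/|Y|`), F1; realized FDR (mean loss, empty sets 0); coverage
(fraction of proteins with non-empty sets). Because empty sets push
precision toward 0 while leaving FDR at 0, precision is only interpretable
next to coverage, and both are always reported together. The micro PR
curve pools all (protein, label) decisions across every distinct score
threshold; Fmax is the maximum micro-F1 along it. nDCG uses binary
relevance with `1/log2(rank+1)` discounting over the prediction set ranked
by descending score (label-order tie-break); the ideal ranking places all
`|Y|` true labels first, so missed true labels lower the score even when
every prediction is correct. FDR@1st-hit is the smallest `α` on a tolerance
grid (default 0.05–0.5 in steps of 0.05) at which a protein's calibrated
set first contains a true label; nestedness of the sets in `α` makes it
well defined, and never-hit proteins are reported as missing.

## Synthetic generator

The generator draws exchangeable protein rows so the guarantee's assumption
holds by construction:

* **Labels.** `K` level-4 codes arranged in a proper 4-level tree
  (near-balanced branching `⌈K^(1/4)⌉` unless an explicit shape is given).
  Each protein receives one uniform primary EC; with probability
  `promiscuity_rate = 0.1` one extra distinct EC, mirroring the minority of
  promiscuous enzymes in curated databases.
* **Scores.** True-label entries `~ Beta(8, 2)`, false-label entries
  `~ Beta(2, 8)`; a `difficulty ∈ [0, 1]` knob linearly interpolates both
  parameter pairs toward their midpoint (5, 5), so at difficulty 1 the two
  families coincide and scores are pure noise. This stands in for the
  degradation observed on test strata with low sequence identity to
  training data; five preset difficulty values emulate identity strata
  qualitatively, with no claim of a quantitative identity mapping.
* **Embeddings.** One center per EC, the sum of per-prefix Gaussian
  offsets with scales (4, 2, 1, 0.5) down the hierarchy, so codes sharing
  longer prefixes lie closer. A protein sits at the mean of its label
  centers plus isotropic noise of scale `embed_noise × difficulty`.

What the generator does **not** emulate: real sequence/structure features,
covariate shift between calibration and test (the i.i.d. assumption is
enforced, not tested), label-frequency imbalance beyond uniform sampling,
and correlated scores across labels. Passing the guarantee experiments
therefore shows the calibration machinery is correct under its stated
assumption — not that any particular real dataset satisfies that
assumption.

## Experiment sizes and numerical choices

The replicated guarantee experiment uses 200 independent replicates of
n_cal = n_test = 500 with K = 50 labels, at α ∈ {0.1, 0.2, 0.3}; the
calibration-size robustness harness repeats it with calibration fractions
20/10/5/1 % of a 10,000-row pool. Replicate seeds are spawned from one
root seed via `numpy.random.SeedSequence`; the generator uses named
substreams (labels/scores/embeddings) keyed by CRC32 so adding a stream
never perturbs the others. Risk curves are computed vectorized over the
whole grid in row chunks; the empirical risk is reused across tolerances
(only p-values depend on `α`). Score ties at a threshold are included
(inclusive ≥); top-1 and gap ties break by label-universe (lexicographic
EC) order. Euclidean distances use exact difference-based computation
(`scipy.spatial.distance.cdist`) rather than the quadratic expansion, which
loses ~1e-7 of precision near zero.

## Known limitations

* FDR is the only implemented risk; FNR/miscoverage variants would need
  monotone-risk calibrators.
* The guarantee is marginal over calibration draws, not conditional per
  protein or per subgroup; subgroup consistency is an empirical
  observation, not a theorem.
* Under covariate shift between calibration and test the guarantee is void;
  weighted conformal variants are out of scope.
* Max-separation depends on gap magnitudes, so it is invariant under
  increasing affine transforms of the distances but not under arbitrary
  monotone warps; top-1 depends only on ranks.
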