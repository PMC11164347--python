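# conformal-ec

FDR-controlled multi-label enzyme function (EC number) prediction via
conformal risk control.

## The problem

Machine-learning annotators for enzyme function emit, for each query protein,
a score `f_k(X) ∈ [0, 1]` for every candidate EC number `k`, and predict the
label set `C_λ(X) = {k : f_k(X) ≥ λ}` for some decision threshold `λ`. Picking
`λ` by hand gives no control over how many of the predicted labels are wrong —
a real cost when each predicted protein–EC pair is a wet-lab validation
experiment. This package calibrates `λ` on held-out data so that the
**averaged per-protein false discovery rate** of the prediction sets is
statistically guaranteed:

```
P( E[ l_FDR(C_λ(X), Y) ] ≤ α ) ≥ 1 − δ,
l_FDR(C, Y) = 1 − |C ∩ Y| / |C|   (0 when C = ∅)
```

where `α` is the user's FDR tolerance and `δ` (default 0.1) the probability
budget with which the bound may fail. The only assumption is that calibration
and test pairs `(X, Y)` are i.i.d.

Calibration is Learn-then-Test with fixed-sequence testing: each candidate
threshold `λ_i` on an evenly spaced 100-point grid is a null hypothesis
"risk(λ_i) > α", tested with a Hoeffding p-value
`p_i = exp(−2 n_c ((α − R̂(λ_i))₊)²)` from the empirical calibration risk
`R̂(λ_i)` over `n_c` calibration proteins. Hypotheses are tested from `λ_N`
downward, stopping at the first `p_i > δ`; the certified thresholds form a
suffix `Λ̂` of the grid, and `λ* = min Λ̂` is used (the smallest certified
threshold maximizes discoveries). If even `λ_N` fails, the calibrator
abstains and every prediction set is empty (FDR 0 by convention).

Around this core the package provides:

- an embedding **nearest-cluster scorer**: per-EC cluster embeddings
  `z_γ = mean{x_p : γ ∈ EC(p)}`, query-to-cluster distances mapped to scores
  by `exp(−d/τ)` with `τ` the median true-pair distance;
- the non-conformal cutoff baselines **top-1**, **max-separation** (cut at
  the largest gap in the sorted distance list) and **σ-threshold** (predict
  everything closer than `μ + 2σ` of the true-pair distance distribution),
  plus the contrastive **triplet sampler** for multi-label anchors;
- a **cascade**: emit the calibrated level-4 EC set when non-empty, else
  fall back to the calibrated level-3 set, with hit-rate accounting;
- **metrics**: sample-averaged precision/recall/F1, micro-averaged PR curve
  with Fmax, nDCG, coverage, realized FDR, and FDR@1st-hit (the smallest α
  at which a protein first receives a correct label);
- a **synthetic generator** producing i.i.d. calibration/test pools with a
  hierarchical EC universe, a minority of promiscuous (multi-label) enzymes,
  Beta-distributed scores and a difficulty knob.

## Worked example

```python
from conformal_ec import FDRController
from conformal_ec.simulate import GeneratorConfig, make_dataset, split_cal_test
from conformal_ec.metrics import evaluate_at_lambda

cfg = GeneratorConfig(n_proteins=1000, n_labels=50, difficulty=0.3, seed=1)
ann, scores, emb = make_dataset(cfg)
cal, test = split_cal_test(ann, scores, n_cal=500, seed=1)

for alpha in (0.1, 0.2, 0.3):
    ctrl = FDRController(alpha=alpha).fit(*cal)
    rec = evaluate_at_lambda(test[0], test[1], ctrl.lambda_)
    print(f"alpha={alpha:.1f}  lambda*={ctrl.lambda_:.3f}  "
          f"test FDR={rec['fdr']:.3f}  precision={rec['precision']:.3f}  "
          f"recall={rec['recall']:.3f}  coverage={rec['coverage']:.3f}")
```

prints

```
alpha=0.1  lambda*=0.737  test FDR=0.052  precision=0.460  recall=0.447  coverage=0.512
alpha=0.2  lambda*=0.687  test FDR=0.146  precision=0.542  recall=0.585  coverage=0.688
alpha=0.3  lambda*=0.657  test FDR=0.231  precision=0.555  recall=0.657  coverage=0.786
```

Each realized test FDR sits below its tolerance `α`; loosening `α` lowers
`λ*`, grows the prediction sets (recall and coverage rise) and trades
precision for yield. `FDRController` is a scikit-learn estimator
(`get_params`/`set_params`, fitted attributes `lambda_`, `empirical_risk_`,
`pvalues_`, `rejection_set_`, `abstained_`), and `NearestClusterScorer`
(`fit`/`transform`) turns embedding tables into the score matrices it
consumes.

The same workflow is available from the shell:

```sh
conformal-ec simulate --n-proteins 1000 --n-labels 50 --seed 1 --out-dir data/
conformal-ec calibrate --scores data/scores.tsv --labels data/annotations.tsv \
    --alpha 0.2 --out calib.json
conformal-ec predict --scores data/scores.tsv --calib calib.json --out preds.tsv
conformal-ec evaluate --scores data/scores.tsv --labels data/annotations.tsv \
    --cal-scores data/scores.tsv --cal-labels data/annotations.tsv \
    --alphas 0.05:0.5:0.05 --out report.json
```

(`score`, `cascade` and `pipeline` subcommands cover the embedding scorer,
the coarse/fine cascade and the end-to-end seeded pipeline.)

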