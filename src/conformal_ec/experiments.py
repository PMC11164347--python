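"""Replicated guarantee experiments.

The conformal guarantee is a statement about repeated draws: over many
independent calibration/test replicates, the fraction where the realized
mean test FDR exceeds the tolerance alpha must stay below the failure rate
delta. These helpers run that experiment on the synthetic generator,
reusing the calibration risk curve across tolerances (the empirical risk
does not depend on alpha, only the p-values do).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Sequence

import numpy as np

from .conformal import _fixed_sequence, _PVALUE_FNS
from .simulate import GeneratorConfig, generate_labels, generate_scores

__all__ = ["replicate_fdr", "guarantee_failure_rate"]


def _mean_fdr_at(scores: np.ndarray, mask: np.ndarray, lam: float) -> float:
    if not np.isfinite(lam):
        return 0.0  # abstention: every set empty
    pred = scores >= lam
    npred = pred.sum(axis=1)
    ntp = (pred & mask).sum(axis=1)
    loss = np.zeros(scores.shape[0])
    nz = npred > 0
    loss[nz] = 1.0 - ntp[nz] / npred[nz]
    return float(loss.mean())


def replicate_fdr(
    base: GeneratorConfig,
    n_cal: int,
    alphas: Sequence[float],
    seed: int,
    delta: float = 0.1,
    n_grid: int = 100,
    pvalue: str = "hoeffding",
) -> Dict[float, float]:
    """One replicate: calibrate per tolerance, return realized test FDRs.

    The generator's rows are i.i.d., so the first ``n_cal`` rows serve as
    the calibration split and the rest as test.
    """
    from .conformal import risk_curve

    cfg = replace(base, seed=seed)
    ann = generate_labels(cfg)
    scores = generate_scores(ann, cfg)
    mask = ann.indicator_matrix()
    grid = np.linspace(0.0, 1.0, n_grid)
    cal_s, cal_m = scores.scores[:n_cal], mask[:n_cal]
    test_s, test_m = scores.scores[n_cal:], mask[n_cal:]
    risks = risk_curve(cal_s, cal_m, grid)
    pfn = _PVALUE_FNS[pvalue]
    out = {}
    for alpha in alphas:
        pvals = np.array([pfn(r, n_cal, alpha) for r in risks])
        _, lam = _fixed_sequence(grid, pvals, delta)
        lam_eff = float(lam) if isinstance(lam, float) else np.inf
        out[alpha] = _mean_fdr_at(test_s, test_m, lam_eff)
    return out


def guarantee_failure_rate(
    alphas: Sequence[float] = (0.1, 0.2, 0.3),
    n_replicates: int = 200,
    n_cal: int = 500,
    n_test: int = 500,
    n_labels: int = 50,
    delta: float = 0.1,
    n_grid: int = 100,
    seed: int = 1,
    **generator_kwargs,
) -> Dict[float, float]:
    """Fraction of replicates whose realized test FDR exceeds each alpha.

    Each replicate draws a fresh i.i.d. pool of ``n_cal + n_test`` proteins
    from the synthetic generator, calibrates on the first ``n_cal`` rows and
    measures the mean per-protein FDR on the rest. Under the conformal
    guarantee the returned fractions must not exceed ``delta`` (and with the
    conservative Hoeffding p-values they are expected to be far below it).
    """
    base = GeneratorConfig(
        n_proteins=n_cal + n_test, n_labels=n_labels, **generator_kwargs
    )
    exceed = {alpha: 0 for alpha in alphas}
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    for rs in rep_seeds:
        fdrs = replicate_fdr(
            base, n_cal, alphas, int(rs % (2**31)), delta=delta, n_grid=n_grid
        )
        for alpha in alphas:
            if fdrs[alpha] > alpha:
                exceed[alpha] += 1
    return {alpha: exceed[alpha] / n_replicates for alpha in alphas}
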