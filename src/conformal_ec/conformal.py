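"""Conformal risk control of the per-protein false discovery rate.

Given per-label scores ``f_k(X)`` in [0, 1], a prediction set is formed by
thresholding: ``C_lam(X) = {k : f_k(X) >= lam}``. The per-protein FDR loss of
a set is the fraction of its members that are wrong, with the convention that
an empty set incurs loss 0. The calibration procedure (Learn-then-Test with
fixed-sequence testing) selects the threshold ``lam*`` on held-out calibration
data so that the expected test-set FDR stays below a user tolerance ``alpha``
with probability at least ``1 - delta``:

    P( E[ l_FDR(C_lam*(X), Y) ] <= alpha ) >= 1 - delta.

Each candidate threshold ``lam_i`` on an evenly spaced grid is paired with a
null hypothesis "risk(lam_i) > alpha", tested with a valid p-value computed
from the empirical calibration risk (Hoeffding's inequality by default).
Thresholds are tested from the largest downward, stopping at the first
acceptance; the rejection set is a suffix of the grid and its minimum is the
operating threshold, maximizing discoveries among certified thresholds.

The whole procedure assumes calibration and test pairs (X, Y) are i.i.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Set

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .ontology import AnnotationSet, ECNumber

__all__ = [
    "ABSTAIN",
    "ScoreMatrix",
    "RiskSpec",
    "CalibrationResult",
    "FDRController",
    "fdr_loss",
    "prediction_set",
    "empirical_risk",
    "risk_curve",
    "hoeffding_pvalue",
    "hoeffding_bentkus_pvalue",
    "calibrate",
]


class _Abstain:
    """Sentinel: no grid threshold could be certified at the requested risk."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "ABSTAIN"

    def __bool__(self):
        return False


ABSTAIN = _Abstain()


@dataclass
class ScoreMatrix:
    """Per-protein, per-label scores in [0, 1].

    Rows are proteins, columns EC labels in a declared universe order.
    """

    proteins: List[str]
    labels: List[ECNumber]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.proteins), len(self.labels)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.labels)} labels"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains non-finite entries")
        if (self.scores < 0).any() or (self.scores > 1).any():
            i, j = np.argwhere((self.scores < 0) | (self.scores > 1))[0]
            raise ValueError(
                f"score out of [0, 1] at protein {self.proteins[i]!r}, "
                f"label {self.labels[j]}: {self.scores[i, j]}"
            )

    def __len__(self):
        return len(self.proteins)

    def row(self, pid: str) -> np.ndarray:
        return self.scores[self.proteins.index(pid)]

    def subset(self, proteins: Sequence[str]) -> "ScoreMatrix":
        idx = {p: i for i, p in enumerate(self.proteins)}
        rows = [idx[p] for p in proteins]
        return ScoreMatrix(list(proteins), self.labels, self.scores[rows])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.proteins, name="protein_id"),
            columns=[str(ec) for ec in self.labels],
        )

    @classmethod
    def from_frame(cls, df) -> "ScoreMatrix":
        from .ontology import parse_ec

        labels = [parse_ec(c) for c in df.columns]
        return cls(list(df.index.astype(str)), labels, df.to_numpy(dtype=float))


@dataclass
class RiskSpec:
    """Risk tolerance and testing configuration.

    Parameters
    ----------
    alpha : float in (0, 1)
        FDR tolerance: the bound on expected per-protein FDR.
    delta : float in (0, 1), default 0.1
        Failure rate: the probability budget with which the bound may fail.
    grid : ndarray, optional
        Strictly increasing candidate thresholds with endpoints 0 and 1.
        Defaults to ``n_grid`` evenly spaced points.
    n_grid : int, default 100
        Grid size when ``grid`` is not given.
    """

    alpha: float
    delta: float = 0.1
    grid: np.ndarray | None = None
    n_grid: int = 100

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if self.grid is None:
            self.grid = np.linspace(0.0, 1.0, self.n_grid)
        else:
            self.grid = np.asarray(self.grid, dtype=float)
            if self.grid.ndim != 1 or len(self.grid) < 2:
                raise ValueError("grid must be a 1-D array of >= 2 thresholds")
            if not (np.diff(self.grid) > 0).all():
                raise ValueError("grid must be strictly increasing")
            if self.grid[0] != 0.0 or self.grid[-1] != 1.0:
                raise ValueError("grid endpoints must be 0 and 1")
            self.n_grid = len(self.grid)


@dataclass
class CalibrationResult:
    """Everything the calibration step computed.

    ``rejection_set`` is a contiguous suffix of the grid (fixed-sequence
    testing walks from the largest threshold downward) and ``lambda_star`` is
    its minimum, or the ``ABSTAIN`` sentinel when no threshold was certified.
    """

    grid: np.ndarray
    empirical_risk: np.ndarray
    pvalue: np.ndarray
    rejection_set: np.ndarray
    lambda_star: object  # float or ABSTAIN
    alpha: float
    delta: float
    n_cal: int

    @property
    def abstained(self) -> bool:
        return self.lambda_star is ABSTAIN

    def effective_lambda(self) -> float:
        """The operating threshold; +inf when abstaining (every set empty)."""
        return np.inf if self.abstained else float(self.lambda_star)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "delta": self.delta,
            "n_cal": self.n_cal,
            "grid": self.grid.tolist(),
            "empirical_risk": self.empirical_risk.tolist(),
            "pvalue": self.pvalue.tolist(),
            "rejection_set": self.rejection_set.tolist(),
            "lambda_star": None if self.abstained else float(self.lambda_star),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        lam = d["lambda_star"]
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            empirical_risk=np.asarray(d["empirical_risk"], dtype=float),
            pvalue=np.asarray(d["pvalue"], dtype=float),
            rejection_set=np.asarray(d["rejection_set"], dtype=float),
            lambda_star=ABSTAIN if lam is None else float(lam),
            alpha=d["alpha"],
            delta=d["delta"],
            n_cal=d["n_cal"],
        )


# ---------------------------------------------------------------------------
# loss and risk


def fdr_loss(pred: Set[ECNumber], truth: Set[ECNumber]) -> float:
    """Per-protein false discovery proportion of a prediction set.

    ``1 - |pred & truth| / |pred|`` for non-empty ``pred``; an empty set
    incurs loss 0 by convention (no discovery, no false discovery).
    """
    if not truth:
        raise ValueError("ground-truth label set must be non-empty")
    if not pred:
        return 0.0
    return 1.0 - len(pred & truth) / len(pred)


def prediction_set(
    scores_row: np.ndarray, labels: Sequence[ECNumber], lam: float
) -> Set[ECNumber]:
    """Labels scoring at least ``lam`` (inclusive threshold)."""
    scores_row = np.asarray(scores_row, dtype=float)
    return {labels[k] for k in np.flatnonzero(scores_row >= lam)}


def _truth_mask(scores: ScoreMatrix, truth: AnnotationSet) -> np.ndarray:
    if scores.proteins != truth.proteins:
        truth = truth.subset(scores.proteins)
    return truth.indicator_matrix(scores.labels)


def risk_curve(
    score_mat: np.ndarray,
    truth_mask: np.ndarray,
    grid: np.ndarray,
    chunk: int = 2048,
) -> np.ndarray:
    """Mean per-protein FDR at every grid threshold, vectorized.

    Rows are processed in chunks to bound the n x N x K boolean intermediate.
    """
    grid = np.asarray(grid, dtype=float)
    n = score_mat.shape[0]
    if n == 0:
        raise ValueError("empty calibration set")
    total = np.zeros(len(grid))
    for start in range(0, n, chunk):
        s = score_mat[start : start + chunk]
        t = truth_mask[start : start + chunk]
        pred = s[:, None, :] >= grid[None, :, None]
        npred = pred.sum(axis=2)
        ntp = (pred & t[:, None, :]).sum(axis=2)
        loss = np.zeros_like(npred, dtype=float)
        nz = npred > 0
        loss[nz] = 1.0 - ntp[nz] / npred[nz]
        total += loss.sum(axis=0)
    return total / n


def empirical_risk(
    cal_scores: ScoreMatrix, cal_truth: AnnotationSet, lam: float
) -> float:
    """Mean FDR loss of the lam-thresholded sets over the calibration set."""
    if len(cal_scores) == 0:
        raise ValueError("empty calibration set")
    mask = _truth_mask(cal_scores, cal_truth)
    pred = cal_scores.scores >= lam
    npred = pred.sum(axis=1)
    ntp = (pred & mask).sum(axis=1)
    loss = np.zeros(len(cal_scores))
    nz = npred > 0
    loss[nz] = 1.0 - ntp[nz] / npred[nz]
    return float(loss.mean())


# ---------------------------------------------------------------------------
# p-values


def hoeffding_pvalue(r_hat: float, n_c: int, alpha: float) -> float:
    """Hoeffding-inequality p-value for the null "risk > alpha".

    ``exp(-2 n_c ((alpha - r_hat)_+)^2)`` where ``(.)_+`` is the positive
    part; equals 1 whenever the empirical risk is at or above the tolerance.
    """
    if n_c < 1:
        raise ValueError("calibration size must be >= 1")
    hinge = max(alpha - r_hat, 0.0)
    return float(np.exp(-2.0 * n_c * hinge * hinge))


def _kl_bernoulli(a: float, b: float) -> float:
    """KL divergence between Bernoulli(a) and Bernoulli(b)."""
    eps = 1e-300
    a = min(max(a, 0.0), 1.0)
    kl = 0.0
    if a > 0:
        kl += a * np.log(a / max(b, eps))
    if a < 1:
        kl += (1 - a) * np.log((1 - a) / max(1 - b, eps))
    return kl


def hoeffding_bentkus_pvalue(r_hat: float, n_c: int, alpha: float) -> float:
    """Tighter p-value combining the Hoeffding KL bound with Bentkus' bound.

    The minimum of ``exp(-n_c * KL(min(r_hat, alpha) || alpha))`` and
    ``e * P(Bin(n_c, alpha) <= ceil(n_c * r_hat))``, following the standard
    Learn-then-Test construction. Never larger than the plain Hoeffding
    p-value and still valid, so fixed-sequence testing rejects at least as
    many thresholds.
    """
    if n_c < 1:
        raise ValueError("calibration size must be >= 1")
    if r_hat >= alpha:
        return 1.0
    h = np.exp(-n_c * _kl_bernoulli(r_hat, alpha))
    b = np.e * stats.binom.cdf(np.ceil(n_c * r_hat), n_c, alpha)
    # keep the value in (0, 1]: the exact bound is positive but can
    # underflow float64 for large n_c
    return float(min(1.0, max(min(h, b), np.finfo(float).tiny)))


_PVALUE_FNS = {
    "hoeffding": hoeffding_pvalue,
    "hoeffding-bentkus": hoeffding_bentkus_pvalue,
}


# ---------------------------------------------------------------------------
# calibration


def _fixed_sequence(
    grid: np.ndarray, pvalues: np.ndarray, delta: float
) -> tuple[np.ndarray, object]:
    """Walk the grid from the largest threshold down, collecting rejections
    until the first p-value above delta; return (rejection suffix, min)."""
    i = len(grid) - 1
    first = len(grid)  # index of the smallest rejected threshold
    while i >= 0 and pvalues[i] <= delta:
        first = i
        i -= 1
    rejection = grid[first:]
    lam = ABSTAIN if len(rejection) == 0 else float(rejection[0])
    return rejection, lam


class FDRController(BaseEstimator):
    """Conformal FDR control for multi-label prediction sets.

    Calibrates a score threshold via Learn-then-Test with fixed-sequence
    testing so that the mean per-protein FDR of the thresholded prediction
    sets on exchangeable test data is at most ``alpha`` with probability at
    least ``1 - delta``.

    Parameters
    ----------
    alpha : float, default 0.1
        FDR tolerance.
    delta : float, default 0.1
        Failure-rate budget of the guarantee.
    n_grid : int, default 100
        Number of evenly spaced candidate thresholds on [0, 1].
    pvalue : {"hoeffding", "hoeffding-bentkus"}, default "hoeffding"
        Concentration bound used to convert empirical risks into p-values.

    Attributes
    ----------
    grid_ : ndarray of shape (n_grid,)
        Candidate thresholds.
    empirical_risk_ : ndarray of shape (n_grid,)
        Mean calibration FDR at each threshold.
    pvalues_ : ndarray of shape (n_grid,)
        Per-threshold p-values for the null "risk > alpha".
    rejection_set_ : ndarray
        Certified thresholds (a contiguous suffix of the grid).
    lambda_ : float
        Operating threshold ``min(rejection_set_)``; ``nan`` when abstaining.
    abstained_ : bool
        True when no threshold could be certified; ``predict`` then emits
        empty sets for every protein (FDR 0 by the empty-set convention).
    result_ : CalibrationResult
        The full calibration record.

    Examples
    --------
    >>> ctrl = FDRController(alpha=0.2).fit(cal_scores, cal_annotations)
    >>> sets = ctrl.predict_sets(test_scores)
    """

    def __init__(
        self,
        alpha: float = 0.1,
        delta: float = 0.1,
        n_grid: int = 100,
        pvalue: str = "hoeffding",
    ):
        self.alpha = alpha
        self.delta = delta
        self.n_grid = n_grid
        self.pvalue = pvalue

    def _spec(self) -> RiskSpec:
        return RiskSpec(alpha=self.alpha, delta=self.delta, n_grid=self.n_grid)

    def fit(self, cal_scores: ScoreMatrix, cal_truth: AnnotationSet):
        """Calibrate the threshold on held-out scores and annotations."""
        if self.pvalue not in _PVALUE_FNS:
            raise ValueError(
                f"pvalue must be one of {sorted(_PVALUE_FNS)}, got {self.pvalue!r}"
            )
        spec = self._spec()
        if len(cal_scores) == 0:
            raise ValueError("empty calibration set")
        mask = _truth_mask(cal_scores, cal_truth)
        if not mask.any(axis=1).all():
            bad = cal_scores.proteins[int(np.argmin(mask.any(axis=1)))]
            raise ValueError(
                f"calibration protein {bad!r} has no true label in the score "
                "matrix's label universe"
            )
        n_c = len(cal_scores)
        risks = risk_curve(cal_scores.scores, mask, spec.grid)
        pfn = _PVALUE_FNS[self.pvalue]
        pvals = np.array([pfn(r, n_c, spec.alpha) for r in risks])
        rejection, lam = _fixed_sequence(spec.grid, pvals, spec.delta)
        self.result_ = CalibrationResult(
            grid=spec.grid,
            empirical_risk=risks,
            pvalue=pvals,
            rejection_set=rejection,
            lambda_star=lam,
            alpha=spec.alpha,
            delta=spec.delta,
            n_cal=n_c,
        )
        self.grid_ = spec.grid
        self.empirical_risk_ = risks
        self.pvalues_ = pvals
        self.rejection_set_ = rejection
        self.abstained_ = lam is ABSTAIN
        self.lambda_ = np.nan if self.abstained_ else float(lam)
        if self.abstained_:
            warnings.warn(
                f"no threshold certified at alpha={spec.alpha}, "
                f"delta={spec.delta} with n_cal={n_c}; predictions abstain "
                "(empty sets)",
                UserWarning,
                stacklevel=2,
            )
        return self

    def predict(self, scores: ScoreMatrix) -> np.ndarray:
        """Boolean membership matrix of the calibrated prediction sets."""
        self._check_fitted()
        lam = self.result_.effective_lambda()
        return scores.scores >= lam

    def predict_sets(self, scores: ScoreMatrix) -> List[Set[ECNumber]]:
        """Calibrated prediction set for each protein row."""
        member = self.predict(scores)
        labels = np.asarray(scores.labels, dtype=object)
        return [set(labels[row]) for row in member]

    def score(self, scores: ScoreMatrix, truth: AnnotationSet) -> float:
        """Negative realized mean FDR (sklearn convention: larger is better)."""
        self._check_fitted()
        mask = _truth_mask(scores, truth)
        pred = self.predict(scores)
        npred = pred.sum(axis=1)
        ntp = (pred & mask).sum(axis=1)
        loss = np.zeros(len(scores))
        nz = npred > 0
        loss[nz] = 1.0 - ntp[nz] / npred[nz]
        return -float(loss.mean())

    def realized_fdr(self, scores: ScoreMatrix, truth: AnnotationSet) -> float:
        """Mean per-protein FDR of the calibrated sets on the given data."""
        return -self.score(scores, truth)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("FDRController is not fitted; call fit() first")


def calibrate(
    cal_scores: ScoreMatrix, cal_truth: AnnotationSet, spec: RiskSpec,
    pvalue: str = "hoeffding",
) -> CalibrationResult:
    """Functional form of :class:`FDRController`'s calibration step.

    Unlike the estimator, accepts an arbitrary (strictly increasing) grid via
    ``spec`` and does not warn on abstention.
    """
    n_c = len(cal_scores)
    if n_c == 0:
        raise ValueError("empty calibration set")
    mask = _truth_mask(cal_scores, cal_truth)
    risks = risk_curve(cal_scores.scores, mask, spec.grid)
    pfn = _PVALUE_FNS[pvalue]
    pvals = np.array([pfn(r, n_c, spec.alpha) for r in risks])
    rejection, lam = _fixed_sequence(spec.grid, pvals, spec.delta)
    return CalibrationResult(
        grid=spec.grid,
        empirical_risk=risks,
        pvalue=pvals,
        rejection_set=rejection,
        lambda_star=lam,
        alpha=spec.alpha,
        delta=spec.delta,
        n_cal=n_c,
    )
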