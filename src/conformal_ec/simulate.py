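"""Synthetic calibration/test data with the structure the guarantee assumes.

The conformal guarantee only needs calibration and test pairs (X, Y) to be
i.i.d.; this module draws both from one generator so every stage of the
pipeline is testable without any downloads. It emulates the shape of real
enzyme annotation data:

* a label universe of K level-4 EC codes arranged in a proper four-level
  tree (near-balanced branching unless an explicit shape is given);
* one EC per protein, plus a second with probability ``promiscuity_rate``
  (defaults to 0.1 — promiscuous, multi-functional enzymes are a minority
  in curated databases);
* per-(protein, label) scores drawn from a Beta(a1, b1) family for true
  labels and Beta(a0, b0) for false labels; a ``difficulty`` knob in [0, 1]
  interpolates both families toward their common midpoint, standing in for
  the degradation seen on low train-test sequence-identity strata (at
  difficulty 1 the two families coincide and scores carry no signal);
* embeddings with one Gaussian center per EC, built hierarchically so codes
  sharing longer prefixes lie closer, with isotropic protein noise scaled
  by difficulty.

All draws flow from the config seed; the same config reproduces the same
data bit for bit.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .conformal import ScoreMatrix
from .ontology import AnnotationSet, ECNumber
from .predictor import EmbeddingTable

__all__ = [
    "GeneratorConfig",
    "generate_labels",
    "generate_scores",
    "generate_embeddings",
    "split_cal_test",
    "make_dataset",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic enzyme-annotation generator.

    Parameters
    ----------
    n_proteins : int
        Total proteins to generate (split later into calibration/test).
    n_labels : int
        Number of distinct level-4 EC codes (K).
    hierarchy_shape : tuple of 4 ints, optional
        Branching factor per EC level; its product must equal ``n_labels``.
        When omitted, a near-balanced four-level tree is built and the first
        ``n_labels`` leaves in lexicographic order are used.
    promiscuity_rate : float, default 0.1
        Probability a protein carries a second EC number.
    score_beta_true : (a1, b1), default (8, 2)
        Beta parameters of true-label scores.
    score_beta_false : (a0, b0), default (2, 8)
        Beta parameters of false-label scores.
    difficulty : float in [0, 1], default 0.0
        Shrinks the separation between the two Beta families (0 = cleanly
        separated, 1 = identical distributions).
    embed_dim : int, default 16
        Embedding dimensionality.
    embed_noise : float, default 1.0
        Base scale of isotropic protein noise; the effective noise is
        ``embed_noise * difficulty`` (difficulty 0 puts single-label
        proteins exactly on their EC center).
    seed : int, default 0
        Seed for all randomness.
    """

    n_proteins: int = 1000
    n_labels: int = 50
    hierarchy_shape: Tuple[int, int, int, int] | None = None
    promiscuity_rate: float = 0.1
    score_beta_true: Tuple[float, float] = (8.0, 2.0)
    score_beta_false: Tuple[float, float] = (2.0, 8.0)
    difficulty: float = 0.0
    embed_dim: int = 16
    embed_noise: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1 or self.n_labels < 2:
            raise ValueError("need >= 1 protein and >= 2 labels")
        if not 0 <= self.promiscuity_rate < 1:
            raise ValueError("promiscuity_rate must be in [0, 1)")
        if not 0 <= self.difficulty <= 1:
            raise ValueError("difficulty must be in [0, 1]")
        if self.hierarchy_shape is not None:
            shape = tuple(self.hierarchy_shape)
            if len(shape) != 4 or any(b < 1 for b in shape):
                raise ValueError("hierarchy_shape must be 4 positive ints")
            if math.prod(shape) != self.n_labels:
                raise ValueError(
                    f"hierarchy_shape product {math.prod(shape)} != "
                    f"n_labels {self.n_labels}"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent substream derived from the config seed."""
        tag = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng([self.seed, tag])


def _universe(cfg: GeneratorConfig) -> List[ECNumber]:
    """K level-4 codes forming a proper four-level tree."""
    if cfg.hierarchy_shape is not None:
        shape = tuple(cfg.hierarchy_shape)
    else:
        b = max(2, math.ceil(cfg.n_labels ** 0.25))
        shape = (b, b, b, b)
    codes = []
    for idx in np.ndindex(*shape):
        codes.append(ECNumber(tuple(str(i + 1) for i in idx)))
        if len(codes) == cfg.n_labels:
            break
    if len(codes) < cfg.n_labels:
        raise ValueError("hierarchy too small for n_labels")
    return codes


def generate_labels(cfg: GeneratorConfig) -> AnnotationSet:
    """Draw per-protein label sets over the synthetic EC universe.

    Every protein gets one primary EC uniformly at random; with probability
    ``promiscuity_rate`` a second, distinct EC is added (uniform over the
    rest), emulating promiscuous enzymes.
    """
    universe = _universe(cfg)
    K = len(universe)
    rng = cfg.rng("labels")
    primary = rng.integers(K, size=cfg.n_proteins)
    promiscuous = rng.random(cfg.n_proteins) < cfg.promiscuity_rate
    extra_raw = rng.integers(K - 1, size=cfg.n_proteins)
    labels_of = {}
    for i in range(cfg.n_proteins):
        pid = f"P{i:05d}"
        labs = {universe[primary[i]]}
        if promiscuous[i]:
            j = extra_raw[i]
            if j >= primary[i]:
                j += 1  # skip the primary label -> uniform over the rest
            labs.add(universe[j])
        labels_of[pid] = labs
    return AnnotationSet(labels_of, universe=universe)


def _interp_beta(
    true_ab: Tuple[float, float],
    false_ab: Tuple[float, float],
    difficulty: float,
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    mid = ((true_ab[0] + false_ab[0]) / 2, (true_ab[1] + false_ab[1]) / 2)
    t = difficulty
    true_d = tuple((1 - t) * a + t * m for a, m in zip(true_ab, mid))
    false_d = tuple((1 - t) * a + t * m for a, m in zip(false_ab, mid))
    return true_d, false_d


def generate_scores(ann: AnnotationSet, cfg: GeneratorConfig) -> ScoreMatrix:
    """Draw the per-(protein, label) score matrix.

    True-label entries come from the "true" Beta family, false-label entries
    from the "false" family, both interpolated toward their common midpoint
    as difficulty grows. Rows are independent, so calibration/test splits of
    the rows are i.i.d.
    """
    rng = cfg.rng("scores")
    mask = ann.indicator_matrix()
    (a1, b1), (a0, b0) = _interp_beta(
        cfg.score_beta_true, cfg.score_beta_false, cfg.difficulty
    )
    n, K = mask.shape
    scores = rng.beta(a0, b0, size=(n, K))
    scores[mask] = rng.beta(a1, b1, size=int(mask.sum()))
    return ScoreMatrix(list(ann.proteins), list(ann.universe), scores)


def generate_embeddings(ann: AnnotationSet, cfg: GeneratorConfig) -> EmbeddingTable:
    """Draw protein embeddings around hierarchically correlated EC centers.

    Each level-4 EC center is the sum of Gaussian offsets attached to its
    four prefixes, with scales shrinking down the hierarchy (4, 2, 1, 0.5),
    so codes sharing longer prefixes have closer centers. A protein sits at
    the mean of its label centers plus isotropic noise of scale
    ``embed_noise * difficulty``.
    """
    rng = cfg.rng("embeddings")
    d = cfg.embed_dim
    scales = (4.0, 2.0, 1.0, 0.5)
    offsets: dict = {}
    centers = {}
    for ec in ann.universe:
        center = np.zeros(d)
        for level in range(1, 5):
            prefix = ec.components[:level]
            if prefix not in offsets:
                offsets[prefix] = rng.normal(scale=scales[level - 1], size=d)
            center = center + offsets[prefix]
        centers[ec] = center
    noise = cfg.embed_noise * cfg.difficulty
    vectors = np.empty((len(ann.proteins), d))
    for i, pid in enumerate(ann.proteins):
        labs = sorted(ann[pid])
        base = np.mean([centers[ec] for ec in labs], axis=0)
        vectors[i] = base + (rng.normal(scale=noise, size=d) if noise > 0 else 0.0)
    return EmbeddingTable(list(ann.proteins), vectors)


def split_cal_test(
    ann: AnnotationSet,
    scores: ScoreMatrix,
    n_cal: int,
    seed: int,
) -> Tuple[Tuple[ScoreMatrix, AnnotationSet], Tuple[ScoreMatrix, AnnotationSet]]:
    """Disjoint uniform random calibration/test split of the rows."""
    n = len(ann)
    if not 0 < n_cal < n:
        raise ValueError(
            f"calibration size {n_cal} infeasible for pool of {n} proteins"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_ids = [ann.proteins[i] for i in sorted(perm[:n_cal])]
    test_ids = [ann.proteins[i] for i in sorted(perm[n_cal:])]
    return (
        (scores.subset(cal_ids), ann.subset(cal_ids)),
        (scores.subset(test_ids), ann.subset(test_ids)),
    )


def make_dataset(cfg: GeneratorConfig):
    """Convenience: labels, scores and embeddings from one config."""
    ann = generate_labels(cfg)
    scores = generate_scores(ann, cfg)
    emb = generate_embeddings(ann, cfg)
    return ann, scores, emb
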