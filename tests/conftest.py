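import numpy as np
import pytest

from conformal_ec.ontology import AnnotationSet, parse_ec
from conformal_ec.simulate import GeneratorConfig, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean synthetic pool shared across tests (read-only)."""
    cfg = GeneratorConfig(n_proteins=300, n_labels=16,
                          hierarchy_shape=(2, 2, 2, 2), seed=11)
    return cfg, *make_dataset(cfg)


@pytest.fixture
def toy_annotations():
    return AnnotationSet(
        {
            "A": {parse_ec("1.1.1.1")},
            "B": {parse_ec("1.1.1.2"), parse_ec("2.3.4.5")},
            "C": {parse_ec("2.3.4.5")},
        }
    )


def random_instance(rng, n=20, k=10):
    """Random score matrix + annotations for oracle comparisons."""
    from conformal_ec.conformal import ScoreMatrix

    universe = [parse_ec(f"{j // 4 + 1}.{j % 4 + 1}.1.{j + 1}") for j in range(k)]
    labels_of = {}
    for i in range(n):
        m = 1 + (rng.random() < 0.2)
        labels_of[f"P{i}"] = set(
            universe[j] for j in rng.choice(k, size=m, replace=False)
        )
    ann = AnnotationSet(labels_of, universe=universe)
    scores = rng.random((n, k))
    return ScoreMatrix([f"P{i}" for i in range(n)], universe, scores), ann
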