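import numpy as np
import pytest

from vblmf import Hyperparameters, fit, make_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """30x20 block-kernel scenario used by several modules' tests."""
    return make_scenario(I=30, J=20, L_true=3, n_drug_blocks=3,
                         n_target_blocks=2, seed=7)


@pytest.fixture(scope="session")
def fitted_small(small_scenario):
    """A converged fit of the small scenario (package defaults except L)."""
    hyper = Hyperparameters(L=3, iterations=15, seed=7)
    return fit(small_scenario.data, small_scenario.drug_kernels,
               small_scenario.target_kernels, hyper, record="sweep")


def brute_force_auroc(scores, labels) -> float:
    """Pair-counting oracle: P(random positive outscores random negative),
    ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_average_precision(scores, labels) -> float:
    """Step oracle for AUPRC with distinct scores: mean precision at each
    positive's rank when sorted by descending score."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores)
    lab = labels[order]
    hits = 0
    out = 0.0
    for k, y in enumerate(lab, start=1):
        if y == 1:
            hits += 1
            out += hits / k
    return out / labels.sum()
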