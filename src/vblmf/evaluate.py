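"""Cross-validation machinery, ranking metrics, and learning curves.

Three blinding schemes are supported, mirroring the standard DTI protocol:

* CVS1 — random cells: all I*J entries (both classes) are partitioned into
  folds; blinded cells become unobserved zeros during training and are
  scored against their true values.
* CVS2 — random drugs: whole rows are blinded; every cell of a test row is
  scored.  Blinded rows are empty in the training matrix, so their mask is
  0 and their factors are informed by the kernel prior only (no leakage).
* CVS3 — random targets: the column-wise analogue of CVS2.

AUROC is the probability a random positive outscores a random negative
(ties count 1/2); AUPRC is step-wise average precision.  Both are delegated
to scikit-learn and cross-checked against exhaustive brute-force oracles in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .inference import fit
from .kernels import KernelSet, identity_kernelset
from .model import Hyperparameters, InteractionData
from .predict import predict_probabilities

logger = logging.getLogger(__name__)

SETTINGS = ("cvs1", "cvs2", "cvs3")


class MetricUndefinedError(ValueError):
    """Raised when a metric is requested on a degenerate label set."""


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (tie-aware rank statistic)."""
    labels = np.asarray(labels)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise MetricUndefinedError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve as step-wise average precision
    (precision summed at each recall increment; no trapezoidal smoothing)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise MetricUndefinedError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class FoldPlan:
    """Reproducible fold assignments for one CV experiment.

    ``folds[r][f]`` holds, per repeat r and fold f, an ``(n, 2)`` array of
    blinded cells (CVS1) or a 1-D array of blinded row/column indices
    (CVS2/CVS3).
    """

    setting: str
    n_folds: int
    n_repeats: int
    seed: int
    folds: tuple[tuple[np.ndarray, ...], ...]

    def to_dict(self) -> dict:
        return {
            "setting": self.setting,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "folds": [[f.tolist() for f in rep] for rep in self.folds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldPlan":
        folds = tuple(
            tuple(np.asarray(f, dtype=int) for f in rep) for rep in d["folds"]
        )
        return cls(d["setting"], d["n_folds"], d["n_repeats"], d["seed"], folds)


def make_folds(
    data: InteractionData,
    setting: str,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Partition cells (CVS1), drug rows (CVS2) or target columns (CVS3)
    into disjoint folds, independently per repeat.  Deterministic in seed."""
    setting = setting.lower()
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}, got {setting!r}")
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    I, J = data.shape
    if setting == "cvs2" and n_folds > I:
        raise ValueError(f"cvs2 with {n_folds} folds needs >= {n_folds} drugs, have {I}")
    if setting == "cvs3" and n_folds > J:
        raise ValueError(f"cvs3 with {n_folds} folds needs >= {n_folds} targets, have {J}")
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        if setting == "cvs1":
            cells = np.stack(np.unravel_index(rng.permutation(I * J), (I, J)), axis=1)
            repeats.append(tuple(np.array_split(cells, n_folds)))
        elif setting == "cvs2":
            repeats.append(tuple(np.array_split(rng.permutation(I), n_folds)))
        else:
            repeats.append(tuple(np.array_split(rng.permutation(J), n_folds)))
    return FoldPlan(setting, n_folds, n_repeats, seed, tuple(repeats))


@dataclass(frozen=True)
class MetricSummary:
    """Per-fold metrics with means and normal-approximation 95% CIs."""

    per_fold: pd.DataFrame  # columns: repeat, fold, auroc, auprc
    n_skipped: int

    @property
    def mean_auroc(self) -> float:
        return float(self.per_fold["auroc"].mean())

    @property
    def mean_auprc(self) -> float:
        return float(self.per_fold["auprc"].mean())

    def ci_halfwidth(self, metric: str) -> float:
        vals = self.per_fold[metric]
        if len(vals) < 2:
            return float("nan")
        return float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))

    def to_dict(self) -> dict:
        return {
            "n_folds_scored": int(len(self.per_fold)),
            "n_folds_skipped": self.n_skipped,
            "auroc_mean": self.mean_auroc,
            "auroc_ci95": self.ci_halfwidth("auroc"),
            "auprc_mean": self.mean_auprc,
            "auprc_ci95": self.ci_halfwidth("auprc"),
            "auprc_definition": "stepwise average precision",
        }


def _blind_and_score_sets(data: InteractionData, setting: str, fold: np.ndarray):
    """Training data with the fold blinded, plus the test cell index arrays."""
    I, J = data.shape
    if setting == "cvs1":
        train = data.blinded(cells=fold)
        ti, tj = fold[:, 0], fold[:, 1]
    elif setting == "cvs2":
        train = data.blinded(rows=fold)
        ti = np.repeat(fold, J)
        tj = np.tile(np.arange(J), fold.size)
        assert np.all(train.m_u[fold] == 0), "test rows leaked into training mask"
    else:
        train = data.blinded(cols=fold)
        ti = np.tile(np.arange(I), fold.size)
        tj = np.repeat(fold, I)
        assert np.all(train.m_v[fold] == 0), "test columns leaked into training mask"
    return train, ti, tj


def cross_validate(
    data: InteractionData,
    drug_kernels: KernelSet,
    target_kernels: KernelSet,
    hyper: Hyperparameters,
    plan: FoldPlan,
    mode: str = "plugin",
) -> MetricSummary:
    """Blind each fold, refit from scratch, score the blinded cells against
    their true values; aggregate per-fold AUROC/AUPRC."""
    rows = []
    skipped = 0
    for r, repeat in enumerate(plan.folds):
        for f, fold in enumerate(repeat):
            train, ti, tj = _blind_and_score_sets(data, plan.setting, fold)
            labels = data.R[ti, tj]
            if labels.sum() == 0 or labels.sum() == labels.size:
                logger.warning("repeat %d fold %d: degenerate test labels; skipped", r, f)
                skipped += 1
                continue
            state = fit(train, drug_kernels, target_kernels, hyper, record="none")
            scores = predict_probabilities(state, mode=mode).P[ti, tj]
            rows.append(
                {"repeat": r, "fold": f,
                 "auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}
            )
    return MetricSummary(per_fold=pd.DataFrame(rows), n_skipped=skipped)


def learning_curve(
    data: InteractionData,
    drug_kernels: KernelSet,
    target_kernels: KernelSet,
    hyper: Hyperparameters,
    train_fractions: Sequence[float],
    seeds: Sequence[int],
    test_fraction: float = 0.2,
    mode: str = "plugin",
) -> pd.DataFrame:
    """Prior-fading experiment: metrics vs. training size, with and without
    side information.

    Per seed, a fixed random ``test_fraction`` of cells is held out; for each
    training fraction f, a random f-subset of the remaining cells stays
    observed (the rest is blinded to unobserved zeros) and the model is fit
    twice — ``kernels='on'`` with the given kernels, ``'off'`` with identity
    kernels (Laplacian vanishes, leaving the alpha ridge).  Returns a tidy
    table with columns (fraction, seed, condition, auroc, auprc).
    """
    fractions = [float(f) for f in train_fractions]
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("train fractions must be in (0, 1]")
    I, J = data.shape
    id_u = identity_kernelset(data.drug_ids, "drug")
    id_v = identity_kernelset(data.target_ids, "target")
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = np.stack(np.unravel_index(rng.permutation(I * J), (I, J)), axis=1)
        n_test = max(1, int(round(test_fraction * I * J)))
        test, pool = perm[:n_test], perm[n_test:]
        labels = data.R[test[:, 0], test[:, 1]]
        if labels.sum() == 0:
            logger.warning("seed %d: no positive test cell; skipped", seed)
            continue
        for frac in fractions:
            n_keep = int(round(frac * len(pool)))
            hidden = np.concatenate([test, pool[n_keep:]], axis=0)
            train = data.blinded(cells=hidden)
            if train.R.sum() == 0:
                logger.warning("seed %d fraction %g: no positives left; skipped",
                               seed, frac)
                continue
            for cond, ku, kv in (
                ("on", drug_kernels, target_kernels),
                ("off", id_u, id_v),
            ):
                state = fit(train, ku, kv, hyper, record="none")
                scores = predict_probabilities(state, mode=mode).P[test[:, 0], test[:, 1]]
                rows.append(
                    {"fraction": frac, "seed": seed, "condition": cond,
                     "auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}
                )
    return pd.DataFrame(rows)


def summarize_learning_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% CI half-width per (fraction, condition)."""
    def ci(x):
        return 1.96 * x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    return (
        table.groupby(["fraction", "condition"])
        .agg(auroc_mean=("auroc", "mean"), auroc_ci95=("auroc", ci),
             auprc_mean=("auprc", "mean"), auprc_ci95=("auprc", ci))
        .reset_index()
    )
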