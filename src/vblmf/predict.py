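"""Posterior predictions: interaction probabilities, promiscuity and
druggability expectations, novel-interaction ranking, latent exports.

The interaction probability is the logistic link applied to the latent
inner product.  Two modes are offered: the plug-in sigma(E[u]^T E[v]) and
a moment-corrected link sigma(mu / sqrt(1 + pi s^2 / 8)) that integrates
the Gaussian uncertainty of u^T v through the probit approximation of the
sigmoid (it shrinks probabilities toward 0.5 when the posterior is wide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as sigmoid

from .inference import VariationalState, second_moment_products
from .model import InteractionData

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionMatrix:
    """Posterior interaction probabilities with their provenance."""

    P: np.ndarray
    link_mode: str  # 'plugin' | 'moment'
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]


@dataclass(frozen=True)
class PromiscuityReport:
    """Expected interaction counts (sum of probabilities, independence
    assumed across cells)."""

    expected: pd.Series  # indexed by entity id
    axis: str            # 'drug' | 'target'
    subset: tuple[str, ...] | None
    note: str = "expected counts assume independent Bernoulli cells"


def predict_probabilities(state: VariationalState, mode: str = "plugin") -> PredictionMatrix:
    """Interaction probability matrix from a fitted state.

    ``plugin``: P_ij = sigma(E[u_i]^T E[v_j]).
    ``moment``: P_ij = sigma(mu_ij / sqrt(1 + pi s2_ij / 8)) with mu, s2 the
    posterior mean and variance of u_i^T v_j.
    """
    mu = state.U_post.mean.T @ state.V_post.mean
    if mode == "plugin":
        P = sigmoid(mu)
    elif mode == "moment":
        s2 = second_moment_products(state.U_post, state.V_post) - mu**2
        s2 = np.maximum(s2, 0.0)
        P = sigmoid(mu / np.sqrt(1.0 + np.pi * s2 / 8.0))
    else:
        raise ValueError(f"mode must be 'plugin' or 'moment', got {mode!r}")
    return PredictionMatrix(
        P=P, link_mode=mode,
        drug_ids=state.data.drug_ids, target_ids=state.data.target_ids,
    )


def expected_interactions(
    P: PredictionMatrix, axis: str = "drug", subset: Sequence[str] | None = None
) -> PromiscuityReport:
    """Per-drug (promiscuity) or per-target (druggability) expected number of
    interactions: the row/column sum of predicted probabilities, optionally
    restricted to a named subset of the opposite side."""
    if axis == "drug":
        own_ids, other_ids, M = P.drug_ids, P.target_ids, P.P
    elif axis == "target":
        own_ids, other_ids, M = P.target_ids, P.drug_ids, P.P.T
    else:
        raise ValueError(f"axis must be 'drug' or 'target', got {axis!r}")
    if subset is not None:
        subset = tuple(str(s) for s in subset)
        unknown = [s for s in subset if s not in other_ids]
        if unknown:
            raise ValueError(f"subset ids not in model: {unknown}")
        cols = [other_ids.index(s) for s in subset]
        M = M[:, cols] if cols else np.zeros((M.shape[0], 0))
    expected = pd.Series(M.sum(axis=1), index=list(own_ids), name="expected_interactions")
    return PromiscuityReport(expected=expected, axis=axis, subset=subset)


def rank_novel(
    P: PredictionMatrix, data: InteractionData, top_k: int
) -> list[tuple[str, str, float]]:
    """Top-k unobserved (R_ij = 0) pairs by predicted probability.

    Ties are broken by (drug index, target index) for determinism.
    """
    if P.P.shape != data.shape:
        raise ValueError("prediction matrix not aligned with interaction data")
    zi, zj = np.nonzero(data.R == 0)
    probs = P.P[zi, zj]
    order = np.lexsort((zj, zi, -probs))
    order = order[: min(top_k, order.size)]
    return [
        (data.drug_ids[zi[o]], data.target_ids[zj[o]], float(probs[o]))
        for o in order
    ]


def export_latent(
    state: VariationalState, annotations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Posterior-mean latent coordinates for all drugs and targets.

    One row per entity with columns ``entity_id, side, coord_1..coord_L,
    label``; suitable for scatter (L = 2) or parallel-coordinates plots.
    Annotation ids absent from the model are logged and skipped.
    """
    annotations = dict(annotations or {})
    known = set(state.data.drug_ids) | set(state.data.target_ids)
    for k in list(annotations):
        if k not in known:
            logger.warning("annotation id %r not in model; skipped", k)
            annotations.pop(k)
    L = state.hyper.L
    rows = []
    for ids, side, mean in (
        (state.data.drug_ids, "drug", state.U_post.mean),
        (state.data.target_ids, "target", state.V_post.mean),
    ):
        for i, eid in enumerate(ids):
            row = {"entity_id": eid, "side": side}
            row.update({f"coord_{l + 1}": mean[l, i] for l in range(L)})
            row["label"] = annotations.get(eid, "")
            rows.append(row)
    return pd.DataFrame(rows)
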