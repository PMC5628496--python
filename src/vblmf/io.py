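"""File formats and model serialization.

All tabular files are tab-separated, UTF-8, '.' decimal, unquoted — the
dialect of the public DTI gold-standard distributions.  Interaction files
are drugs-as-rows: the header row holds target identifiers, the first
column drug identifiers, cells are 0/1.  Kernel files are square with the
same identifiers on both axes.

A fitted model is serialized as a directory holding one ``.npz`` with all
numeric arrays (exact binary floats, so save -> load -> predict is bitwise
stable) plus a JSON metadata file (identifiers, hyperparameters, ELBO
trace, seed, software version).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import FactorPosterior, GammaPosterior, VariationalState
from .kernels import Kernel, KernelSet
from .model import Hyperparameters, InteractionData, likelihood_aux

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # ragged rows, empty file, ...
        raise ParseError(f"{path}: cannot parse as TSV matrix ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_interactions(path, transpose: bool = False) -> InteractionData:
    """Read a binary interaction TSV (drugs as rows unless ``transpose``)."""
    df = _read_tsv(path)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicated drug ids {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicated target ids {dups}")
    R = np.empty(df.shape)
    for i, (rid, row) in enumerate(df.iterrows()):
        for j, val in enumerate(row):
            s = str(val).strip()
            if s not in ("0", "1"):
                raise ParseError(
                    f"{path}: non-binary cell at drug {rid!r} / "
                    f"target {df.columns[j]!r}: {val!r}"
                )
            R[i, j] = float(s)
    return InteractionData(R, tuple(df.index), tuple(df.columns))


def load_kernel(path, expected_ids, name: str | None = None) -> Kernel:
    """Read a square similarity TSV, reorder to ``expected_ids``, and
    average away asymmetry beyond 1e-8 (with a logged warning)."""
    df = _read_tsv(path)
    expected = [str(i) for i in expected_ids]
    missing = sorted(set(expected) - set(df.index))
    extra = sorted(set(df.index) - set(expected))
    col_missing = sorted(set(expected) - set(df.columns))
    if missing or extra or col_missing:
        raise ParseError(
            f"{path}: id mismatch (missing rows {missing}, extra rows {extra}, "
            f"missing columns {col_missing})"
        )
    df = df.loc[expected, expected]
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric similarity value ({exc})") from exc
    asym = float(np.max(np.abs(S - S.T))) if S.size else 0.0
    if asym > 1e-8:
        logger.warning("%s: asymmetric by %.3g; symmetrized by averaging", path, asym)
        S = 0.5 * (S + S.T)
    return Kernel(name or Path(path).stem, S, tuple(expected))


def load_kernelset(named_paths, expected_ids, side: str) -> KernelSet:
    """Load ``NAME=PATH`` pairs (or bare paths) into an aligned KernelSet."""
    kernels = []
    for item in named_paths:
        if "=" in str(item):
            nm, p = str(item).split("=", 1)
        else:
            nm, p = None, item
        kernels.append(load_kernel(p, expected_ids, name=nm))
    return KernelSet(tuple(kernels), side)


# ---------------------------------------------------------------------------
# writers


def write_matrix_tsv(path, M: np.ndarray, row_ids, col_ids) -> None:
    pd.DataFrame(M, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def write_interactions_tsv(path, data: InteractionData) -> None:
    pd.DataFrame(
        data.R.astype(int), index=list(data.drug_ids), columns=list(data.target_ids)
    ).to_csv(path, sep="\t")


def write_predictions_tsv(path, P, drug_ids, target_ids) -> None:
    """Long-form (drug_id, target_id, probability) table."""
    I, J = P.shape
    di = np.repeat(list(drug_ids), J)
    tj = np.tile(list(target_ids), I)
    pd.DataFrame(
        {"drug_id": di, "target_id": tj, "probability": P.reshape(-1)}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_scenario(directory, scenario) -> None:
    """Write a synthetic scenario: interaction TSV, kernel TSVs, and a
    ground-truth JSON (true factors, P*, generator parameters)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_interactions_tsv(d / "interactions.tsv", scenario.data)
    for k in scenario.drug_kernels:
        write_matrix_tsv(d / f"drug_kernel_{k.name}.tsv", k.S, k.ids, k.ids)
    for k in scenario.target_kernels:
        write_matrix_tsv(d / f"target_kernel_{k.name}.tsv", k.S, k.ids, k.ids)
    truth = {
        "U": scenario.U.tolist(),
        "V": scenario.V.tolist(),
        "P_star": scenario.P_star.tolist(),
        "shift": scenario.shift,
        "scale": scenario.scale,
        "params": scenario.params,
        "seed": scenario.seed,
    }
    (d / "ground_truth.json").write_text(json.dumps(truth))


# ---------------------------------------------------------------------------
# model serialization


def save_model(directory, state: VariationalState) -> None:
    """Serialize a fitted state: arrays to ``arrays.npz``, metadata to JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {
        "R": state.data.R,
        "mean_u": state.U_post.mean,
        "cov_u": state.U_post.covariance,
        "prec_u": state.U_post.precision,
        "mean_v": state.V_post.mean,
        "cov_v": state.V_post.covariance,
        "prec_v": state.V_post.precision,
        "gamma_u_shape": state.gamma_u.shape,
        "gamma_u_rate": state.gamma_u.rate,
        "gamma_v_shape": state.gamma_v.shape,
        "gamma_v_rate": state.gamma_v.rate,
        "xi": state.aux.xi,
    }
    for side, ks in (("u", state.drug_kernels), ("v", state.target_kernels)):
        for idx, k in enumerate(ks):
            arrays[f"kernel_{side}_{idx}"] = k.S
    np.savez(d / "arrays.npz", **arrays)
    meta = {
        "version": __version__,
        "drug_ids": list(state.data.drug_ids),
        "target_ids": list(state.data.target_ids),
        "kernel_names_u": [k.name for k in state.drug_kernels],
        "kernel_names_v": [k.name for k in state.target_kernels],
        "hyperparameters": {
            "L": state.hyper.L, "c": state.hyper.c,
            "alpha_u": state.hyper.alpha_u, "alpha_v": state.hyper.alpha_v,
            "a": state.hyper.a, "b": state.hyper.b,
            "neighbors": state.hyper.neighbors,
            "iterations": state.hyper.iterations, "seed": state.hyper.seed,
        },
        "elbo_trace": list(state.elbo_trace),
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(directory) -> VariationalState:
    """Inverse of :func:`save_model`; predictions from the loaded state are
    bitwise identical to the original."""
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    with np.load(d / "arrays.npz") as z:
        arrays = {k: z[k] for k in z.files}
    hyper = Hyperparameters(**meta["hyperparameters"])
    data = InteractionData(
        arrays["R"], tuple(meta["drug_ids"]), tuple(meta["target_ids"])
    )
    kernels = {}
    for side, ids, names in (
        ("u", data.drug_ids, meta["kernel_names_u"]),
        ("v", data.target_ids, meta["kernel_names_v"]),
    ):
        ks = tuple(
            Kernel(nm, arrays[f"kernel_{side}_{idx}"], ids)
            for idx, nm in enumerate(names)
        )
        kernels[side] = KernelSet(ks, "drug" if side == "u" else "target")
    U_post = FactorPosterior(arrays["mean_u"], arrays["cov_u"], arrays["prec_u"])
    V_post = FactorPosterior(arrays["mean_v"], arrays["cov_v"], arrays["prec_v"])
    return VariationalState(
        data=data, hyper=hyper,
        drug_kernels=kernels["u"], target_kernels=kernels["v"],
        U_post=U_post, V_post=V_post,
        gamma_u=GammaPosterior(arrays["gamma_u_shape"], arrays["gamma_u_rate"]),
        gamma_v=GammaPosterior(arrays["gamma_v_shape"], arrays["gamma_v_rate"]),
        aux=likelihood_aux(data, hyper.c, arrays["xi"]),
        elbo_trace=tuple(meta["elbo_trace"]),
    )
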