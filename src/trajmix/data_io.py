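"""Longitudinal CSV input and model-file serialization.

The observation-level table is long format: one row per observation with
a subject-identifier column, fully observed predictor columns, and
continuous/binary target columns in which individual cells may be
missing (empty string or NaN).  Model files are versioned JSON archives;
floats are written with full ``repr`` precision so a save/load round
trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import PriorSpec, TrajModel, VariationalPosterior

MODEL_FORMAT = "trajmix-model"
MODEL_VERSION = 1


class DataValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


class ModelFileError(ValueError):
    """Raised when a model file is corrupted or has an unsupported version."""


@dataclass
class LongitudinalDataset:
    """Observation-level longitudinal table grouped by subject.

    ``Y`` and ``B`` hold NaN where a target cell is missing; the boolean
    masks expose observed cells.  Predictors are dense (rows with missing
    predictors are rejected at load).
    """

    subject_ids: np.ndarray          # (n_obs,) object/int
    X: np.ndarray                    # (n_obs, M)
    Y: np.ndarray                    # (n_obs, D_c) with NaN for missing
    B: np.ndarray                    # (n_obs, D_b) in {0,1,NaN}
    predictor_names: list[str]
    continuous_names: list[str]
    binary_names: list[str]
    subject_col: str = "id"
    subjects: list = field(init=False)
    subject_index: dict = field(init=False)

    def __post_init__(self):
        n = len(self.subject_ids)
        self.X = np.asarray(self.X, dtype=float).reshape(n, -1)
        self.Y = np.asarray(self.Y, dtype=float).reshape(n, len(self.continuous_names))
        self.B = np.asarray(self.B, dtype=float).reshape(n, len(self.binary_names))
        if not np.all(np.isfinite(self.X)):
            bad = int(np.argwhere(~np.isfinite(self.X))[0, 0])
            raise DataValidationError(f"missing/non-finite predictor value at data row {bad + 1}")
        obs = ~np.isnan(self.B)
        if not np.all(np.isin(self.B[obs], (0.0, 1.0))):
            bad_rows = np.where((obs & ~np.isin(self.B, (0.0, 1.0))).any(axis=1))[0]
            raise DataValidationError(
                f"binary target contains a value outside {{0,1}} at data row {bad_rows[0] + 1}")
        # subject index map: first-appearance order, partitions the rows
        self.subjects = list(dict.fromkeys(self.subject_ids.tolist()))
        lut = {s: j for j, s in enumerate(self.subjects)}
        self.subject_rows = np.asarray([lut[s] for s in self.subject_ids.tolist()], dtype=int)
        self.subject_index = {s: np.where(self.subject_rows == j)[0]
                              for j, s in enumerate(self.subjects)}

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def mask_c(self) -> np.ndarray:
        return ~np.isnan(self.Y)

    @property
    def mask_b(self) -> np.ndarray:
        return ~np.isnan(self.B)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.subject_col: self.subject_ids})
        for j, name in enumerate(self.predictor_names):
            df[name] = self.X[:, j]
        for j, name in enumerate(self.continuous_names):
            df[name] = self.Y[:, j]
        for j, name in enumerate(self.binary_names):
            df[name] = self.B[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def load_longitudinal_csv(path, subject_col: str,
                          predictors: Sequence[str],
                          targets_continuous: Sequence[str] = (),
                          targets_binary: Sequence[str] = ()) -> LongitudinalDataset:
    """Read and validate a long-format longitudinal CSV.

    Empty cells and the string "NaN" denote missing target values;
    missing predictors or subject ids are rejected.  Row order is
    preserved.
    """
    df = pd.read_csv(path)
    for col in [subject_col, *predictors, *targets_continuous, *targets_binary]:
        if col not in df.columns:
            raise DataValidationError(f"column '{col}' not found in {path}")
    if df[subject_col].isna().any():
        bad = int(df.index[df[subject_col].isna()][0])
        raise DataValidationError(f"missing subject id at data row {bad + 1}")
    n = len(df)
    return LongitudinalDataset(
        subject_ids=df[subject_col].to_numpy(dtype=object),
        X=df[list(predictors)].to_numpy(dtype=float) if predictors else np.empty((n, 0)),
        Y=(df[list(targets_continuous)].to_numpy(dtype=float)
           if targets_continuous else np.empty((n, 0))),
        B=(df[list(targets_binary)].to_numpy(dtype=float)
           if targets_binary else np.empty((n, 0))),
        predictor_names=list(predictors),
        continuous_names=list(targets_continuous),
        binary_names=list(targets_binary),
        subject_col=subject_col,
    )


def _arr_to_json(arr: Optional[np.ndarray]):
    if arr is None:
        return None
    return {"shape": list(arr.shape), "data": np.asarray(arr, dtype=float).ravel().tolist()}


def _arr_from_json(obj) -> Optional[np.ndarray]:
    if obj is None:
        return None
    return np.asarray(obj["data"], dtype=float).reshape(obj["shape"])


def save_model(model: TrajModel, path) -> None:
    """Serialize a fitted model to a versioned JSON archive."""
    p = model.prior
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "prior": {
            "predictor_names": p.predictor_names,
            "continuous_names": p.continuous_names,
            "binary_names": p.binary_names,
            "w0_c": _arr_to_json(p.w0_c), "p0_c": _arr_to_json(p.p0_c),
            "a0": _arr_to_json(p.a0), "b0": _arr_to_json(p.b0),
            "w0_b": _arr_to_json(p.w0_b), "p0_b": _arr_to_json(p.p0_b),
            "alpha": p.alpha, "K": int(p.K),
            "re_idx": p.re_idx,
            "S0": _arr_to_json(p.S0), "nu0": _arr_to_json(p.nu0),
            "lambda_fixed": _arr_to_json(p.lambda_fixed),
        },
        "posterior": {k: _arr_to_json(v) for k, v in model.posterior.array_fields().items()},
        "subject_ids": list(model.subject_ids),
        "metadata": model.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> TrajModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFileError(f"model file {path} is corrupted: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFileError(f"{path} is not a trajmix model file")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFileError(
            f"unsupported model file version {doc.get('version')!r} "
            f"(this build reads version {MODEL_VERSION})")
    pr = doc["prior"]
    prior = PriorSpec(
        predictor_names=pr["predictor_names"],
        continuous_names=pr["continuous_names"],
        binary_names=pr["binary_names"],
        w0_c=_arr_from_json(pr["w0_c"]), p0_c=_arr_from_json(pr["p0_c"]),
        a0=_arr_from_json(pr["a0"]), b0=_arr_from_json(pr["b0"]),
        w0_b=_arr_from_json(pr["w0_b"]), p0_b=_arr_from_json(pr["p0_b"]),
        alpha=pr["alpha"], K=pr["K"],
        re_idx=pr["re_idx"], S0=_arr_from_json(pr["S0"]),
        nu0=_arr_from_json(pr["nu0"]),
        lambda_fixed=_arr_from_json(pr["lambda_fixed"]),
    )
    po = doc["posterior"]
    posterior = VariationalPosterior(**{k: _arr_from_json(v) for k, v in po.items()})
    return TrajModel(prior=prior, posterior=posterior,
                     subject_ids=doc["subject_ids"], metadata=doc["metadata"])
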