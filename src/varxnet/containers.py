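"""Data containers for multichannel neural recordings and stimulus features.

Arrays follow the channels-by-samples convention throughout: a neural
recording is a ``d_y x T`` matrix ``y(t)`` and the time-aligned stimulus
features are a ``d_x x T`` matrix ``x(t)``.  Containers validate on
construction and carry the sampling rate so downstream lag settings can be
expressed in milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "NeuralTimeSeries",
    "StimulusFeatureSet",
    "LagSpec",
    "VARXModelFit",
    "AlignmentError",
    "InsufficientDataError",
    "DegenerateChannelError",
    "SingularDesignError",
    "InstabilityError",
    "read_dataset_h5",
    "write_dataset_h5",
    "read_dataset_csv",
    "read_model_h5",
    "write_model_h5",
]


class AlignmentError(ValueError):
    """Neural signal and stimulus features disagree in length or rate."""


class InsufficientDataError(ValueError):
    """Fewer samples than the requested lag history."""


class DegenerateChannelError(ValueError):
    """A channel (or feature) has zero variance and cannot be modeled."""


class SingularDesignError(np.linalg.LinAlgError):
    """Rank-deficient design with no ridge penalty; advise lambda > 0."""


class InstabilityError(ValueError):
    """Recurrent filter is unstable (companion spectral radius >= 1)."""


def _as_2d_float(data, name: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (channels x samples) array")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class NeuralTimeSeries:
    """Multichannel neural signal ``y(t)``, shape ``(d_y, T)``.

    Parameters
    ----------
    data : array-like, shape (d_y, T)
        Signal in arbitrary units (e.g. LFP voltage or BHA power envelope).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str, optional
    condition_label : str
        Experimental condition tag (e.g. ``"movie"`` or ``"rest"``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data, "data")
        if self.data.shape[1] < 1 or self.data.shape[0] < 1:
            raise ValueError("need at least one channel and one sample")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal channel count")

    def require_nondegenerate(self) -> None:
        """Reject zero-variance channels (called at model-fit validation)."""
        variances = self.data.var(axis=1)
        if self.n_samples > 1 and np.any(variances == 0.0):
            bad = [self.channel_labels[i] for i in np.flatnonzero(variances == 0.0)]
            raise DegenerateChannelError(f"zero-variance channel(s): {bad}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class StimulusFeatureSet:
    """Extrinsic input features ``x(t)``, shape ``(d_x, T)``.

    ``feature_kinds`` marks each row as ``"pulse"`` (sparse nonnegative event
    train) or ``"continuous"`` (dense regressor such as a sound envelope).
    An empty set (``d_x = 0``) is valid and denotes a VAR model.
    """

    data: np.ndarray
    fs: float
    feature_labels: list[str] = field(default_factory=list)
    feature_kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError("data must be 2-D (features x samples)")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("data contains non-finite values")
        self.data = arr
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.feature_labels:
            self.feature_labels = [f"x{i}" for i in range(self.n_features)]
        if not self.feature_kinds:
            self.feature_kinds = ["continuous"] * self.n_features
        if len(self.feature_labels) != self.n_features:
            raise ValueError("feature_labels length must equal feature count")
        if len(self.feature_kinds) != self.n_features:
            raise ValueError("feature_kinds length must equal feature count")
        for kind in self.feature_kinds:
            if kind not in ("pulse", "continuous"):
                raise ValueError(f"unknown feature kind {kind!r}")
        for i, kind in enumerate(self.feature_kinds):
            if kind == "pulse" and arr.size and np.any(arr[i] < 0):
                raise ValueError(f"pulse feature {self.feature_labels[i]!r} has negative values")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @classmethod
    def empty(cls, T: int, fs: float) -> "StimulusFeatureSet":
        """A zero-feature set (pure VAR modeling) of length ``T``."""
        return cls(data=np.zeros((0, T)), fs=fs)


@dataclass(frozen=True)
class LagSpec:
    """Lag and regularization settings.

    ``n_a`` recurrent taps at lags 1..n_a, ``n_b`` input taps at lags
    0..n_b-1 (so 36 taps at 60 Hz span 0-583 ms), and a dimensionless ridge
    weight ``lambda_reg`` applied to internally standardized predictors.
    """

    n_a: int = 6
    n_b: int = 36
    lambda_reg: float = 0.3

    def __post_init__(self) -> None:
        if self.n_a < 0:
            raise ValueError("n_a must be >= 0")
        if self.n_b < 1:
            raise ValueError("n_b must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")

    @property
    def history(self) -> int:
        """Samples of history consumed before the first usable target."""
        return max(self.n_a, self.n_b - 1)


@dataclass
class VARXModelFit:
    """Fitted VARX parameters and innovation estimate.

    ``A`` has shape ``(d_y, d_y, n_a)`` (lags 1..n_a), ``B`` has shape
    ``(d_y, d_x, n_b)`` (lags 0..n_b-1).  ``residuals`` is the estimated
    innovation ``e(t)`` over the ``T_eff`` fitted samples and
    ``sigma2_full`` its per-channel mean square.
    """

    A: np.ndarray
    B: np.ndarray
    sigma2_full: np.ndarray
    residuals: np.ndarray
    lag_spec: LagSpec
    T_eff: int
    fs: float = 1.0
    channel_labels: list[str] = field(default_factory=list)
    feature_labels: list[str] = field(default_factory=list)

    @property
    def d_y(self) -> int:
        return self.A.shape[0]

    @property
    def d_x(self) -> int:
        return self.B.shape[1]


# ---------------------------------------------------------------------------
# HDF5 / CSV I/O


def write_dataset_h5(path, y: NeuralTimeSeries, x: StimulusFeatureSet) -> None:
    """Write a paired recording to HDF5 (datasets /y, /x plus attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=y.data, dtype="float64")
        f.create_dataset("x", data=x.data, dtype="float64")
        f.attrs["fs"] = float(y.fs)
        f.attrs["channel_labels"] = json.dumps(y.channel_labels)
        f.attrs["condition_label"] = y.condition_label
        f.attrs["feature_labels"] = json.dumps(x.feature_labels)
        f.attrs["feature_kinds"] = json.dumps(x.feature_kinds)


def read_dataset_h5(path) -> tuple[NeuralTimeSeries, StimulusFeatureSet]:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        y = NeuralTimeSeries(
            data=f["y"][()],
            fs=fs,
            channel_labels=json.loads(f.attrs.get("channel_labels", "[]")),
            condition_label=str(f.attrs.get("condition_label", "")),
        )
        x = StimulusFeatureSet(
            data=f["x"][()],
            fs=fs,
            feature_labels=json.loads(f.attrs.get("feature_labels", "[]")),
            feature_kinds=json.loads(f.attrs.get("feature_kinds", "[]")),
        )
    return y, x


def read_dataset_csv(y_path, fs: float, x_path=None) -> tuple[NeuralTimeSeries, StimulusFeatureSet]:
    """Read small recordings from CSV files with samples as rows."""
    ydf = pd.read_csv(y_path)
    y = NeuralTimeSeries(data=ydf.to_numpy().T, fs=fs, channel_labels=list(ydf.columns))
    if x_path is None:
        x = StimulusFeatureSet.empty(y.n_samples, fs)
    else:
        xdf = pd.read_csv(x_path)
        x = StimulusFeatureSet(data=xdf.to_numpy().T, fs=fs, feature_labels=list(xdf.columns))
    return y, x


def write_model_h5(path, fit: VARXModelFit, metadata: dict | None = None) -> None:
    """Persist a fit: /A, /B, /sigma2, /residuals plus a JSON metadata block."""
    meta = {
        "lambda_reg": fit.lag_spec.lambda_reg,
        "n_a": fit.lag_spec.n_a,
        "n_b": fit.lag_spec.n_b,
        "fs": fit.fs,
        "T_eff": fit.T_eff,
        "channel_labels": fit.channel_labels,
        "feature_labels": fit.feature_labels,
    }
    if metadata:
        meta.update(metadata)
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=fit.A)
        f.create_dataset("B", data=fit.B)
        f.create_dataset("sigma2", data=fit.sigma2_full)
        f.create_dataset("residuals", data=fit.residuals)
        f.attrs["metadata"] = json.dumps(meta)


def read_model_h5(path) -> tuple[VARXModelFit, dict]:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        fit = VARXModelFit(
            A=f["A"][()],
            B=f["B"][()],
            sigma2_full=f["sigma2"][()],
            residuals=f["residuals"][()],
            lag_spec=LagSpec(meta["n_a"], meta["n_b"], meta["lambda_reg"]),
            T_eff=int(meta["T_eff"]),
            fs=float(meta.get("fs", 1.0)),
            channel_labels=list(meta.get("channel_labels", [])),
            feature_labels=list(meta.get("feature_labels", [])),
        )
    return fit, meta
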