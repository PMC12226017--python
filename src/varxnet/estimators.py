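"""VARX and temporal-response-function estimators.

The central model is the vector autoregression with exogenous input,

    y_i(t) = sum_j sum_{tau=1}^{n_a} A_ij(tau) y_j(t-tau)
           + sum_j sum_{tau=0}^{n_b-1} B_ij(tau) x_j(t-tau) + e_i(t),

fitted by (optionally ridge-regularized) least squares on the innovation
power ``sigma^2 = mean_t e(t)^2``.  ``A`` captures intrinsic recurrent
connectivity between channels, ``B`` the feed-forward stimulus response,
and ``e(t)`` the unobserved innovation driving intrinsic variability.

Estimators follow scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit``, fitted attributes with a trailing
underscore, and ``get_params``/``set_params`` inherited from
``BaseEstimator``.  Channels-by-samples arrays or the containers from
:mod:`varxnet.containers` are accepted interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .containers import (
    AlignmentError,
    InsufficientDataError,
    LagSpec,
    NeuralTimeSeries,
    SingularDesignError,
    StimulusFeatureSet,
    VARXModelFit,
)

__all__ = [
    "VARX",
    "TemporalResponseFunction",
    "build_lagged_design",
    "design_column_blocks",
    "shuffle_features",
    "fit_varx",
    "fit_var_control",
    "fit_mtrf",
]


def _coerce_y(y, fs: float) -> NeuralTimeSeries:
    if isinstance(y, NeuralTimeSeries):
        return y
    return NeuralTimeSeries(data=np.asarray(y, dtype=float), fs=fs)


def _coerce_x(x, T: int, fs: float) -> StimulusFeatureSet:
    if x is None:
        return StimulusFeatureSet.empty(T, fs)
    if isinstance(x, StimulusFeatureSet):
        return x
    return StimulusFeatureSet(data=np.asarray(x, dtype=float), fs=fs)


def design_column_blocks(d_y: int, d_x: int, lags: LagSpec) -> list[tuple[str, int, slice]]:
    """Column layout of the lagged design matrix.

    Columns are grouped by predictor source: first one block of ``n_a``
    recurrent lags (tau = 1..n_a) per signal channel, then one block of
    ``n_b`` input lags (tau = 0..n_b-1) per stimulus feature.  Returns
    ``(kind, source_index, column_slice)`` triples with kind in
    ``{"y", "x"}``.  This ordering is stable and is relied on by the
    Granger reduced-model solver.
    """
    blocks = []
    col = 0
    for j in range(d_y):
        blocks.append(("y", j, slice(col, col + lags.n_a)))
        col += lags.n_a
    for j in range(d_x):
        blocks.append(("x", j, slice(col, col + lags.n_b)))
        col += lags.n_b
    return blocks


def build_lagged_design(y, x, lags: LagSpec, fs: float = 1.0):
    """Build the lagged design matrix and aligned targets.

    For each target sample ``t`` the predictor row holds ``y_j(t - tau)``
    for tau = 1..n_a (all channels j) followed by ``x_j(t - tau)`` for
    tau = 0..n_b-1 (all features j).  Rows with incomplete history are
    dropped, so ``T_eff = T - max(n_a, n_b - 1)``.

    Returns
    -------
    D : ndarray, shape (T_eff, n_cols)
    Y : ndarray, shape (T_eff, d_y)
        Targets aligned with the rows of ``D``.
    """
    y = _coerce_y(y, fs)
    x = _coerce_x(x, y.n_samples, y.fs)
    if x.n_samples != y.n_samples:
        raise AlignmentError(
            f"y has {y.n_samples} samples but x has {x.n_samples}"
        )
    if x.fs != y.fs:
        raise AlignmentError(f"sampling rates differ: y fs={y.fs}, x fs={x.fs}")
    T = y.n_samples
    p0 = lags.history
    if T <= p0:
        raise InsufficientDataError(
            f"T={T} samples cannot support history of {p0} lags"
        )
    T_eff = T - p0
    d_y, d_x = y.n_channels, x.n_features
    n_cols = d_y * lags.n_a + d_x * lags.n_b
    D = np.empty((T_eff, n_cols))
    col = 0
    for j in range(d_y):
        for tau in range(1, lags.n_a + 1):
            D[:, col] = y.data[j, p0 - tau : T - tau]
            col += 1
    for j in range(d_x):
        for tau in range(lags.n_b):
            D[:, col] = x.data[j, p0 - tau : T - tau]
            col += 1
    Y = y.data[:, p0:].T.copy()
    return D, Y


def shuffle_features(x: StimulusFeatureSet, which=None) -> StimulusFeatureSet:
    """Circularly shift selected features by half the recording duration.

    The half-period circular shift destroys the time alignment with the
    neural signal (in expectation) while preserving each feature's marginal
    distribution and circular autocovariance exactly, so a model fitted on
    shuffled features has identical parameter count and input covariance
    structure.  Odd ``T`` rounds the shift down to ``floor(T/2)``.
    """
    if which is None:
        which = list(range(x.n_features))
    which = list(which)
    if not which:
        warnings.warn("shuffle_features called with an empty feature set; no-op")
        return x
    shifted = x.data.copy()
    shift = x.n_samples // 2
    for j in which:
        shifted[j] = np.roll(x.data[j], shift)
    return StimulusFeatureSet(
        data=shifted,
        fs=x.fs,
        feature_labels=list(x.feature_labels),
        feature_kinds=list(x.feature_kinds),
    )


class VARX(BaseEstimator):
    """Vector autoregression with exogenous input, fit by ridge least squares.

    Parameters
    ----------
    n_a : int, default 6
        Recurrent filter length in samples (lags 1..n_a).  At 60 Hz the
        default spans 100 ms.  ``n_a=0`` gives a pure moving-average model.
    n_b : int, default 36
        Input filter taps (lags 0..n_b-1); 36 taps at 60 Hz span 600 ms.
    lambda_reg : float, default 0.3
        Dimensionless ridge weight.  Predictor columns are standardized to
        unit power internally and the penalty ``lambda_reg * T_eff`` is
        applied to the standardized coefficients, then mapped back, so the
        value is comparable across signals with different units.
    fs : float, default 1.0
        Sampling rate assumed when plain arrays are passed to :meth:`fit`.

    Attributes
    ----------
    A_ : ndarray, shape (d_y, d_y, n_a)
        Recurrent filters, ``A_[i, j, tau-1]`` the effect of channel j at
        lag tau on channel i.
    B_ : ndarray, shape (d_y, d_x, n_b)
        Feed-forward input filters at lags 0..n_b-1.
    sigma2_ : ndarray, shape (d_y,)
        Innovation power (mean squared residual) per channel.
    residuals_ : ndarray, shape (d_y, T_eff)
        Estimated innovation process ``e(t)``.
    T_eff_ : int
        Number of fitted samples after dropping incomplete history.

    Notes
    -----
    Per-channel means of ``y`` and ``x`` are subtracted before fitting in
    place of an explicit intercept.  The standardized Gram matrix and
    cross-products are retained on the fitted object so Granger
    reduced models can be solved by block elimination without refitting.
    """

    def __init__(self, n_a: int = 6, n_b: int = 36, lambda_reg: float = 0.3, fs: float = 1.0):
        self.n_a = n_a
        self.n_b = n_b
        self.lambda_reg = lambda_reg
        self.fs = fs

    # -- fitting -----------------------------------------------------------

    def fit(self, y, x=None) -> "VARX":
        y = _coerce_y(y, self.fs)
        y.require_nondegenerate()
        x = _coerce_x(x, y.n_samples, y.fs)
        lags = LagSpec(self.n_a, self.n_b, self.lambda_reg)

        y_centered = NeuralTimeSeries(
            data=y.data - y.data.mean(axis=1, keepdims=True),
            fs=y.fs,
            channel_labels=list(y.channel_labels),
            condition_label=y.condition_label,
        )
        x_centered = StimulusFeatureSet(
            data=(x.data - x.data.mean(axis=1, keepdims=True)) if x.n_features else x.data,
            fs=x.fs,
            feature_labels=list(x.feature_labels),
            # centering breaks the nonnegativity of pulse trains by design
            feature_kinds=["continuous"] * x.n_features,
        )
        D, Y = build_lagged_design(y_centered, x_centered, lags, fs=y.fs)
        T_eff, p = D.shape
        if p == 0:
            raise ValueError("model has no predictors (n_a=0 and no features)")

        scale = np.sqrt(np.mean(D**2, axis=0))
        zero_cols = scale == 0.0
        scale = np.where(zero_cols, 1.0, scale)

        G = D.T @ D
        C = D.T @ Y
        G_std = G / np.outer(scale, scale)
        C_std = C / scale[:, np.newaxis]
        if np.any(zero_cols):
            # all-zero predictors (e.g. a silent feature) carry no information;
            # give them a unit diagonal so the solve stays well posed and
            # their coefficients are pinned to zero below
            idx = np.flatnonzero(zero_cols)
            G_std[idx, idx] = 1.0
        yty = np.sum(Y**2, axis=0)

        lam = self.lambda_reg * T_eff
        w_std = _ridge_solve(G_std, C_std, lam, zero_cols)
        W = w_std / scale[:, np.newaxis]  # coefficients on original units

        resid = (Y - D @ W).T
        sigma2 = np.mean(resid**2, axis=1)

        blocks = design_column_blocks(y.n_channels, x.n_features, lags)
        n_a, n_b = lags.n_a, lags.n_b
        A = np.zeros((y.n_channels, y.n_channels, n_a))
        B = np.zeros((y.n_channels, x.n_features, n_b))
        for kind, j, sl in blocks:
            if kind == "y":
                A[:, j, :] = W[sl, :].T
            else:
                B[:, j, :] = W[sl, :].T

        self.A_ = A
        self.B_ = B
        self.sigma2_ = sigma2
        self.residuals_ = resid
        self.T_eff_ = T_eff
        self.lag_spec_ = lags
        self.fs_ = y.fs
        self.channel_labels_ = list(y.channel_labels)
        self.feature_labels_ = list(x.feature_labels)
        # retained for Granger block elimination
        self._gram_std = G_std
        self._xty_std = C_std
        self._yty = yty
        self._col_scale = scale
        self._col_blocks = blocks
        return self

    # -- derived quantities ------------------------------------------------

    def to_fit(self) -> VARXModelFit:
        """Export the fitted parameters as a plain :class:`VARXModelFit`."""
        self._check_fitted()
        return VARXModelFit(
            A=self.A_.copy(),
            B=self.B_.copy(),
            sigma2_full=self.sigma2_.copy(),
            residuals=self.residuals_.copy(),
            lag_spec=self.lag_spec_,
            T_eff=self.T_eff_,
            fs=self.fs_,
            channel_labels=list(self.channel_labels_),
            feature_labels=list(self.feature_labels_),
        )

    def predict(self, y, x=None) -> np.ndarray:
        """One-step-ahead prediction of ``y(t)`` from observed history.

        Returns the predicted signal over the ``T_eff`` aligned samples,
        shape ``(d_y, T_eff)``.
        """
        self._check_fitted()
        y = _coerce_y(y, self.fs_)
        x = _coerce_x(x, y.n_samples, y.fs)
        yc = y.data - y.data.mean(axis=1, keepdims=True)
        xc = x.data - x.data.mean(axis=1, keepdims=True) if x.n_features else x.data
        D, _ = build_lagged_design(
            NeuralTimeSeries(yc, y.fs),
            StimulusFeatureSet(xc, x.fs),
            self.lag_spec_,
        )
        W = self._coef_matrix()
        return (D @ W).T + y.data.mean(axis=1, keepdims=True)

    def score(self, y, x=None) -> float:
        """Mean per-channel prediction R^2 (one step ahead)."""
        y = _coerce_y(y, self.fs if not hasattr(self, "fs_") else self.fs_)
        pred = self.predict(y, x)
        obs = y.data[:, y.n_samples - pred.shape[1] :]
        ss_res = np.sum((obs - pred) ** 2, axis=1)
        ss_tot = np.sum((obs - obs.mean(axis=1, keepdims=True)) ** 2, axis=1)
        return float(np.mean(1.0 - ss_res / ss_tot))

    def _coef_matrix(self) -> np.ndarray:
        """Stacked coefficients, shape (n_cols, d_y), matching design columns."""
        n_cols = self._gram_std.shape[0]
        W = np.empty((n_cols, self.A_.shape[0]))
        for kind, j, sl in self._col_blocks:
            W[sl, :] = (self.A_[:, j, :] if kind == "y" else self.B_[:, j, :]).T
        return W

    def _check_fitted(self) -> None:
        if not hasattr(self, "A_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


def _ridge_solve(G_std, C_std, lam, zero_cols) -> np.ndarray:
    """Solve the (standardized) normal equations with ridge weight ``lam``."""
    p = G_std.shape[0]
    lhs = G_std + lam * np.eye(p)
    try:
        cho = scipy.linalg.cho_factor(lhs, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # scipy's LinAlgError subclasses numpy's
        raise SingularDesignError(
            "design matrix is rank deficient with lambda_reg=0; "
            "set lambda_reg > 0 to regularize"
        ) from exc
    w = scipy.linalg.cho_solve(cho, C_std, check_finite=False)
    if np.any(zero_cols):
        w[zero_cols, :] = 0.0
    return w


class TemporalResponseFunction(BaseEstimator):
    """Multivariate temporal response function (mTRF) encoding model.

    A moving-average-only model: each output channel is a ridge regression
    on the stimulus features at lags 0..L-1, with no recurrent terms.  This
    directly estimates the *total* stimulus response, which for data
    generated by a VARX process equals the factorized system response
    ``H = (1 - A)^{-1} B``.

    Attributes
    ----------
    kernels_ : ndarray, shape (d_y, d_x, L)
        Estimated response filters.
    """

    def __init__(self, L: int = 36, lambda_reg: float = 0.3, fs: float = 1.0):
        self.L = L
        self.lambda_reg = lambda_reg
        self.fs = fs

    def fit(self, y, x) -> "TemporalResponseFunction":
        inner = VARX(n_a=0, n_b=self.L, lambda_reg=self.lambda_reg, fs=self.fs)
        inner.fit(y, x)
        self.kernels_ = inner.B_.copy()
        self.sigma2_ = inner.sigma2_.copy()
        self.T_eff_ = inner.T_eff_
        self.fs_ = inner.fs_
        self._inner = inner
        return self

    def to_impulse_responses(self):
        from .response import ImpulseResponseSet

        return ImpulseResponseSet(kernels=self.kernels_.copy(), fs=self.fs_, kind="mTRF")


# ---------------------------------------------------------------------------
# Thin functional wrappers


def fit_varx(y, x=None, lags: LagSpec | None = None) -> VARX:
    """Fit a VARX model; see :class:`VARX`."""
    lags = lags or LagSpec()
    fs = y.fs if isinstance(y, NeuralTimeSeries) else 1.0
    return VARX(lags.n_a, lags.n_b, lags.lambda_reg, fs=fs).fit(y, x)


def fit_var_control(y, x, lags: LagSpec | None = None) -> VARX:
    """Fit the VAR control: a VARX with every feature circularly shuffled.

    The shuffle disrupts stimulus-to-signal alignment while keeping the
    parameter count and input covariance identical to the matched VARX fit,
    so differences between the two fits isolate the stimulus contribution.
    """
    x_shuf = shuffle_features(x) if x is not None and x.n_features else x
    return fit_varx(y, x_shuf, lags)


def fit_mtrf(y, x, L: int = 36, lambda_reg: float = 0.3):
    """Estimate the mTRF and return it as an ``ImpulseResponseSet``."""
    fs = y.fs if isinstance(y, NeuralTimeSeries) else 1.0
    est = TemporalResponseFunction(L=L, lambda_reg=lambda_reg, fs=fs).fit(y, x)
    return est.to_impulse_responses()
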