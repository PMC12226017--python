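"""Granger deviance statistics for recurrent connections and input effects.

For every (target channel i, source j) pair the full model's innovation
power ``sigma_f^2`` is compared with the reduced model that omits all of
source j's lagged predictors when predicting channel i:

    D_ij  = T_eff * log(sigma_r^2 / sigma_f^2)
    p_ij  = chi-square upper tail of D_ij with dof = omitted parameters
    R2_ij = 1 - exp(-D_ij / T_eff)

``D`` is the likelihood-ratio deviance of nested Gaussian regressions and
is asymptotically chi-square with as many degrees of freedom as parameters
removed (``n_a`` per recurrent source, ``n_b`` per input feature); the
generalized ``R^2`` serves as per-connection effect size.  Reduced models
reuse the full fit's Gram matrix (same ridge weight and scaling), so the
deviance reflects only the omitted predictors and the block-elimination
solution agrees with naive refitting to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LagSpec
from .estimators import VARX, fit_varx

__all__ = ["GrangerMap", "granger_map", "granger_map_from_model", "significance_mask"]


@dataclass
class GrangerMap:
    """Deviance, p-value and generalized R^2 matrices for one effect kind.

    Rows index the target (incoming) channel; columns index the source:
    another channel for ``kind="recurrent"`` (shape d_y x d_y) or an input
    feature for ``kind="input"`` (shape d_y x d_x).
    """

    D: np.ndarray
    p: np.ndarray
    R2: np.ndarray
    kind: str
    T_eff: int
    dof: int
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    @property
    def shape(self):
        return self.D.shape

    def off_diagonal(self, matrix: np.ndarray | None = None) -> np.ndarray:
        """Off-diagonal entries (recurrent maps) or all entries (input maps)."""
        m = self.R2 if matrix is None else matrix
        if self.kind != "recurrent":
            return m.ravel()
        mask = ~np.eye(m.shape[0], dtype=bool)
        return m[mask]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: target, source, D, p, R2."""
        n_i, n_j = self.D.shape
        rows = self.row_labels or [f"ch{i}" for i in range(n_i)]
        cols = self.col_labels or [f"s{j}" for j in range(n_j)]
        ii, jj = np.meshgrid(range(n_i), range(n_j), indexing="ij")
        return pd.DataFrame(
            {
                "target": [rows[i] for i in ii.ravel()],
                "source": [cols[j] for j in jj.ravel()],
                "D": self.D.ravel(),
                "p": self.p.ravel(),
                "R2": self.R2.ravel(),
            }
        )

    def save_h5(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as f:
            f.create_dataset("D", data=self.D)
            f.create_dataset("p", data=self.p)
            f.create_dataset("R2", data=self.R2)
            f.attrs["kind"] = self.kind
            f.attrs["T_eff"] = self.T_eff
            f.attrs["dof"] = self.dof
            f.attrs["row_labels"] = json.dumps(self.row_labels)
            f.attrs["col_labels"] = json.dumps(self.col_labels)


def granger_map_from_model(model: VARX, which: str = "recurrent") -> GrangerMap:
    """Granger statistics from a fitted :class:`~varxnet.estimators.VARX`.

    Uses the Gram matrix retained by the fit; each source's reduced models
    (one per target channel) come from a single block-eliminated solve.
    """
    model._check_fitted()
    if which not in ("recurrent", "input"):
        raise ValueError("which must be 'recurrent' or 'input'")
    d_y = model.A_.shape[0]
    d_x = model.B_.shape[1]
    T_eff = model.T_eff_
    lags = model.lag_spec_
    lam = model.lambda_reg * T_eff

    if which == "recurrent":
        sources = [(k, j, sl) for (k, j, sl) in model._col_blocks if k == "y"]
        n_src, dof = d_y, lags.n_a
        col_labels = list(model.channel_labels_)
    else:
        sources = [(k, j, sl) for (k, j, sl) in model._col_blocks if k == "x"]
        n_src, dof = d_x, lags.n_b
        col_labels = list(model.feature_labels_)
    if which == "recurrent" and lags.n_a == 0:
        raise ValueError("no recurrent lags in the model (n_a=0)")
    if which == "input" and d_x == 0:
        empty = np.zeros((d_y, 0))
        return GrangerMap(empty, empty.copy(), empty.copy(), which, T_eff, dof,
                          list(model.channel_labels_), [])

    G = model._gram_std
    C = model._xty_std
    yty = model._yty
    sigma_f2 = model.sigma2_
    n_cols = G.shape[0]

    D = np.zeros((d_y, n_src))
    for _, j, sl in sources:
        keep = np.ones(n_cols, dtype=bool)
        keep[sl] = False
        G_r = G[np.ix_(keep, keep)]
        C_r = C[keep, :]
        lhs = G_r + lam * np.eye(G_r.shape[0])
        cho = scipy.linalg.cho_factor(lhs, lower=True, check_finite=False)
        W_r = scipy.linalg.cho_solve(cho, C_r, check_finite=False)
        rss_r = yty - 2.0 * np.einsum("pi,pi->i", W_r, C_r) + np.einsum(
            "pi,pq,qi->i", W_r, G_r, W_r
        )
        sigma_r2 = rss_r / T_eff
        Dj = T_eff * np.log(sigma_r2 / sigma_f2)
        # nested OLS guarantees D >= 0; ridge can leave tiny negatives
        if model.lambda_reg == 0:
            assert np.all(Dj >= -1e-8 * T_eff), "nested-model deviance went negative"
        else:
            assert np.all(Dj >= -1e-6 * T_eff)
        D[:, j] = np.clip(Dj, 0.0, None)

    p = stats.chi2.sf(D, dof)
    R2 = 1.0 - np.exp(-D / T_eff)
    return GrangerMap(
        D=D,
        p=p,
        R2=R2,
        kind=which,
        T_eff=T_eff,
        dof=dof,
        row_labels=list(model.channel_labels_),
        col_labels=col_labels,
    )


def granger_map(y, x=None, lags: LagSpec | None = None, which: str = "recurrent") -> GrangerMap:
    """Fit a VARX model and compute Granger statistics in one call."""
    model = fit_varx(y, x, lags or LagSpec())
    return granger_map_from_model(model, which)


def significance_mask(
    gmap: GrangerMap, alpha: float = 0.0001, correction: str = "none"
) -> tuple[np.ndarray, float]:
    """Threshold a Granger map, optionally with multiplicity correction.

    Parameters
    ----------
    gmap : GrangerMap
    alpha : float
        Significance level in (0, 1).
    correction : {"none", "bonferroni", "fdr_bh"}
        Family-wise (Bonferroni) or Benjamini-Hochberg false-discovery-rate
        correction over the tested entries (off-diagonal for recurrent
        maps, all entries for input maps).

    Returns
    -------
    mask : boolean ndarray, same shape as the map
        Survivors of the threshold.  Diagonal entries of recurrent maps
        are always False (self-connections are excluded from summaries).
    fraction : float
        Fraction of tested entries that are significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if correction not in ("none", "bonferroni", "fdr_bh"):
        raise ValueError(f"unknown correction {correction!r}")
    p = gmap.p
    mask = np.zeros_like(p, dtype=bool)
    if p.size == 0:
        return mask, float("nan")
    if gmap.kind == "recurrent":
        tested = ~np.eye(p.shape[0], dtype=bool)
    else:
        tested = np.ones_like(p, dtype=bool)
    pvec = p[tested]
    if correction == "none":
        sig = pvec < alpha
    else:
        sig = multipletests(pvec, alpha=alpha, method=correction)[0]
    mask[tested] = sig
    fraction = float(np.mean(sig)) if pvec.size else float("nan")
    return mask, fraction
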