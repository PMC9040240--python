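"""Integration-effect scoring of multi-indicator pharmacodynamic panels.

A panel of per-animal indicators for one efficacy is reduced to a single
composite "integration effect" per animal: indicators are standardized,
factors are extracted by the principal-component method (retain eigenvalues
of the correlation matrix above a threshold), factor scores are computed
from the scoring-coefficient matrix, and the composite is the variance-
proportion-weighted sum of the retained factor scores (proportions
renormalized over the retained factors).

Sampling-adequacy (KMO) and sphericity (Bartlett) diagnostics are reported
with every fit.  Composites are oriented so that higher = healthier
according to the panel's indicator directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateDataError, InsufficientDataError
from .simulate import IndexPanel

__all__ = [
    "EIGEN_THRESHOLDS",
    "FactorScorer",
    "fit_factor_model",
    "composite_scores",
    "ks_normality",
    "group_stats",
    "IntegratedEffect",
]

#: conventional per-efficacy eigenvalue retention thresholds
EIGEN_THRESHOLDS = {"E1": 0.8, "E2": 0.7, "E3": 0.7, "E4": 0.65, "E5": 0.65}


def _kmo(corr: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy from a correlation matrix."""
    inv = np.linalg.pinv(corr)
    d = np.sqrt(np.abs(np.diag(inv)))
    partial = -inv / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    r2 = corr.copy()
    np.fill_diagonal(r2, 0.0)
    num = np.sum(r2 ** 2)
    den = num + np.sum(partial ** 2)
    return float(num / den) if den > 0 else np.nan


def _bartlett(corr: np.ndarray, n: int) -> tuple[float, float]:
    """Bartlett's test of sphericity: chi2 statistic and p-value."""
    p = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        return np.inf, 0.0
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


def _varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (kaiser-normalized not applied)."""
    p, k = loadings.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / p))
        R = u @ vt
        new_var = float(np.sum(s))
        if new_var <= var * (1 + tol):
            break
        var = new_var
    return loadings @ R


class FactorScorer(TransformerMixin, BaseEstimator):
    """Principal-component factor extraction with composite scoring.

    Parameters
    ----------
    eigen_threshold : retain factors whose correlation-matrix eigenvalue
        exceeds this value.  Typical per-efficacy values are given in
        :data:`EIGEN_THRESHOLDS`.
    rotation : ``None`` (default) or ``"varimax"``.  No rotation is applied
        by default because scoring coefficients and variance proportions are
        defined on the initial (unrotated) extraction.
    min_avg_abs_corr : optional indicator screen — drop indicators whose
        mean absolute correlation with the others falls below this value
        (off by default).

    Attributes (after ``fit``)
    --------------------------
    loadings_ : (p, k) factor loadings.
    scoring_coefficients_ : (p, k) regression scoring coefficients; factor
        scores are ``Z @ scoring_coefficients_`` on standardized data.
    eigenvalues_ : retained eigenvalues, descending.
    variance_props_ : per-retained-factor proportion of total variance.
    kmo_, bartlett_chi2_, bartlett_p_ : adequacy diagnostics.
    """

    def __init__(self, eigen_threshold: float = 1.0, rotation: str | None = None,
                 min_avg_abs_corr: float | None = None, directions=None):
        self.eigen_threshold = eigen_threshold
        self.rotation = rotation
        self.min_avg_abs_corr = min_avg_abs_corr
        self.directions = directions

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
            raise ValueError("need >= 3 observations of >= 2 indicators")
        if self.eigen_threshold <= 0:
            raise ValueError("eigen_threshold must be positive")
        p = X.shape[1]
        keep = np.arange(p)

        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateDataError(
                f"constant indicators at columns {np.flatnonzero(sd == 0).tolist()}")
        corr = np.corrcoef(X, rowvar=False)

        if self.min_avg_abs_corr is not None:
            offdiag = np.abs(corr) - np.eye(p)
            avg = offdiag.sum(axis=1) / (p - 1)
            keep = np.flatnonzero(avg >= self.min_avg_abs_corr)
            if keep.size < 2:
                raise DegenerateDataError("indicator screen removed too many indicators")
            X = X[:, keep]
            corr = np.corrcoef(X, rowvar=False)
            sd = sd[keep]

        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
        retained = evals > self.eigen_threshold
        k = int(retained.sum())
        if k == 0:
            raise DegenerateDataError(
                f"no eigenvalue above threshold {self.eigen_threshold} "
                f"(largest is {evals[0]:.4f})")

        lam = evals[:k]
        V = evecs[:, :k]
        loadings = V * np.sqrt(lam)
        # orient each factor along the healthier direction of its indicators
        direction = (np.ones(X.shape[1]) if self.directions is None
                     else np.asarray(self.directions, dtype=float)[keep])
        flip = np.where(loadings.T @ direction < 0, -1.0, 1.0)
        loadings = loadings * flip
        if self.rotation == "varimax" and k > 1:
            loadings = _varimax(loadings)
            lam = np.sum(loadings ** 2, axis=0)
            order2 = np.argsort(lam)[::-1]
            lam, loadings = lam[order2], loadings[:, order2]
        elif self.rotation not in (None, "varimax"):
            raise ValueError(f"unknown rotation {self.rotation!r}")

        self.kept_indicators_ = keep
        self.mean_ = np.asarray(X, dtype=float).mean(axis=0)
        self.std_ = sd
        self.eigenvalues_ = lam
        self.loadings_ = loadings
        self.scoring_coefficients_ = loadings / lam  # = V/sqrt(lam) unrotated
        self.variance_props_ = lam / corr.shape[0]
        self.cumulative_variance_ = float(self.variance_props_.sum())
        self.kmo_ = _kmo(corr)
        self.bartlett_chi2_, self.bartlett_p_ = _bartlett(corr, X.shape[0])
        self.n_features_in_ = p
        self.n_factors_ = k
        return self

    def transform(self, X) -> np.ndarray:
        """Factor scores of new observations (standardized by the fit)."""
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] == self.n_features_in_:
            X = X[:, self.kept_indicators_]
        elif X.shape[1] != len(self.kept_indicators_):
            raise ValueError("indicator count mismatch with the fitted model")
        Z = (X - self.mean_) / self.std_
        return Z @ self.scoring_coefficients_

    def composite(self, X) -> np.ndarray:
        """Variance-weighted composite score per observation.

        Weights are the retained factors' variance proportions renormalized
        to sum to one, so a single-factor model returns that factor's score
        unchanged.
        """
        scores = self.transform(X)
        w = self.variance_props_ / self.variance_props_.sum()
        return scores @ w


def fit_factor_model(panel: IndexPanel, eigen_threshold: float | None = None,
                     **kwargs) -> FactorScorer:
    """Fit a :class:`FactorScorer` on a panel, defaulting the threshold to
    the panel's per-efficacy convention."""
    if eigen_threshold is None:
        eigen_threshold = EIGEN_THRESHOLDS.get(panel.effect_label, 1.0)
    scorer = FactorScorer(eigen_threshold=eigen_threshold,
                          directions=panel.indicator_directions, **kwargs)
    return scorer.fit(panel.values.to_numpy(dtype=float))


def composite_scores(model: FactorScorer, panel: IndexPanel) -> pd.Series:
    """Per-animal composite integration-effect scores, oriented so that a
    higher score means a healthier animal under the panel's indicator
    directions."""
    X = panel.values.to_numpy(dtype=float)
    comp = model.composite(X)
    # orientation check against the direction-weighted mean indicator
    Z = (X[:, model.kept_indicators_] - model.mean_) / model.std_
    proxy = Z @ np.asarray(panel.indicator_directions, dtype=float)[model.kept_indicators_]
    if comp.std() > 0 and proxy.std() > 0 and np.corrcoef(comp, proxy)[0, 1] < 0:
        comp = -comp
    return pd.Series(comp, index=panel.values.index, name=f"{panel.effect_label}_composite")


def ks_normality(scores, group: str | None = None) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    own mean and SD.  Returns ``(statistic, p_value)``."""
    x = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 values for a normality test{f' (group {group})' if group else ''}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance: normality test undefined")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _sig(p: float) -> str:
    for cut, code in _TIERS:
        if p < cut:
            return code
    return "ns"


@dataclass
class IntegratedEffect:
    """Per-group integration-effect summary for one efficacy."""

    effect_label: str
    scores: pd.Series  # per animal
    table: pd.DataFrame  # group, n, mean, sd, p_vs_model, sig_vs_model, ...


def group_stats(scores, group_labels, control: str, model: str,
                effect_label: str = "E1") -> IntegratedEffect:
    """Group means +- SD with pairwise two-sided t-tests.

    Each treated group is compared against the model group; the model group
    itself is compared against the control.  Significance codes follow the
    0.05 / 0.01 / 0.001 convention.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    g = pd.Series(np.asarray(group_labels)).reset_index(drop=True)
    labels = list(dict.fromkeys(g))
    for lab in (control, model):
        if lab not in labels:
            raise ValueError(f"group label {lab!r} not present")
    model_vals = s[g == model].to_numpy()
    control_vals = s[g == control].to_numpy()
    rows = []
    for lab in labels:
        v = s[g == lab].to_numpy()
        row = {"group": lab, "n": v.size, "mean": float(v.mean()),
               "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
               "p_vs_model": np.nan, "sig_vs_model": "",
               "p_vs_control": np.nan, "sig_vs_control": ""}
        if lab == model:
            p = float(stats.ttest_ind(v, control_vals).pvalue)
            row.update(p_vs_control=p, sig_vs_control=_sig(p))
        elif lab != control:
            p = float(stats.ttest_ind(v, model_vals).pvalue)
            row.update(p_vs_model=p, sig_vs_model=_sig(p))
        rows.append(row)
    return IntegratedEffect(effect_label=effect_label, scores=s,
                            table=pd.DataFrame(rows))
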