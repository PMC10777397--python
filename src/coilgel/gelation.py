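"""Gelation-time regression and the extent-of-gelation phase plane.

Models
------
* ``TcRegression("univariate")`` — OLS of the critical gelation time t_c
  (hours) on ΔEE_bcf (kJ/mol).
* ``TcRegression("bivariate")`` — OLS of t_c on (NEE_bcf, CEE_bcf), with
  per-surface-residue normalized slopes (N slope / 5 residues, C slope /
  11 residues; units h·mol·kJ⁻¹·AA⁻¹).
* ``GelationPlane`` — linear probability model of the binary tube-inversion
  outcome on (temperature, concentration); the fitted plane is the extent
  of gelation η(T, c) and the UCST is the temperature solving η = 0.5 at
  the solubility-limit concentration.

All fits are ordinary least squares (deliberately not logistic for the
phase plane).  RMSE uses the 1/n convention (no degrees-of-freedom
correction); the residual sum of squares is exposed so either convention
can be recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

#: b/c/f surface-residue counts of the N (AA17-28) and C (AA29-54) windows
#: for the Q-family register; used to normalize bivariate slopes per residue.
DEFAULT_RESIDUE_COUNTS = (5, 11)

_CONDITION_LIMIT = 1e10


class CollinearityError(ValueError):
    """Design matrix is (near-)singular."""


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Plain least squares with intercept -> (slopes, intercept, r2, rmse)."""
    n = len(y)
    A = np.column_stack([X, np.ones(n)])
    if np.any(X.std(axis=0) == 0):
        raise CollinearityError("a predictor has zero variance")
    if np.linalg.cond(A) > _CONDITION_LIMIT:
        raise CollinearityError("predictors are collinear")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / n))
    return beta[:-1], float(beta[-1]), r2, rmse


class TcRegression(BaseEstimator, RegressorMixin):
    """OLS prediction of the critical gelation time t_c (hours).

    Parameters
    ----------
    mode : {"univariate", "bivariate"}
        Univariate regresses t_c on ΔEE_bcf; bivariate on (NEE, CEE).
    residue_counts : tuple of int
        Surface-residue counts used to normalize the bivariate slopes
        per amino acid (N window, C window).

    Fitted attributes: ``coef_`` (h·mol/kJ), ``intercept_`` (h), ``r2_``,
    ``rmse_`` (h, 1/n convention), ``n_obs_`` and, in bivariate mode,
    ``normalized_coef_`` (h·mol·kJ⁻¹·AA⁻¹ = coef_/residue_counts).
    """

    def __init__(self, mode: str = "univariate",
                 residue_counts: tuple[int, int] = DEFAULT_RESIDUE_COUNTS):
        self.mode = mode
        self.residue_counts = residue_counts

    def fit(self, X, y):
        if self.mode not in ("univariate", "bivariate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 2:
            X = X.T
        y = np.asarray(y, dtype=float)
        p = 1 if self.mode == "univariate" else 2
        if X.shape[1] != p:
            raise ValueError(f"{self.mode} mode expects {p} feature column(s)")
        min_obs = 3 if p == 1 else 4
        if len(y) < min_obs:
            raise ValueError(f"need at least {min_obs} observations")
        self.coef_, self.intercept_, self.r2_, self.rmse_ = _ols(X, y)
        self.n_obs_ = len(y)
        if self.mode == "bivariate":
            counts = np.asarray(self.residue_counts, dtype=float)
            self.normalized_coef_ = self.coef_ / counts
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coef_):
            raise ValueError(
                f"model expects {len(self.coef_)} feature(s), got {X.shape[1]}")
        pred = X @ self.coef_ + self.intercept_
        if np.any(pred < 0):
            warnings.warn("negative gelation-time prediction(s)",
                          RuntimeWarning, stacklevel=2)
        return pred


class GelationPlane(BaseEstimator):
    """Extent-of-gelation plane η(T, c) fitted to binary gel outcomes.

    η = intercept_ + temp_coef_·T + conc_coef_·c, fitted by OLS on
    outcomes in {0, 1} (linear probability model).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): temperature, concentration")
        classes = set(np.unique(y))
        if not classes <= {0.0, 1.0}:
            raise ValueError("outcomes must be binary 0/1")
        if len(classes) < 2:
            raise ValueError("both gel and no-gel outcomes are required")
        (self.temp_coef_, self.conc_coef_), self.intercept_, self.r2_, _ = \
            _ols(X, y)
        self.n_obs_ = len(y)
        return self

    def eta(self, temperature, concentration):
        return (self.intercept_ + self.temp_coef_ * np.asarray(temperature)
                + self.conc_coef_ * np.asarray(concentration))

    def ucst(self, solubility_limit: float) -> float:
        """Temperature (°C) where η = 0.5 at the solubility limit (mM)."""
        if self.temp_coef_ == 0:
            raise ZeroDivisionError(
                "temperature coefficient is zero: no UCST solution")
        return float((0.5 - self.intercept_
                      - self.conc_coef_ * solubility_limit) / self.temp_coef_)


# --------------------------------------------------------------------------
# thin functional wrappers over the estimators

def fit_tc_univariate(records: pd.DataFrame,
                      delta_col: str = "delta_ee_bcf",
                      tc_col: str = "t_c") -> TcRegression:
    model = TcRegression(mode="univariate")
    return model.fit(records[[delta_col]].to_numpy(), records[tc_col])


def fit_tc_bivariate(records: pd.DataFrame,
                     nee_col: str = "nee_bcf", cee_col: str = "cee_bcf",
                     tc_col: str = "t_c",
                     residue_counts: tuple[int, int] = DEFAULT_RESIDUE_COUNTS
                     ) -> TcRegression:
    model = TcRegression(mode="bivariate", residue_counts=residue_counts)
    return model.fit(records[[nee_col, cee_col]].to_numpy(), records[tc_col])


def predict_tc(model: TcRegression, *features: float) -> float:
    """Predict t_c (hours) from (ΔEE,) or (NEE, CEE) features."""
    return float(model.predict(np.array([features]))[0])


def fit_eta_plane(observations: pd.DataFrame,
                  temp_col: str = "temperature",
                  conc_col: str = "concentration",
                  outcome_col: str = "gel") -> GelationPlane:
    model = GelationPlane()
    return model.fit(observations[[temp_col, conc_col]].to_numpy(),
                     observations[outcome_col])


def solve_ucst(plane: GelationPlane, solubility_limit: float) -> float:
    return plane.ucst(solubility_limit)
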