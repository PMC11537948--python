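"""Penalized-likelihood fitting of age-varying LMS curves.

The model: a positive outcome y at age t follows BCCG(L(t), M(t), S(t)),
with each parameter curve a penalized B-spline (P-spline) on the age axis:

* L: identity link, so L(t) = B(t) @ c_L
* M, S: log link, guaranteeing positivity

Fitting maximizes the BCCG log-likelihood minus second-order difference
penalties on each coefficient vector, by Rigby-Stasinopoulos (RS) type
backfitting: the three curves are updated in turn by a penalized weighted
least-squares step built from the score and the expected (Fisher)
information of that parameter, iterated to convergence, with step-halving
whenever the penalized deviance would increase.  The per-observation
expected information terms (z ~ N(0,1) under the model, sigma small):

* eta_M = log M:  score z(1 + L*S*z)/S - L,  weight (1 + 2 L^2 S^2)/S^2
* eta_S = log S:  score z^2 - 1,             weight 2
* eta_L = L:      score -z dz/dL + log(y/M), weight 7 S^2 / 4

Smoothing parameters are either fixed or chosen per curve on a grid by
generalized cross-validation applied to that curve's working penalized
weighted-least-squares fit, GCV = n*D_w / (n - gamma*edf)^2, where D_w is
the weighted working-residual sum of squares (the working fit's deviance),
edf the curve's effective degrees of freedom, and gamma a mild inflation
(default 1.4) guarding against the occasional undersmoothing GCV is known
for.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.linalg import solve as dense_solve
from sklearn.base import BaseEstimator

__all__ = ["FitConfig", "ConvergenceError", "LMSRegressor", "fit_lms",
           "select_smoothing_gcv"]

_PARAMS = ("l", "m", "s")
# coefficient box bounds (B-spline convex hull => curve bounds)
_L_BOUNDS = (-4.0, 4.0)
_ETA_S_BOUNDS = (np.log(5e-4), np.log(3.0))


class ConvergenceError(RuntimeError):
    """Raised when backfitting does not reach tolerance; carries the last
    iterate in ``.estimator``."""

    def __init__(self, message, estimator=None):
        super().__init__(message)
        self.estimator = estimator


@dataclass
class FitConfig:
    """Configuration of the P-spline GAMLSS fit.

    Attributes
    ----------
    n_interior_knots : int
        Interior knots, equally spaced over the age range (default 20).
    degree : int
        B-spline degree (default 3, cubic).
    penalty_order : int
        Order of the difference penalty (default 2).
    lambda_l, lambda_m, lambda_s : float or None
        Fixed smoothing parameters; None selects by GCV on ``gcv_grid``.
    gcv_grid : array-like
        Candidate smoothing values (default 21 log-spaced in [1e-2, 1e6]).
    gcv_gamma : float
        Effective-degrees-of-freedom inflation in the GCV denominator
        (default 1.4, the standard guard against occasional GCV
        undersmoothing).
    tol : float
        Convergence tolerance on the relative change of the penalized
        deviance (default 1e-6; the shape curve L moves the deviance
        slowly, so a loose tolerance stops it short of its optimum).
    max_iter : int
        Maximum outer backfitting iterations (default 200).
    age_range : (float, float) or None
        Declared age range; default the observed data range.
    constant : tuple of str
        Parameter names (subset of 'l','m','s') fitted as age-constant.
    fix_l : float or None
        Freeze the L curve at this value (no L update).
    """

    n_interior_knots: int = 20
    degree: int = 3
    penalty_order: int = 2
    lambda_l: float | None = None
    lambda_m: float | None = None
    lambda_s: float | None = None
    gcv_grid: tuple = tuple(np.logspace(-2, 6, 21))
    gcv_gamma: float = 1.4
    tol: float = 1e-6
    max_iter: int = 200
    age_range: tuple | None = None
    constant: tuple = ()
    fix_l: float | None = None

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _knot_vector(lo: float, hi: float, n_interior: int, degree: int) -> np.ndarray:
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([np.repeat(lo, degree + 1), interior,
                           np.repeat(hi, degree + 1)])


def _difference_penalty(ncoef: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(ncoef), n=order, axis=0)
    return D.T @ D


class LMSRegressor(BaseEstimator):
    """Age-varying LMS (BCCG) curves by penalized P-spline likelihood.

    scikit-learn style: ``fit(X, y)`` with X the ages (n,) or (n, 1) and y
    the positive measurements.  ``predict`` returns the fitted median
    M(age); :meth:`predict_params`, :meth:`zscore` and :meth:`centiles`
    expose the full distributional fit.

    Fitted attributes
    -----------------
    knots_ : full B-spline knot vector
    coef_l_, coef_m_, coef_s_ : coefficient vectors (eta scale)
    lambda_ : dict of selected/fixed smoothing parameters
    edf_ : dict of effective degrees of freedom per curve
    deviance_ : global deviance (-2 log-likelihood)
    penalized_deviance_ : deviance plus difference penalties
    deviance_trace_ : penalized deviance after each outer iteration
    gcv_profile_ : dict param -> (grid, gcv values), when GCV ran
    n_iter_ : outer iterations used
    age_range_ : (min, max) ages the fit covers
    """

    def __init__(self, n_interior_knots=20, degree=3, penalty_order=2,
                 lambda_l=None, lambda_m=None, lambda_s=None,
                 gcv_grid=tuple(np.logspace(-2, 6, 21)), gcv_gamma=1.4,
                 tol=1e-6, max_iter=200, age_range=None, constant=(),
                 fix_l=None):
        self.n_interior_knots = n_interior_knots
        self.degree = degree
        self.penalty_order = penalty_order
        self.lambda_l = lambda_l
        self.lambda_m = lambda_m
        self.lambda_s = lambda_s
        self.gcv_grid = gcv_grid
        self.gcv_gamma = gcv_gamma
        self.tol = tol
        self.max_iter = max_iter
        self.age_range = age_range
        self.constant = constant
        self.fix_l = fix_l

    # ------------------------------------------------------------------ setup

    def _validate(self, X, y):
        X = np.asarray(X, float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be (n,) or (n, 1) ages")
        y = np.asarray(y, float)
        if y.shape != X.shape:
            raise ValueError("X and y lengths differ")
        if X.size < 50:
            raise ValueError("need at least 50 observations to fit LMS curves")
        if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
            raise ValueError("non-finite ages or measurements")
        if np.any(y <= 0):
            raise ValueError("measurements must be > 0")
        lo, hi = (self.age_range if self.age_range is not None
                  else (X.min(), X.max()))
        if np.any((X < lo) | (X > hi)):
            raise ValueError("ages outside the declared age_range")
        return X, y, float(lo), float(hi)

    def _basis(self, x: np.ndarray, param: str):
        if param in self.constant or (param == "l" and self.fix_l is not None):
            return sparse.csr_matrix(np.ones((x.size, 1)))
        x = np.clip(x, self.age_range_[0], self.age_range_[1])
        return BSpline.design_matrix(x, self.knots_, self.degree,
                                     extrapolate=False).tocsr()

    def _pmat(self, param: str) -> np.ndarray:
        if param in self.constant or (param == "l" and self.fix_l is not None):
            return np.zeros((1, 1))
        ncoef = self.n_interior_knots + self.degree + 1
        return _difference_penalty(ncoef, self.penalty_order)

    # ------------------------------------------------------ likelihood pieces

    @staticmethod
    def _theta(eta_l, eta_m, eta_s):
        L = eta_l
        M = np.exp(eta_m)
        S = np.exp(np.clip(eta_s, *_ETA_S_BOUNDS))
        return L, M, S

    @staticmethod
    def _zscore(y, L, M, S):
        ratio = y / M
        logr = np.log(ratio)
        nz = np.abs(L) > 1e-12
        Ls = np.where(nz, L, 1.0)
        z = np.where(nz, (np.exp(Ls * logr) - 1.0) / (Ls * S), logr / S)
        return np.clip(z, -38.0, 38.0)

    @staticmethod
    def _loglik(y, L, M, S):
        z = LMSRegressor._zscore(y, L, M, S)
        return np.sum((L - 1.0) * np.log(y) - L * np.log(M) - np.log(S)
                      - 0.5 * z * z - 0.5 * np.log(2.0 * np.pi))

    def _deviance(self, y, L, M, S) -> float:
        return -2.0 * self._loglik(y, L, M, S)

    def _penalty_term(self, coefs, lambdas) -> float:
        tot = 0.0
        for k in _PARAMS:
            P = self._pmat(k)
            tot += lambdas[k] * float(coefs[k] @ P @ coefs[k])
        return tot

    @staticmethod
    def _score_weight(param, y, L, M, S):
        """Per-observation score u and Fisher weight w on the eta scale."""
        z = LMSRegressor._zscore(y, L, M, S)
        if param == "m":
            u = z * (1.0 + L * S * z) / S - L
            w = (1.0 + 2.0 * L * L * S * S) / (S * S)
        elif param == "s":
            u = z * z - 1.0
            w = np.full_like(z, 2.0)
        else:  # "l"
            logr = np.log(y / M)
            small = np.abs(L) < 1e-5
            Ls = np.where(small, 1.0, L)
            dzdl = np.where(
                small,
                logr * logr / (2.0 * S),
                (logr * (1.0 + L * S * z)) / (Ls * S) - z / Ls,
            )
            u = -z * dzdl + logr
            w = 7.0 * S * S / 4.0
        return u, np.maximum(w, 1e-10)

    # -------------------------------------------------------------- fit core

    def fit(self, X, y):
        """Fit the three penalized curves; returns self."""
        X, y, lo, hi = self._validate(X, y)
        self.age_range_ = (lo, hi)
        self.knots_ = _knot_vector(lo, hi, self.n_interior_knots, self.degree)
        self._B = {k: self._basis(X, k) for k in _PARAMS}
        self._P = {k: self._pmat(k) for k in _PARAMS}
        self._x, self._y = X, y

        coefs = self._initial_coefs(X, y)
        fixed = {"l": self.lambda_l, "m": self.lambda_m, "s": self.lambda_s}
        lambdas = {k: (fixed[k] if fixed[k] is not None else 100.0)
                   for k in _PARAMS}

        if any(fixed[k] is None and not self._is_trivial(k) for k in _PARAMS):
            coefs, lambdas = self._select_gcv(y, coefs, lambdas, fixed)
        coefs, trace, niter, converged = self._backfit(
            y, coefs, lambdas, self.max_iter)

        self.coef_l_, self.coef_m_, self.coef_s_ = (coefs["l"], coefs["m"],
                                                    coefs["s"])
        self.lambda_ = dict(lambdas)
        self.deviance_trace_ = trace
        self.n_iter_ = niter
        L, M, S = self._curves(coefs)
        self.deviance_ = self._deviance(y, L, M, S)
        self.penalized_deviance_ = self.deviance_ + self._penalty_term(coefs, lambdas)
        self.edf_ = {k: self._edf(k, y, coefs, lambdas) for k in _PARAMS}
        del self._B
        if not converged:
            raise ConvergenceError(
                f"backfitting did not reach tol={self.tol} in "
                f"{self.max_iter} iterations", estimator=self)
        return self

    def _is_trivial(self, param):
        return param == "l" and self.fix_l is not None

    def _initial_coefs(self, X, y):
        """Robust deterministic start: binned running median / log-SD."""
        nbins = int(np.clip(X.size // 50, 4, 12))
        edges = np.quantile(X, np.linspace(0, 1, nbins + 1))
        edges[0] -= 1e-9
        centers, med, sdl = [], [], []
        for a, b in zip(edges[:-1], edges[1:]):
            m = (X > a) & (X <= b)
            if m.sum() < 5:
                continue
            centers.append(X[m].mean())
            med.append(np.median(y[m]))
            sdl.append(max(np.std(np.log(y[m])), 1e-3))
        centers, med, sdl = map(np.asarray, (centers, med, sdl))
        t = {
            "l": np.zeros_like(X) if self.fix_l is None
                 else np.full_like(X, self.fix_l),
            "m": np.interp(X, centers, np.log(med)),
            "s": np.interp(X, centers, np.log(sdl)),
        }
        coefs = {}
        for k in _PARAMS:
            B, P = self._B[k], self._P[k]
            A = (B.T @ B).toarray() + 1.0 * P + 1e-8 * np.eye(P.shape[0])
            coefs[k] = dense_solve(A, B.T @ t[k], assume_a="pos")
        return coefs

    def _curves(self, coefs):
        eta = {k: self._B[k] @ coefs[k] for k in _PARAMS}
        return self._theta(eta["l"], eta["m"], eta["s"])

    def _pwls_step(self, param, y, coefs, lam):
        L, M, S = self._curves(coefs)
        u, w = self._score_weight(param, y, L, M, S)
        B = self._B[param]
        eta = B @ coefs[param]
        zwork = eta + u / w
        BtW = B.multiply(w[:, None]).T
        A = (BtW @ B).toarray() + lam * self._P[param]
        A[np.diag_indices_from(A)] += 1e-9
        c = dense_solve(A, BtW @ zwork, assume_a="pos")
        if param == "l":
            c = np.clip(c, *_L_BOUNDS)
        elif param == "s":
            c = np.clip(c, *_ETA_S_BOUNDS)
        return c

    def _backfit(self, y, coefs, lambdas, max_iter):
        coefs = {k: v.copy() for k, v in coefs.items()}
        L, M, S = self._curves(coefs)
        pdev = self._deviance(y, L, M, S) + self._penalty_term(coefs, lambdas)
        trace = [pdev]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            for param in ("m", "s", "l"):
                if param == "l" and self.fix_l is not None:
                    continue
                cnew = self._pwls_step(param, y, coefs, lambdas[param])
                cold = coefs[param]
                step = 1.0
                for _ in range(20):
                    coefs[param] = cold + step * (cnew - cold)
                    L, M, S = self._curves(coefs)
                    cand = (self._deviance(y, L, M, S)
                            + self._penalty_term(coefs, lambdas))
                    if np.isfinite(cand) and cand <= pdev + 1e-10:
                        pdev = cand
                        break
                    step *= 0.5
                else:
                    coefs[param] = cold  # no improving step: keep old curve
            trace.append(pdev)
            rel = abs(trace[-2] - trace[-1]) / (abs(trace[-2]) + 1e-12)
            if rel < self.tol:
                converged = True
                break
        return coefs, np.asarray(trace), it, converged

    def _edf(self, param, y, coefs, lambdas) -> float:
        if param == "l" and self.fix_l is not None:
            return 0.0
        L, M, S = self._curves(coefs)
        _, w = self._score_weight(param, y, L, M, S)
        B = self._B[param]
        BtWB = (B.multiply(w[:, None]).T @ B).toarray()
        A = BtWB + lambdas[param] * self._P[param]
        A[np.diag_indices_from(A)] += 1e-9
        return float(np.trace(dense_solve(A, BtWB)))

    # --------------------------------------------------------- GCV selection

    def _select_gcv(self, y, coefs, lambdas, fixed):
        """One outer pass over the curves; per curve, pick the grid value
        minimizing GCV = n*D/(n-edf)^2 where D is the deviance of the
        working (penalized weighted least-squares) fit — the standard
        performance-iteration criterion for penalized-likelihood smoothers.

        After each curve's selection the model is refitted so the next
        curve's working quantities reflect the choice."""
        n = y.size
        grid = np.sort(np.asarray(self.gcv_grid, float))
        self.gcv_profile_ = {}
        for param in ("m", "s", "l"):
            if fixed[param] is not None or self._is_trivial(param):
                continue
            # stabilize the working quantities under the current lambdas
            coefs, _, _, _ = self._backfit(y, coefs, lambdas, self.max_iter)
            L, M, S = self._curves(coefs)
            u, w = self._score_weight(param, y, L, M, S)
            B = self._B[param]
            eta = B @ coefs[param]
            zwork = eta + u / w
            BtW = B.multiply(w[:, None]).T
            BtWB = (BtW @ B).toarray()
            BtWz = BtW @ zwork
            P = self._P[param]
            scores = np.empty(grid.size)
            for j, lam in enumerate(grid):
                A = BtWB + lam * P
                A[np.diag_indices_from(A)] += 1e-9
                c = dense_solve(A, BtWz, assume_a="pos")
                fitted = B @ c
                rss = float(w @ (zwork - fitted) ** 2)
                edf = float(np.trace(dense_solve(A, BtWB)))
                scores[j] = n * rss / (n - self.gcv_gamma * edf) ** 2
            j = int(np.argmin(scores))
            if j in (0, grid.size - 1):
                warnings.warn(
                    f"GCV minimum for {param!r} at grid boundary "
                    f"(lambda={grid[j]:g}); consider widening gcv_grid",
                    stacklevel=2)
            lambdas[param] = float(grid[j])
            self.gcv_profile_[param] = (grid.copy(), scores)
        coefs, _, _, _ = self._backfit(y, coefs, lambdas, self.max_iter)
        return coefs, lambdas

    # ------------------------------------------------------------ evaluation

    def _check_ages(self, X):
        X = np.asarray(X, float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        lo, hi = self.age_range_
        if np.any((X < lo - 1e-9) | (X > hi + 1e-9)):
            raise ValueError(
                f"age outside the fitted range [{lo:g}, {hi:g}]: "
                "no extrapolation")
        return X

    def predict_params(self, X):
        """(L, M, S) arrays at the requested ages (refuses extrapolation)."""
        X = self._check_ages(X)
        eta = {}
        for k, coef in (("l", self.coef_l_), ("m", self.coef_m_),
                        ("s", self.coef_s_)):
            B = self._basis(X, k)
            eta[k] = B @ coef
        return self._theta(eta["l"], eta["m"], eta["s"])

    def predict(self, X):
        """Fitted median M(age)."""
        return self.predict_params(X)[1]

    def zscore(self, X, y):
        """LMS z-scores of measurements y at ages X under the fitted curves."""
        from . import bccg
        L, M, S = self.predict_params(X)
        return bccg.z_from_value(np.asarray(y, float), (L, M, S))

    def centiles(self, X, levels=(1, 3, 5, 15, 25, 50, 75, 85, 95, 97, 99)):
        """Centile matrix (len(X) x len(levels)) from the fitted curves."""
        from scipy import stats
        from . import bccg
        L, M, S = self.predict_params(X)
        out = np.empty((np.size(X), len(levels)))
        for j, p in enumerate(levels):
            z = stats.norm.ppf(p / 100.0)
            out[:, j] = bccg.value_from_z(z, (L, M, S))
        return out

    # --------------------------------------------------------- serialization

    def to_dict(self, **meta) -> dict:
        """JSON-ready description of the fitted curves."""
        return {
            "meta": meta,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "age_range": list(self.age_range_),
            "knots": self.knots_.tolist(),
            "degree": self.degree,
            "links": {"l": "identity", "m": "log", "s": "log"},
            "coef": {"l": self.coef_l_.tolist(), "m": self.coef_m_.tolist(),
                     "s": self.coef_s_.tolist()},
            "lambda": self.lambda_,
            "edf": self.edf_,
            "deviance": self.deviance_,
            "penalized_deviance": self.penalized_deviance_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMSRegressor":
        cfg = dict(d["config"])
        for key in ("gcv_grid", "constant", "age_range"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
        est = cls(**cfg)
        est.age_range_ = tuple(d["age_range"])
        est.knots_ = np.asarray(d["knots"])
        est.coef_l_ = np.asarray(d["coef"]["l"])
        est.coef_m_ = np.asarray(d["coef"]["m"])
        est.coef_s_ = np.asarray(d["coef"]["s"])
        est.lambda_ = d["lambda"]
        est.edf_ = d["edf"]
        est.deviance_ = d["deviance"]
        est.penalized_deviance_ = d["penalized_deviance"]
        return est

    def save(self, path, **meta):
        with open(path, "w") as fh:
            json.dump(self.to_dict(**meta), fh, indent=1)

    @classmethod
    def load(cls, path) -> "LMSRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_lms(age, y, config: FitConfig | None = None) -> LMSRegressor:
    """Fit LMS curves to (age, y) data; thin wrapper over LMSRegressor."""
    config = config or FitConfig()
    est = LMSRegressor(**{f: getattr(config, f)
                          for f in FitConfig.__dataclass_fields__})
    return est.fit(np.asarray(age, float), np.asarray(y, float))


def select_smoothing_gcv(age, y, config: FitConfig | None = None):
    """GCV-selected smoothing parameters and profiles for each curve.

    Returns ``(lambdas, profiles)`` where profiles maps parameter name to
    ``(grid, gcv_scores)``.
    """
    config = config or FitConfig()
    est = fit_lms(age, y, config)
    return dict(est.lambda_), dict(getattr(est, "gcv_profile_", {}))
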