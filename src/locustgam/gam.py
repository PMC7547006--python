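"""Negative-binomial square-root-link GAM with penalized regression splines.

The linear predictor is additive on the square-root scale,

    sqrt(mu) = eta = b0 + sum_s f_s(x_s) + T(lon, lat, doy),

with univariate cubic-spline smooths f_s, a three-way tensor-product smooth
T over longitude, latitude and (cyclic) day-of-year, and a negative binomial
quasi-likelihood with dispersion theta.  The response is treated as a
non-negative continuous quantity: the NB deviance and log-likelihood are
evaluated at non-integer y, which reproduces the unusual but deliberate
pairing of a count family with a sixth-root-transformed density response.

Fitting is penalized IRLS with step-halving on the penalized deviance;
smoothing parameters are chosen by coordinate-wise search of the GCV score
of the working linear model (coarse log-grid scan plus golden-section
refinement, a configurable number of sweeps); theta is estimated by an outer
profile-likelihood step.  The coefficient covariance is the Bayesian
posterior covariance (penalized information inverse), as is standard for
penalized spline models.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._bases import (
    DOY_PERIOD,
    cubic_design,
    cubic_knots,
    cubic_penalty,
    cyclic_design,
    cyclic_penalty,
    doy_phase,
    row_kron,
    sum_to_zero,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothSpec",
    "ResponseCurve",
    "NegativeBinomialGAM",
    "nb_deviance",
    "nb_loglik",
    "build_basis",
    "fit_gam",
    "predict",
    "response_curves",
    "tensor_slices",
    "default_specs",
]


@dataclass(frozen=True)
class SmoothSpec:
    """One model term.

    basis: 'cubic_spline' (univariate), 'cyclic_spline' (day-of-year only),
    'tensor3' (lon x lat x doy, cyclic doy margin) or 'linear' (a single
    unpenalized centred column -- the GLM limit of a smooth).
    k: basis dimension (per margin for tensor3; defaults 10 and (8, 8, 6)).
    """

    covariates: tuple[str, ...]
    basis: str = "cubic_spline"
    k: tuple[int, ...] | int | None = None
    penalty_order: int = 2

    def __post_init__(self) -> None:
        covs = (self.covariates,) if isinstance(self.covariates, str) else tuple(
            self.covariates
        )
        object.__setattr__(self, "covariates", covs)
        if self.basis not in ("cubic_spline", "cyclic_spline", "tensor3", "linear"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.basis == "tensor3":
            if len(covs) != 3:
                raise ValueError("tensor3 needs exactly 3 covariates (lon, lat, doy)")
            k = self.k if self.k is not None else (8, 8, 6)
            k = tuple(int(v) for v in k)
        elif self.basis == "linear":
            if len(covs) != 1:
                raise ValueError("linear terms are univariate")
            k = (1,)
        else:
            if len(covs) != 1:
                raise ValueError("spline smooths are univariate")
            if self.basis == "cyclic_spline" and covs[0] != "doy":
                raise ValueError("cyclic basis is reserved for day-of-year")
            k = (int(self.k) if self.k is not None else 10,)
        if self.basis in ("cubic_spline", "cyclic_spline", "tensor3") and any(
            v < 4 for v in k
        ):
            raise ValueError("basis dimension must be >= 4 per margin")
        if self.penalty_order != 2:
            raise ValueError("only second-order (curvature) penalties are supported")
        object.__setattr__(self, "k", k)

    @property
    def name(self) -> str:
        if self.basis == "tensor3":
            return "te(" + ",".join(self.covariates) + ")"
        return f"s({self.covariates[0]})"


@dataclass
class ResponseCurve:
    """A univariate smooth's contribution to the link-scale fit."""

    covariate: str
    grid: np.ndarray
    fit: np.ndarray
    se: np.ndarray
    snr_mask: np.ndarray  # True where se < |fit| / 2 (signal-to-noise >= 2)

    @property
    def band(self) -> tuple[np.ndarray, np.ndarray]:
        return self.fit - 2 * self.se, self.fit + 2 * self.se

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.band
        return pd.DataFrame(
            {
                "x": self.grid,
                "fit": self.fit,
                "se": self.se,
                "lower2sd": lo,
                "upper2sd": hi,
                "snr_mask": self.snr_mask,
            }
        )


# ---------------------------------------------------------------------------
# family helpers (continuous-response NB quasi-likelihood)


def nb_deviance(y, mu, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    term2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(term1 - term2))


def nb_loglik(y, mu, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    ll = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# term construction


class _Term:
    """A built model term: constrained design block + penalties + metadata."""

    def __init__(self, spec: SmoothSpec, df: pd.DataFrame):
        self.spec = spec
        self.ranges = {}
        for c in spec.covariates:
            x = df[c].to_numpy(dtype=float)
            self.ranges[c] = (float(np.min(x)), float(np.max(x)))
        raw, penalties = self._raw_design(df, training=True)
        if spec.basis == "linear":
            self.Z = None
            self.design0 = raw
            self.penalties = []
        else:
            self.Z = sum_to_zero(raw)
            self.design0 = raw @ self.Z
            self.penalties = [self.Z.T @ S @ self.Z for S in penalties]
        self.width = self.design0.shape[1]

    def _marginal(self, cov: str, x: np.ndarray, k: int, cyclic: bool, training: bool):
        if cyclic:
            if training:
                self.__dict__.setdefault("_cyc_k", {})[cov] = k
            return cyclic_design(doy_phase(x), k), cyclic_penalty(k)
        lo, hi = self.ranges[cov]
        if training:
            if k >= len(np.unique(x)):
                raise ValueError(
                    f"basis dimension k={k} must be < number of distinct "
                    f"values of {cov} ({len(np.unique(x))})"
                )
            self.__dict__.setdefault("_knots", {})[cov] = cubic_knots(lo, hi, k)
        knots = self._knots[cov]
        return cubic_design(np.clip(x, lo, hi), knots), cubic_penalty(knots)

    def _raw_design(self, df: pd.DataFrame, training: bool):
        spec = self.spec
        if spec.basis == "linear":
            c = spec.covariates[0]
            x = df[c].to_numpy(dtype=float)
            if training:
                self.center = float(np.mean(x))
            return (x - self.center)[:, None], []
        if spec.basis == "tensor3":
            mats, pens = [], []
            for c, k in zip(spec.covariates, spec.k):
                cyc = c == "doy"
                B, S = self._marginal(c, df[c].to_numpy(dtype=float), k, cyc, training)
                mats.append(B)
                pens.append(S)
            X = row_kron(*mats)
            dims = [m.shape[1] for m in mats]
            eye = [np.eye(d) for d in dims]
            S1 = np.kron(pens[0], np.kron(eye[1], eye[2]))
            S2 = np.kron(eye[0], np.kron(pens[1], eye[2]))
            S3 = np.kron(eye[0], np.kron(eye[1], pens[2]))
            return X, [S1, S2, S3]
        c = spec.covariates[0]
        cyc = spec.basis == "cyclic_spline"
        B, S = self._marginal(c, df[c].to_numpy(dtype=float), spec.k[0], cyc, training)
        return B, [S]

    def design(self, df: pd.DataFrame) -> tuple[np.ndarray, int]:
        """Prediction design block; out-of-range values are clamped to the
        training range and counted."""
        n_clamped = 0
        clipped = df.copy()
        for c in self.spec.covariates:
            if c == "doy" and self.spec.basis in ("cyclic_spline", "tensor3"):
                continue  # cyclic margin wraps instead of clamping
            lo, hi = self.ranges[c]
            x = clipped[c].to_numpy(dtype=float)
            bad = (x < lo) | (x > hi)
            n_clamped += int(bad.sum())
            clipped[c] = np.clip(x, lo, hi)
        raw, _ = self._raw_design(clipped, training=False)
        block = raw if self.Z is None else raw @ self.Z
        return block, n_clamped


def build_basis(spec: SmoothSpec, x) -> tuple[np.ndarray, list[np.ndarray]]:
    """Build one term's constrained design block and penalty matrices from a
    covariate vector (or DataFrame for tensor terms)."""
    if isinstance(x, pd.DataFrame):
        df = x
    else:
        df = pd.DataFrame({spec.covariates[0]: np.asarray(x, dtype=float)})
    term = _Term(spec, df)
    return term.design0, term.penalties


def default_specs(covariates, tensor: bool = True, k: int = 10) -> list[SmoothSpec]:
    """Cubic smooths for each named covariate plus the space-time tensor."""
    specs = [SmoothSpec((c,), "cubic_spline", k) for c in covariates]
    if tensor:
        specs.append(SmoothSpec(("lon", "lat", "doy"), "tensor3"))
    return specs


# ---------------------------------------------------------------------------
# the estimator


class NegativeBinomialGAM(BaseEstimator):
    """Penalized-spline GAM, NB family, square-root link.

    Parameters
    ----------
    smooths : list of SmoothSpec
    theta : float or None
        NB dispersion; None (default) profiles it during fitting.
    select_lambda : bool
        If False, smoothing parameters stay at ``lambda_init``.
    lambda_init : float
        Starting value for every smoothing parameter.
    n_sweeps : int
        Outer GCV/theta sweeps.
    eta_floor : float
        Lower bound applied to the linear predictor during IRLS (the
        square-root link requires eta > 0).
    """

    def __init__(
        self,
        smooths,
        theta=None,
        select_lambda=True,
        lambda_init=1.0,
        n_sweeps=2,
        eta_floor=1e-3,
        max_iter=200,
        tol=1e-7,
    ):
        self.smooths = smooths
        self.theta = theta
        self.select_lambda = select_lambda
        self.lambda_init = lambda_init
        self.n_sweeps = n_sweeps
        self.eta_floor = eta_floor
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ----------------------------------------------------------

    def _penalty_matrix(self, lambdas: np.ndarray) -> np.ndarray:
        S = np.zeros((self.n_coef_, self.n_coef_))
        for (sl, Sb), lam in zip(self._penalties, lambdas):
            S[sl, sl] += lam * Sb
        return S

    def _pen_dev(self, D, y, beta, lambdas, theta) -> float:
        eta = np.maximum(D @ beta, self.eta_floor)
        dev = nb_deviance(y, eta**2, theta)
        pen = 0.0
        for (sl, Sb), lam in zip(self._penalties, lambdas):
            b = beta[sl]
            pen += lam * float(b @ Sb @ b)
        return dev + pen

    @staticmethod
    def _chol_solve(A, B):
        try:
            c = cho_factor(A)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.mean(np.diag(A)) * np.eye(A.shape[0])
            c = cho_factor(A)
        return cho_solve(c, B)

    def _pirls(self, D, y, lambdas, theta, beta=None):
        n = len(y)
        if beta is None:
            eta = np.sqrt(y + 0.1)
            beta_ok = None
            pd_old = np.inf
        else:
            beta_ok = beta
            eta = np.maximum(D @ beta, self.eta_floor)
            pd_old = self._pen_dev(D, y, beta, lambdas, theta)
        trace = []
        for it in range(self.max_iter):
            mu = eta**2
            w = 4.0 * eta**2 / (mu * (1.0 + mu / theta))
            z = eta + (y - mu) / (2.0 * eta)
            H = D.T @ (w[:, None] * D)
            r = D.T @ (w * z)
            A = H + self._penalty_matrix(lambdas)
            beta_new = self._chol_solve(A, r)
            pd_new = self._pen_dev(D, y, beta_new, lambdas, theta)
            if beta_ok is not None:
                halvings = 0
                while pd_new > pd_old + 1e-10 and halvings < 30:
                    beta_new = 0.5 * (beta_new + beta_ok)
                    pd_new = self._pen_dev(D, y, beta_new, lambdas, theta)
                    halvings += 1
                if pd_new > pd_old + 1e-10:
                    break  # no improving step remains: converged
            trace.append(pd_new)
            converged = beta_ok is not None and abs(pd_old - pd_new) < self.tol * (
                abs(pd_new) + 0.1
            )
            beta_ok = beta_new
            pd_old = pd_new
            eta = np.maximum(D @ beta_ok, self.eta_floor)
            if converged:
                return beta_ok, trace
        if len(trace) >= self.max_iter:
            raise RuntimeError(
                f"PIRLS failed to converge in {self.max_iter} iterations; "
                f"penalized-deviance trace tail: {trace[-5:]}"
            )
        return beta_ok, trace

    def _gcv(self, H, r, zwz, lambdas, n) -> float:
        A = H + self._penalty_matrix(lambdas)
        try:
            c = cho_factor(A)
        except np.linalg.LinAlgError:
            return np.inf
        beta = cho_solve(c, r)
        tr = float(np.trace(cho_solve(c, H)))
        rss = max(zwz - 2.0 * beta @ r + beta @ (H @ beta), 1e-300)
        denom = max(n - tr, 1e-3)
        return n * rss / denom**2

    def _select_lambdas(self, D, y, lambdas, theta, beta):
        """One coordinate-wise GCV sweep at the converged working model."""
        n = len(y)
        eta = np.maximum(D @ beta, self.eta_floor)
        mu = eta**2
        w = 4.0 * eta**2 / (mu * (1.0 + mu / theta))
        z = eta + (y - mu) / (2.0 * eta)
        H = D.T @ (w[:, None] * D)
        r = D.T @ (w * z)
        zwz = float(np.sum(w * z * z))
        lambdas = lambdas.copy()
        for j in range(len(lambdas)):

            def score(loglam):
                trial = lambdas.copy()
                trial[j] = 10.0**loglam
                return self._gcv(H, r, zwz, trial, n)

            grid = np.arange(-6.0, 10.1, 2.0)
            vals = [score(g) for g in grid]
            g0 = grid[int(np.argmin(vals))]
            res = minimize_scalar(
                score, bounds=(g0 - 2.0, g0 + 2.0), method="bounded",
                options={"xatol": 0.05},
            )
            lambdas[j] = 10.0 ** float(res.x)
        return lambdas

    def _profile_theta(self, y, mu) -> float:
        res = minimize_scalar(
            lambda lt: -nb_loglik(y, mu, math.exp(lt)),
            bounds=(math.log(1e-3), math.log(1e7)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        return float(math.exp(res.x))

    def _build_design(self, X: pd.DataFrame, training: bool):
        n = len(X)
        blocks = [np.ones((n, 1))]
        n_clamped = 0
        if training:
            self.terms_ = []
            self._penalties = []
            self.term_slices_ = {}
            col = 1
            for spec in self.smooths:
                term = _Term(spec, X)
                sl = slice(col, col + term.width)
                self.terms_.append(term)
                self.term_slices_[spec.name] = sl
                for Sb in term.penalties:
                    # unit-normalised penalty: lambda scales are comparable
                    nrm = np.linalg.norm(Sb, "fro")
                    self._penalties.append((sl, Sb / nrm if nrm > 0 else Sb))
                blocks.append(term.design0)
                col += term.width
            self.n_coef_ = col
        else:
            for term in self.terms_:
                blk, nc = term.design(X)
                blocks.append(blk)
                n_clamped += nc
        return np.hstack(blocks), n_clamped

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float).ravel()
        if np.any(y < 0):
            raise ValueError("response must be non-negative")
        if np.any(~np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        tensor_count = sum(1 for s in self.smooths if s.basis == "tensor3")
        if tensor_count > 1:
            raise ValueError("at most one tensor3 term per model")
        D, _ = self._build_design(X, training=True)
        n, p = D.shape
        theta = float(self.theta) if self.theta is not None else 1.0
        lambdas = np.full(len(self._penalties), float(self.lambda_init))

        beta, trace = self._pirls(D, y, lambdas, theta)
        for _sweep in range(self.n_sweeps):
            if self.select_lambda and len(lambdas):
                lambdas = self._select_lambdas(D, y, lambdas, theta, beta)
                beta, tr2 = self._pirls(D, y, lambdas, theta, beta)
                trace += tr2
            if self.theta is None:
                eta = np.maximum(D @ beta, self.eta_floor)
                theta = self._profile_theta(y, eta**2)
                beta, tr2 = self._pirls(D, y, lambdas, theta, beta)
                trace += tr2

        eta = np.maximum(D @ beta, self.eta_floor)
        mu = eta**2
        w = 4.0 * eta**2 / (mu * (1.0 + mu / theta))
        H = D.T @ (w[:, None] * D)
        A = H + self._penalty_matrix(lambdas)
        Ainv = self._chol_solve(A, np.eye(p))
        F = Ainv @ H  # influence-like matrix; per-block traces give edf
        self.coef_ = beta
        self.cov_ = 0.5 * (Ainv + Ainv.T)
        self.lambdas_ = lambdas
        self.theta_ = theta
        self.deviance_ = nb_deviance(y, mu, theta)
        self.deviance_trace_ = trace
        eta0 = minimize_scalar(
            lambda e: nb_deviance(y, np.full(n, e**2), theta),
            bounds=(1e-4, float(np.sqrt(y.mean()) * 4 + 1)),
            method="bounded",
        ).x
        self.null_deviance_ = nb_deviance(y, np.full(n, float(eta0) ** 2), theta)
        self.deviance_explained_ = 1.0 - self.deviance_ / self.null_deviance_
        self.edf_ = float(np.trace(F))
        self.edf_per_smooth_ = {
            name: float(np.trace(F[sl, sl])) for name, sl in self.term_slices_.items()
        }
        k_theta = 1 if self.theta is None else 0
        self.loglik_ = nb_loglik(y, mu, theta)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * (self.edf_ + k_theta)
        # the model's prediction for the training rows (unfloored eta, so
        # predict() on the training table reproduces these exactly)
        self.fitted_values_ = (D @ beta) ** 2
        self.n_obs_ = n
        self.smoothing_criterion_ = "GCV (working model, coordinate-wise)"
        return self

    def predict_terms(self, X: pd.DataFrame):
        """(eta, mu, se_eta) for new rows; out-of-range covariates are
        clamped to the training range (count logged)."""
        D, n_clamped = self._build_design(X, training=False)
        if n_clamped:
            logger.info("prediction: clamped %d out-of-range covariate values",
                        n_clamped)
        self.last_clamp_count_ = n_clamped
        eta = D @ self.coef_
        mu = eta**2
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, self.cov_, D), 0.0))
        return eta, mu, se

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_terms(X)[1]

    # -- interpretation -----------------------------------------------------

    def response_curve(self, covariate: str, n_grid: int = 100) -> ResponseCurve:
        for term in self.terms_:
            if term.spec.basis in ("cubic_spline", "cyclic_spline") and (
                term.spec.covariates[0] == covariate
            ):
                break
        else:
            raise ValueError(
                f"{covariate!r} has no univariate smooth in this model "
                "(tensor terms: use tensor_slice)"
            )
        lo, hi = term.ranges[covariate]
        grid = np.linspace(lo, hi, n_grid)
        block, _ = term.design(pd.DataFrame({covariate: grid}))
        sl = self.term_slices_[term.spec.name]
        f = block @ self.coef_[sl]
        V = self.cov_[sl, sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", block, V, block), 0.0))
        mask = se < np.abs(f) / 2.0
        return ResponseCurve(covariate, grid, f, se, mask)

    def tensor_slice(self, doy: float, n_lon: int = 40, n_lat: int = 40):
        """Tensor contribution on a lon x lat grid at a fixed day-of-year.
        Returns (lons, lats, field) with field shape (n_lat, n_lon)."""
        if not 1 <= doy <= 366:
            raise ValueError(f"doy must lie in [1, 366], got {doy}")
        for term in self.terms_:
            if term.spec.basis == "tensor3":
                break
        else:
            raise ValueError("model has no tensor3 term")
        c_lon, c_lat, _ = term.spec.covariates
        lons = np.linspace(*term.ranges[c_lon], n_lon)
        lats = np.linspace(*term.ranges[c_lat], n_lat)
        lon2, lat2 = np.meshgrid(lons, lats)
        df = pd.DataFrame(
            {
                c_lon: lon2.ravel(),
                c_lat: lat2.ravel(),
                "doy": np.full(lon2.size, float(doy)),
            }
        )
        block, _ = term.design(df)
        sl = self.term_slices_[term.spec.name]
        f = block @ self.coef_[sl]
        return lons, lats, f.reshape(n_lat, n_lon)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        terms_meta = []
        for term in self.terms_:
            meta = {
                "covariates": list(term.spec.covariates),
                "basis": term.spec.basis,
                "k": list(term.spec.k),
                "ranges": {c: list(r) for c, r in term.ranges.items()},
                "Z": None if term.Z is None else term.Z.tolist(),
                "knots": {c: kn.tolist() for c, kn in getattr(term, "_knots", {}).items()},
                "center": getattr(term, "center", None),
            }
            terms_meta.append(meta)
        payload = {
            "terms": terms_meta,
            "coef": self.coef_.tolist(),
            "cov": self.cov_.tolist(),
            "lambdas": self.lambdas_.tolist(),
            "theta": self.theta_,
            "deviance": self.deviance_,
            "null_deviance": self.null_deviance_,
            "aic": self.aic_,
            "edf": self.edf_,
            "eta_floor": self.eta_floor,
            "smoothing_criterion": self.smoothing_criterion_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NegativeBinomialGAM":
        payload = json.loads(Path(path).read_text())
        specs = []
        for meta in payload["terms"]:
            specs.append(
                SmoothSpec(
                    tuple(meta["covariates"]),
                    meta["basis"],
                    tuple(meta["k"]) if meta["basis"] == "tensor3" else meta["k"][0],
                )
            )
        model = cls(specs, eta_floor=payload["eta_floor"])
        model.terms_ = []
        model.term_slices_ = {}
        col = 1
        for spec, meta in zip(specs, payload["terms"]):
            term = _Term.__new__(_Term)
            term.spec = spec
            term.ranges = {c: tuple(r) for c, r in meta["ranges"].items()}
            term.Z = None if meta["Z"] is None else np.asarray(meta["Z"])
            if meta["knots"]:
                term._knots = {c: np.asarray(kn) for c, kn in meta["knots"].items()}
            if meta["center"] is not None:
                term.center = meta["center"]
            term.width = 1 if term.Z is None else term.Z.shape[1]
            model.terms_.append(term)
            model.term_slices_[spec.name] = slice(col, col + term.width)
            col += term.width
        model.n_coef_ = col
        model.coef_ = np.asarray(payload["coef"])
        model.cov_ = np.asarray(payload["cov"])
        model.lambdas_ = np.asarray(payload["lambdas"])
        model.theta_ = payload["theta"]
        model.deviance_ = payload["deviance"]
        model.null_deviance_ = payload["null_deviance"]
        model.deviance_explained_ = 1.0 - model.deviance_ / model.null_deviance_
        model.aic_ = payload["aic"]
        model.edf_ = payload["edf"]
        model.smoothing_criterion_ = payload["smoothing_criterion"]
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def fit_gam(
    table: pd.DataFrame,
    specs: list[SmoothSpec],
    response_col: str = "response",
    theta=None,
    **kwargs,
) -> NegativeBinomialGAM:
    model = NegativeBinomialGAM(specs, theta=theta, **kwargs)
    return model.fit(table, table[response_col].to_numpy(dtype=float))


def predict(model: NegativeBinomialGAM, new_rows: pd.DataFrame):
    return model.predict_terms(new_rows)


def response_curves(
    model: NegativeBinomialGAM, covariate: str, n_grid: int = 100
) -> ResponseCurve:
    return model.response_curve(covariate, n_grid)


def tensor_slices(model: NegativeBinomialGAM, doy: float, n_lon=40, n_lat=40):
    return model.tensor_slice(doy, n_lon=n_lon, n_lat=n_lat)
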