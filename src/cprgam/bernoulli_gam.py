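"""Penalized Bernoulli GAM: design assembly, PIRLS fitting, smoothness
selection, information criteria, prediction and posterior draws.

The linear predictor is

    logit(p) = intercept + b_dn * [dn == day] + smooth terms,

where the smooth terms follow a structural spec: an additive or
tensor-product representation of (east, north, doy), optionally a smooth
year term, and optional conditioning of the day-of-year and/or year
smooths on the spatial component (north/south of a split latitude).

Smoothing parameters are chosen by minimizing an UBRE-type criterion
``deviance/n + 2*gamma*edf/n - 1`` over log-lambda with a derivative-free
optimizer (multi-start Nelder-Mead, coarse-grid fallback), with the
overfit-guard multiplier ``gamma`` defaulting to 1.4.  AIC uses the
effective degrees of freedom: ``AIC = deviance + 2*edf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from . import geo_time
from .smoother_basis import (
    COMPONENT_LABELS,
    MarginalBasis,
    TensorTerm,
    absorb_constraint,
    cubic_basis,
    cyclic_basis,
    tensor_product,
)

__all__ = [
    "SPACE_TIME_FORMS",
    "YEAR_TERMS",
    "ModelSpec",
    "BasisDims",
    "FitSettings",
    "SmoothBlock",
    "ModelDesign",
    "PirlsResult",
    "FittedModel",
    "assemble_design",
    "fit_pirls",
    "select_lambda",
    "fit_model",
    "aic",
    "deviance_explained",
    "predict_prob",
    "posterior_draws",
    "assign_component",
]

SPACE_TIME_FORMS = ("none", "e+n+doy", "e*n+doy", "e*n*doy")
YEAR_TERMS = ("none", "smooth", "smooth_by_comp")

_MU_EPS = 1e-10
_W_FLOOR = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one ensemble member."""

    space_time: str = "e+n+doy"
    doy_by_comp: bool = False
    year_term: str = "none"
    split_latitude: float = 53.0
    model_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.space_time not in SPACE_TIME_FORMS:
            raise ValueError(f"unknown space_time form {self.space_time!r}")
        if self.year_term not in YEAR_TERMS:
            raise ValueError(f"unknown year_term {self.year_term!r}")
        if self.doy_by_comp and self.space_time != "e*n+doy":
            raise ValueError(
                "doy_by_comp requires the separable-doy form 'e*n+doy'"
            )

    @property
    def components(self) -> int:
        return 2 if (self.doy_by_comp or self.year_term == "smooth_by_comp") else 1

    @property
    def description(self) -> str:
        parts = {
            "none": "",
            "e+n+doy": "east + north + doy",
            "e*n+doy": "east*north + doy x comp" if self.doy_by_comp else "east*north + doy",
            "e*n*doy": "east*north*doy",
        }[self.space_time]
        if self.year_term == "smooth":
            parts = (parts + " + syear") if parts else "syear"
        elif self.year_term == "smooth_by_comp":
            parts = (parts + " + syear x comp") if parts else "syear x comp"
        return parts or "intercept + DN"

    def to_dict(self) -> dict:
        return {
            "space_time": self.space_time,
            "doy_by_comp": self.doy_by_comp,
            "year_term": self.year_term,
            "split_latitude": self.split_latitude,
            "model_id": self.model_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass(frozen=True)
class BasisDims:
    """Default basis dimensions for each smooth type (configurable; the
    choices are declared defaults, not estimates)."""

    k_uni: int = 10       # 1-D east/north smooths
    k_doy: int = 10       # separable cyclic day-of-year smooth
    k_tensor2: int = 8    # per-margin, 2-D east x north tensor
    k_tensor3_space: int = 6
    k_tensor3_doy: int = 8
    k_year: int = 10


@dataclass(frozen=True)
class FitSettings:
    """Controls for fitting and smoothness selection."""

    gamma: float = 1.4
    criterion: str = "ubre"
    max_iter: int = 200
    tol: float = 1e-8
    log10_lambda_bounds: tuple[float, float] = (-5.0, 7.0)
    optimizer_maxfev: Optional[int] = None
    n_starts: int = 2
    basis: BasisDims = field(default_factory=BasisDims)

    def __post_init__(self) -> None:
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        if self.criterion != "ubre":
            raise ValueError("only the 'ubre' criterion is implemented")


def assign_component(lat, split_latitude: float = 53.0) -> np.ndarray:
    """Component label per latitude: north iff lat >= split (ties north)."""
    lat = np.asarray(lat, dtype=float)
    return np.where(lat >= split_latitude, "north", "south")


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

@dataclass
class SmoothBlock:
    """One smooth term's columns after constraint absorption."""

    name: str
    term: TensorTerm
    Z: np.ndarray                      # (raw_dim, dim) constraint absorber
    penalties: list[np.ndarray]        # local (dim x dim), one per margin
    comp: Optional[str] = None         # component mask label, if conditioned
    sl: slice = field(default_factory=lambda: slice(0, 0))

    @property
    def dim(self) -> int:
        return self.Z.shape[1]

    def raw_columns(self, data: pd.DataFrame) -> np.ndarray:
        cols = [data[v].to_numpy(dtype=float) for v in self.term.variables]
        B = self.term.evaluate(cols)
        if self.comp is not None:
            mask = (data["comp"].to_numpy() == self.comp).astype(float)
            B = B * mask[:, None]
        return B

    def build(self, data: pd.DataFrame) -> np.ndarray:
        return self.raw_columns(data) @ self.Z

    def out_of_support(self, data: pd.DataFrame) -> np.ndarray:
        flag = np.zeros(len(data), dtype=bool)
        for m in self.term.margins:
            if m.cyclic:
                continue
            lo, hi = m.support()
            x = data[m.variable].to_numpy(dtype=float)
            flag |= (x < lo) | (x > hi)
        return flag

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "term": self.term.to_dict(),
            "Z": self.Z.tolist(),
            "comp": self.comp,
            "sl": [self.sl.start, self.sl.stop],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothBlock":
        term = TensorTerm.from_dict(d["term"])
        Z = np.asarray(d["Z"], dtype=float)
        pen = [Z.T @ S @ Z for S in term.penalties()]
        blk = cls(name=d["name"], term=term, Z=Z, penalties=pen, comp=d["comp"])
        blk.sl = slice(*d["sl"])
        return blk


@dataclass
class ModelDesign:
    """Assembled design: fixed columns + smooth blocks + penalty layout."""

    spec: ModelSpec
    blocks: list[SmoothBlock]
    n_coef: int

    @property
    def n_penalties(self) -> int:
        return sum(len(b.penalties) for b in self.blocks)

    @property
    def coefficient_map(self) -> dict[str, slice]:
        out = {"intercept": slice(0, 1), "dn_day": slice(1, 2)}
        for b in self.blocks:
            out[b.name] = b.sl
        return out

    def penalty_layout(self) -> list[tuple[slice, np.ndarray]]:
        return [(b.sl, S) for b in self.blocks for S in b.penalties]

    def _ensure_comp(self, data: pd.DataFrame) -> pd.DataFrame:
        needs = any(b.comp is not None for b in self.blocks)
        if needs and "comp" not in data.columns:
            if "lat" in data.columns:
                lat = data["lat"].to_numpy(dtype=float)
            else:
                _, lat = geo_time.unproject_plane(
                    data["east"].to_numpy(dtype=float),
                    data["north"].to_numpy(dtype=float),
                )
            data = data.copy()
            data["comp"] = assign_component(lat, self.spec.split_latitude)
        return data

    def build(self, data: pd.DataFrame) -> np.ndarray:
        data = self._ensure_comp(data)
        n = len(data)
        X = np.empty((n, self.n_coef))
        X[:, 0] = 1.0
        X[:, 1] = (data["dn"].to_numpy() == "day").astype(float)
        for b in self.blocks:
            X[:, b.sl] = b.build(data)
        return X

    def extrapolation_flags(self, data: pd.DataFrame) -> np.ndarray:
        data = self._ensure_comp(data)
        flag = np.zeros(len(data), dtype=bool)
        for b in self.blocks:
            flag |= b.out_of_support(data)
        return flag

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "blocks": [b.to_dict() for b in self.blocks],
            "n_coef": self.n_coef,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDesign":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            blocks=[SmoothBlock.from_dict(b) for b in d["blocks"]],
            n_coef=int(d["n_coef"]),
        )


def _shrink_k(k: int, x: np.ndarray, log: list[str], what: str) -> int:
    distinct = np.unique(x).size
    if distinct < 4:
        raise ValueError(f"too few distinct values ({distinct}) for a {what} smooth")
    if distinct < k:
        log.append(f"{what}: basis dimension reduced {k} -> {distinct} (distinct values)")
        return distinct
    return k


def _make_block(
    name: str,
    margins: list[MarginalBasis],
    data: pd.DataFrame,
    comp: Optional[str],
) -> SmoothBlock:
    term = tensor_product(margins)
    cols = [data[v].to_numpy(dtype=float) for v in term.variables]
    B = term.evaluate(cols)
    if comp is not None:
        mask = (data["comp"].to_numpy() == comp).astype(float)
        B = B * mask[:, None]
    _, Sz, Z = absorb_constraint(B, term.penalties())
    return SmoothBlock(name=name, term=term, Z=Z, penalties=Sz, comp=comp)


def assemble_design(
    data: pd.DataFrame, spec: ModelSpec, settings: Optional[FitSettings] = None
):
    """Build the design matrix and penalty layout for ``spec``.

    Returns ``(X, design)``.  ``data`` must carry east, north, doy, year,
    dn and (for by-component terms) either a ``comp`` column or ``lat``.
    """
    settings = settings or FitSettings()
    dims = settings.basis
    if data.empty:
        raise ValueError("data must be non-empty")
    log: list[str] = []

    needs_comp = spec.doy_by_comp or spec.year_term == "smooth_by_comp"
    if needs_comp:
        if "comp" not in data.columns:
            if "lat" not in data.columns:
                raise ValueError(
                    "by-component terms require a 'comp' or 'lat' column"
                )
            data = data.copy()
            data["comp"] = assign_component(
                data["lat"].to_numpy(dtype=float), spec.split_latitude
            )
        for lab in COMPONENT_LABELS:
            if not (data["comp"] == lab).any():
                raise ValueError(
                    f"no observations in the {lab!r} component under "
                    f"split latitude {spec.split_latitude}"
                )

    east = data["east"].to_numpy(dtype=float)
    north = data["north"].to_numpy(dtype=float)
    doy = data["doy"].to_numpy(dtype=float)

    blocks: list[SmoothBlock] = []
    if spec.space_time == "e+n+doy":
        blocks.append(_make_block(
            "s(east)", [cubic_basis(east, _shrink_k(dims.k_uni, east, log, "east"), "east")],
            data, None))
        blocks.append(_make_block(
            "s(north)", [cubic_basis(north, _shrink_k(dims.k_uni, north, log, "north"), "north")],
            data, None))
        blocks.append(_make_block(
            "s(doy)", [cyclic_basis(doy, dims.k_doy, variable="doy")], data, None))
    elif spec.space_time == "e*n+doy":
        k2e = _shrink_k(dims.k_tensor2, east, log, "east")
        k2n = _shrink_k(dims.k_tensor2, north, log, "north")
        blocks.append(_make_block(
            "te(east,north)",
            [cubic_basis(east, k2e, "east"), cubic_basis(north, k2n, "north")],
            data, None))
        if spec.doy_by_comp:
            for lab in COMPONENT_LABELS:
                blocks.append(_make_block(
                    f"s(doy):{lab}",
                    [cyclic_basis(doy, dims.k_doy, variable="doy")],
                    data, lab))
        else:
            blocks.append(_make_block(
                "s(doy)", [cyclic_basis(doy, dims.k_doy, variable="doy")], data, None))
    elif spec.space_time == "e*n*doy":
        k3e = _shrink_k(dims.k_tensor3_space, east, log, "east")
        k3n = _shrink_k(dims.k_tensor3_space, north, log, "north")
        blocks.append(_make_block(
            "te(east,north,doy)",
            [
                cubic_basis(east, k3e, "east"),
                cubic_basis(north, k3n, "north"),
                cyclic_basis(doy, dims.k_tensor3_doy, variable="doy"),
            ],
            data, None))
    # space_time == "none": no spatial blocks

    if spec.year_term != "none":
        year = data["year"].to_numpy(dtype=float)
        k_year = _shrink_k(dims.k_year, year, log, "year")
        if spec.year_term == "smooth":
            blocks.append(_make_block(
                "s(year)", [cubic_basis(year, k_year, "year")], data, None))
        else:
            for lab in COMPONENT_LABELS:
                blocks.append(_make_block(
                    f"s(year):{lab}", [cubic_basis(year, k_year, "year")], data, lab))

    pos = 2
    for b in blocks:
        b.sl = slice(pos, pos + b.dim)
        pos += b.dim
    design = ModelDesign(spec=spec, blocks=blocks, n_coef=pos)
    X = design.build(data)
    return X, design, log


# ---------------------------------------------------------------------------
# PIRLS
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _penalty_full(
    layout: Sequence[tuple[slice, np.ndarray]], lam: np.ndarray, p: int
) -> np.ndarray:
    S = np.zeros((p, p))
    for (sl, Sj), lj in zip(layout, lam):
        S[sl, sl] += lj * Sj
    return S


@dataclass
class PirlsResult:
    beta: np.ndarray
    deviance: float
    penalized_deviance: float
    edf: float
    edf_by_col: np.ndarray
    Vb: Optional[np.ndarray]
    converged: bool
    n_iter: int
    separation_flag: bool


def fit_pirls(
    X: np.ndarray,
    penalty_layout: Sequence[tuple[slice, np.ndarray]],
    y: np.ndarray,
    lam: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
    beta0: Optional[np.ndarray] = None,
    want_Vb: bool = True,
) -> PirlsResult:
    """Maximize the penalized Bernoulli log-likelihood by iteratively
    reweighted least squares with step halving.

    ``penalty_layout`` is a list of ``(column-slice, local S)`` pairs and
    ``lam`` the aligned smoothing parameters.  ``edf`` is the trace of
    the influence matrix and ``Vb`` the Bayesian covariance
    ``(X'WX + S_lambda)^-1`` at convergence.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    lam = np.asarray(lam, dtype=float)
    if len(lam) != len(penalty_layout):
        raise ValueError("one lambda per penalty required")
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    Slam = _penalty_full(penalty_layout, lam, p)

    if beta0 is not None:
        beta = beta0.copy()
    else:
        beta = np.zeros(p)
        ybar = np.clip(y.mean(), _MU_EPS, 1 - _MU_EPS)
        beta[0] = np.log(ybar / (1.0 - ybar))

    eta = X @ beta
    mu = expit(eta)
    pen_dev = _binomial_deviance(y, mu) + float(beta @ Slam @ beta)
    converged = False
    it = 0
    chol = None
    XtWX = None
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + Slam
        try:
            chol = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.trace(A) / p * np.eye(p)
            chol = cho_factor(A, lower=True)
        beta_new = cho_solve(chol, Xw.T @ z)

        step = 1.0
        for _half in range(40):
            beta_try = beta + step * (beta_new - beta)
            eta_try = X @ beta_try
            mu_try = expit(eta_try)
            pen_try = _binomial_deviance(y, mu_try) + float(beta_try @ Slam @ beta_try)
            if pen_try <= pen_dev + 1e-12 * (abs(pen_dev) + 1.0):
                break
            step *= 0.5
        beta, eta, mu = beta_try, eta_try, mu_try
        delta = pen_dev - pen_try
        pen_dev = pen_try
        if abs(delta) < tol * (abs(pen_dev) + 0.1):
            converged = True
            break

    # influence/covariance at the final weights
    w = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
    XtWX = X.T @ (X * w[:, None])
    A = XtWX + Slam
    try:
        chol = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.trace(A) / p * np.eye(p)
        chol = cho_factor(A, lower=True)
    F = cho_solve(chol, XtWX)
    edf_by_col = np.diag(F).copy()
    edf = float(edf_by_col.sum())
    Vb = cho_solve(chol, np.eye(p)) if want_Vb else None
    dev = _binomial_deviance(y, mu)
    separation = bool(np.linalg.norm(beta) > 1e4 or np.max(np.abs(eta)) > 300.0)

    return PirlsResult(
        beta=beta,
        deviance=dev,
        penalized_deviance=pen_dev,
        edf=edf,
        edf_by_col=edf_by_col,
        Vb=Vb,
        converged=converged,
        n_iter=it,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# Smoothness selection
# ---------------------------------------------------------------------------

def _ubre(dev: float, edf: float, n: int, gamma: float) -> float:
    return dev / n + 2.0 * gamma * edf / n - 1.0


def select_lambda(
    X: np.ndarray,
    penalty_layout: Sequence[tuple[slice, np.ndarray]],
    y: np.ndarray,
    settings: Optional[FitSettings] = None,
):
    """Minimize the UBRE-type criterion over log10-lambda.

    Returns ``(lam_hat, result, log)`` where ``result`` is the fully
    converged :class:`PirlsResult` at the selected lambdas.
    """
    settings = settings or FitSettings()
    m = len(penalty_layout)
    if m < 1:
        raise ValueError("select_lambda requires at least one penalty")
    n = X.shape[0]
    lo, hi = settings.log10_lambda_bounds
    log: list[str] = []
    warm = {"beta": None}

    def objective(loglam: np.ndarray) -> float:
        loglam = np.clip(loglam, lo, hi)
        lam = 10.0 ** loglam
        res = fit_pirls(
            X, penalty_layout, y, lam,
            max_iter=50, tol=max(settings.tol, 1e-7),
            beta0=warm["beta"], want_Vb=False,
        )
        warm["beta"] = res.beta
        val = _ubre(res.deviance, res.edf, n, settings.gamma)
        return val if np.isfinite(val) else 1e10

    starts = [np.zeros(m), np.full(m, 3.0)][: max(1, settings.n_starts)]
    maxfev = settings.optimizer_maxfev or min(max(60, 40 * m), 200)
    best_val, best_x = np.inf, None
    for x0 in starts:
        # default Nelder-Mead simplex is far too small at x0=0; use
        # ~1.5-decade steps so the lambda scale is actually explored
        simplex = np.vstack([x0] + [x0 + 1.5 * np.eye(m)[i] for i in range(m)])
        try:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={
                    "maxfev": maxfev, "xatol": 0.2, "fatol": 1e-6,
                    "adaptive": m > 2, "initial_simplex": simplex,
                },
            )
            if np.isfinite(res.fun) and res.fun < best_val:
                best_val, best_x = res.fun, np.clip(res.x, lo, hi)
        except Exception as exc:  # pragma: no cover - defensive
            log.append(f"optimizer start {x0.tolist()} failed: {exc}")

    if best_x is None:
        log.append("optimizer failed; falling back to coarse log-grid search")
        for g in (-2.0, 0.0, 2.0, 4.0, 6.0):
            x = np.full(m, g)
            val = objective(x)
            if val < best_val:
                best_val, best_x = val, x

    lam_hat = 10.0 ** best_x
    log.append(
        f"selected log10(lambda) = {np.round(best_x, 3).tolist()} "
        f"(criterion {best_val:.6f})"
    )
    final = fit_pirls(
        X, penalty_layout, y, lam_hat,
        max_iter=settings.max_iter, tol=settings.tol,
        beta0=warm["beta"], want_Vb=True,
    )
    if not final.converged:
        log.append("final PIRLS did not meet tolerance within max iterations")
    if final.separation_flag:
        log.append("possible complete separation detected (diverging coefficients)")
    return lam_hat, final, log


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted Bernoulli GAM with everything needed for prediction,
    information criteria and posterior simulation."""

    spec: ModelSpec
    settings: FitSettings
    design: ModelDesign
    beta: np.ndarray
    Vb: np.ndarray
    lam: np.ndarray
    edf_total: float
    edf_by_term: dict[str, float]
    deviance: float
    null_deviance: float
    n: int
    converged: bool
    separation_flag: bool
    fit_log: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        # saturated Bernoulli log-likelihood is 0, so deviance = -2*loglik
        return -0.5 * self.deviance

    def aic(self) -> float:
        return self.deviance + 2.0 * self.edf_total

    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    def linear_predictor(self, points: pd.DataFrame) -> np.ndarray:
        X = self.design.build(points)
        return X @ self.beta

    def predict_prob(
        self, points: pd.DataFrame, return_extrapolation: bool = False
    ):
        eta = self.linear_predictor(points)
        p = expit(eta)
        if return_extrapolation:
            return p, self.design.extrapolation_flags(points)
        return p

    def posterior_draws(self, n_draws: int, seed: int = 0) -> np.ndarray:
        """Draws from Normal(beta, Vb); shape (n_draws, n_coef)."""
        rng = np.random.default_rng(seed)
        p = len(self.beta)
        V = 0.5 * (self.Vb + self.Vb.T)
        try:
            L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / max(p, 1) * np.eye(p))
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(V)
            L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        zs = rng.standard_normal((n_draws, p))
        return self.beta + zs @ L.T

    @property
    def dn_coefficient(self) -> float:
        return float(self.beta[1])

    def dn_interval(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        se = float(np.sqrt(self.Vb[1, 1]))
        zq = norm.ppf(0.5 + level / 2.0)
        return (self.dn_coefficient - zq * se, self.dn_coefficient + zq * se)


def _null_deviance(y: np.ndarray) -> float:
    ybar = float(np.clip(y.mean(), _MU_EPS, 1 - _MU_EPS))
    mu = np.full_like(y, ybar, dtype=float)
    return _binomial_deviance(np.asarray(y, float), mu)


def fit_model(
    data: pd.DataFrame, spec: ModelSpec, settings: Optional[FitSettings] = None
) -> FittedModel:
    """Assemble, select smoothness and fit one model spec on ``data``.

    ``data`` must carry columns y (or present), east, north, doy, year,
    dn, and lat/comp when the spec conditions on components.
    """
    settings = settings or FitSettings()
    ycol = "y" if "y" in data.columns else "present"
    y = data[ycol].to_numpy(dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("response must be 0/1")
    X, design, log = assemble_design(data, spec, settings)
    layout = design.penalty_layout()
    if layout:
        lam, res, sel_log = select_lambda(X, layout, y, settings)
        log += sel_log
    else:
        lam = np.array([])
        res = fit_pirls(
            X, [], y, lam, max_iter=settings.max_iter, tol=settings.tol
        )

    edf_by_term: dict[str, float] = {
        "intercept": float(res.edf_by_col[0]),
        "dn_day": float(res.edf_by_col[1]),
    }
    for b in design.blocks:
        edf_by_term[b.name] = float(res.edf_by_col[b.sl].sum())

    return FittedModel(
        spec=spec,
        settings=settings,
        design=design,
        beta=res.beta,
        Vb=res.Vb,
        lam=np.asarray(lam, dtype=float),
        edf_total=res.edf,
        edf_by_term=edf_by_term,
        deviance=res.deviance,
        null_deviance=_null_deviance(y),
        n=len(data),
        converged=res.converged,
        separation_flag=res.separation_flag,
        fit_log=log,
    )


# Spec-level operation aliases ------------------------------------------------

def aic(model: FittedModel, settings: Optional[FitSettings] = None) -> float:
    """Conditional AIC with effective degrees of freedom."""
    return model.aic()


def deviance_explained(model: FittedModel) -> float:
    return model.deviance_explained()


def predict_prob(model: FittedModel, points: pd.DataFrame, **kw):
    return model.predict_prob(points, **kw)


def posterior_draws(model: FittedModel, n_draws: int, seed: int = 0) -> np.ndarray:
    return model.posterior_draws(n_draws, seed)
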