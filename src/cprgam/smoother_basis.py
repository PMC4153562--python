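"""Penalized spline building blocks.

Univariate cubic B-spline bases with second-order difference penalties
(P-splines) stand in for cubic regression splines: same function class
and the same smoothness rationale.  Day-of-year smooths use a wrapped
(periodic) B-spline basis with a circular difference penalty.  Tensor
products combine 1-3 margins by row-wise Kronecker products, with one
penalty per margin.  Sum-to-zero identifiability constraints are absorbed
by an orthogonal reparameterization built from training-column means,
dropping one column per smooth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "MarginalBasis",
    "TensorTerm",
    "cubic_basis",
    "cyclic_basis",
    "tensor_product",
    "by_component",
    "absorb_constraint",
    "COMPONENT_LABELS",
    "TENSOR_DIM_CAP",
]

COMPONENT_LABELS = ("north", "south")
TENSOR_DIM_CAP = 4096


def _second_difference_matrix(k: int) -> np.ndarray:
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D


def _circular_difference_matrix(k: int) -> np.ndarray:
    D = np.zeros((k, k))
    for i in range(k):
        D[i, i] = 1.0
        D[i, (i + 1) % k] = -2.0
        D[i, (i + 2) % k] = 1.0
    return D


@dataclass
class MarginalBasis:
    """One margin of a smooth: evaluation rule plus roughness penalty."""

    variable: str
    knots: np.ndarray        # full (padded) knot vector
    k: int                   # basis dimension
    cyclic: bool = False
    period: float = 365.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Design columns (n, k) at points ``x``.

        Non-cyclic bases are extended linearly beyond the boundary knots
        so out-of-range prediction points degrade gracefully.
        """
        x = np.asarray(x, dtype=float)
        if self.cyclic:
            return self._evaluate_cyclic(x)
        return self._evaluate_open(x)

    def _evaluate_open(self, x: np.ndarray) -> np.ndarray:
        t = self.knots
        lo, hi = t[3], t[-4]
        xc = np.clip(x, lo, hi)
        B = BSpline.design_matrix(xc, t, 3).toarray()
        below = x < lo
        above = x > hi
        if below.any() or above.any():
            h = 1e-6 * max(hi - lo, 1.0)
            for mask, edge, sgn in ((below, lo, 1.0), (above, hi, -1.0)):
                if mask.any():
                    Be = BSpline.design_matrix(np.array([edge]), t, 3).toarray()
                    Bi = BSpline.design_matrix(np.array([edge + sgn * h]), t, 3).toarray()
                    slope = (Bi - Be) / (sgn * h)
                    B[mask] = Be + (x[mask] - edge)[:, None] * slope
        return B

    def _evaluate_cyclic(self, x: np.ndarray) -> np.ndarray:
        xm = np.mod(x, self.period)
        B = BSpline.design_matrix(xm, self.knots, 3).toarray()  # (n, k+3)
        out = B[:, : self.k].copy()
        out[:, :3] += B[:, self.k :]
        return out

    def penalty(self) -> np.ndarray:
        """Symmetric PSD roughness penalty on the k coefficients."""
        if self.cyclic:
            D = _circular_difference_matrix(self.k)
        else:
            D = _second_difference_matrix(self.k)
        return D.T @ D

    def support(self) -> tuple[float, float]:
        if self.cyclic:
            return (0.0, self.period)
        return (float(self.knots[3]), float(self.knots[-4]))

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "knots": np.asarray(self.knots).tolist(),
            "k": int(self.k),
            "cyclic": bool(self.cyclic),
            "period": float(self.period),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalBasis":
        return cls(
            variable=d["variable"],
            knots=np.asarray(d["knots"], dtype=float),
            k=int(d["k"]),
            cyclic=bool(d["cyclic"]),
            period=float(d["period"]),
        )


def cubic_basis(x: np.ndarray, k: int, variable: str = "x") -> MarginalBasis:
    """Cubic B-spline basis with knots at data quantiles.

    Order-4 B-splines; interior knots at the (k-4) equi-probability
    quantiles of ``x``; second-order difference penalty, so constants and
    index-linear coefficient patterns are unpenalized.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if k < 4:
        raise ValueError("an order-4 B-spline basis needs dimension k >= 4")
    xu = np.unique(x)
    if xu.size < k:
        raise ValueError(
            f"basis dimension k={k} exceeds the {xu.size} distinct design points"
        )
    lo, hi = float(xu[0]), float(xu[-1])
    n_int = k - 4
    if n_int > 0:
        probs = np.arange(1, n_int + 1) / (n_int + 1)
        interior = np.quantile(x, probs)
        interior = np.clip(interior, lo, hi)
        # nudge ties apart; quantiles of heavily tied data can coincide
        for i in range(1, n_int):
            if interior[i] <= interior[i - 1]:
                interior[i] = interior[i - 1] + 1e-8 * max(hi - lo, 1.0)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    return MarginalBasis(variable=variable, knots=t, k=k, cyclic=False)


def cyclic_basis(
    x: np.ndarray, k: int, period: float = 365.0, variable: str = "doy"
) -> MarginalBasis:
    """Periodic cubic B-spline basis on [0, period) with wrapped penalty."""
    if k < 4:
        raise ValueError("cyclic basis requires k >= 4")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    h = period / k
    t = h * np.arange(-3, k + 4)  # k+3 ordinary B-splines covering [0, period]
    return MarginalBasis(variable=variable, knots=t, k=k, cyclic=True, period=period)


@dataclass
class TensorTerm:
    """Tensor-product smooth over 1-3 margins.

    Column ordering: the first margin varies slowest (``np.kron`` order),
    so the expanded penalty for margin *i* is ``I x ... S_i ... x I``.
    """

    margins: list[MarginalBasis]

    def __post_init__(self) -> None:
        if not 1 <= len(self.margins) <= 3:
            raise ValueError("tensor terms take 1-3 margins")
        if self.dim > TENSOR_DIM_CAP:
            raise ValueError(
                f"tensor dimension {self.dim} exceeds the cap of {TENSOR_DIM_CAP}; "
                "reduce per-margin basis dimensions"
            )

    @property
    def dim(self) -> int:
        return int(np.prod([m.k for m in self.margins]))

    @property
    def variables(self) -> list[str]:
        return [m.variable for m in self.margins]

    def evaluate(self, cols: Sequence[np.ndarray]) -> np.ndarray:
        """Row-wise Kronecker product of marginal evaluations."""
        if len(cols) != len(self.margins):
            raise ValueError("one data column per margin required")
        mats = [m.evaluate(np.asarray(c, dtype=float)) for m, c in zip(self.margins, cols)]
        out = mats[0]
        for M in mats[1:]:
            out = (out[:, :, None] * M[:, None, :]).reshape(out.shape[0], -1)
        return out

    def penalties(self) -> list[np.ndarray]:
        """One expanded (dim x dim) penalty per margin."""
        ks = [m.k for m in self.margins]
        out = []
        for i, m in enumerate(self.margins):
            mats = [np.eye(kj) for kj in ks]
            mats[i] = m.penalty()
            S = mats[0]
            for Mj in mats[1:]:
                S = np.kron(S, Mj)
            out.append(S)
        return out

    def to_dict(self) -> dict:
        return {"margins": [m.to_dict() for m in self.margins]}

    @classmethod
    def from_dict(cls, d: dict) -> "TensorTerm":
        return cls(margins=[MarginalBasis.from_dict(m) for m in d["margins"]])


def tensor_product(margins: Sequence[MarginalBasis]) -> TensorTerm:
    """Combine marginal bases into a tensor-product term."""
    return TensorTerm(margins=list(margins))


def absorb_constraint(X: np.ndarray, penalties: Sequence[np.ndarray]):
    """Absorb the sum-to-zero (training-column-mean) constraint.

    Returns ``(XZ, [Z'SZ...], Z)`` where ``Z`` is an orthonormal basis of
    the null space of the column-mean row vector; the reparameterized
    design has one fewer column and the fitted-value space under the
    constraint is preserved.
    """
    c = X.mean(axis=0)
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:
        # already orthogonal to the constraint; drop nothing
        Z = np.eye(X.shape[1])
        return X, [np.asarray(S, dtype=float) for S in penalties], Z
    q, _ = np.linalg.qr(c.reshape(-1, 1) / nrm, mode="complete")
    Z = q[:, 1:]
    Xz = X @ Z
    Sz = [Z.T @ S @ Z for S in penalties]
    return Xz, Sz, Z


@dataclass
class ByComponentTerm:
    """A smooth duplicated per spatial component (separate coefficients
    and penalties per component block)."""

    base: TensorTerm
    labels: tuple[str, ...] = COMPONENT_LABELS

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in COMPONENT_LABELS:
                raise ValueError(f"unknown component label {lab!r}")

    @property
    def dim(self) -> int:
        return self.base.dim * len(self.labels)

    def evaluate(self, cols: Sequence[np.ndarray], comp: np.ndarray) -> np.ndarray:
        comp = np.asarray(comp)
        unknown = set(np.unique(comp)) - set(COMPONENT_LABELS)
        if unknown:
            raise ValueError(f"unknown component label(s): {sorted(unknown)}")
        B = self.base.evaluate(cols)
        blocks = []
        for lab in self.labels:
            mask = (comp == lab).astype(float)[:, None]
            blocks.append(B * mask)
        return np.hstack(blocks)

    def penalties(self) -> list[np.ndarray]:
        """Per-component copies of the base penalties, embedded block-diagonally."""
        k = self.base.dim
        out = []
        for i, _lab in enumerate(self.labels):
            for S in self.base.penalties():
                big = np.zeros((self.dim, self.dim))
                big[i * k : (i + 1) * k, i * k : (i + 1) * k] = S
                out.append(big)
        return out


def by_component(term: TensorTerm | MarginalBasis, labels=COMPONENT_LABELS) -> ByComponentTerm:
    """Expand a smooth so each component gets its own function."""
    if isinstance(term, MarginalBasis):
        term = TensorTerm(margins=[term])
    return ByComponentTerm(base=term, labels=tuple(labels))
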