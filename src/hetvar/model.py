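"""Random-effects meta-analysis / meta-regression model and the moment
estimator of the between-study variance.

The model for study estimates ``y_i`` with known within-study variances
``sigma2_i`` and covariate rows ``x_i`` is

    y_i | x_i  ~  N(x_i beta, sigma2_i + tau2)

where ``tau2`` is the (residual) between-study variance.  Heterogeneity is
measured by a generalised Cochran statistic

    Q_a = sum_i a_i (y_i - yhat_i)^2 = y' B y,
    B = A - A X (X' A X)^{-1} X' A,   A = diag(a_i),

for an arbitrary vector of fixed positive weights ``a_i``; the fitted values
come from the weighted least-squares fit with the same weights.  Equating
``Q_a`` to its model expectation ``tr(B Delta) + tau2 tr(B)`` yields a
moment estimator of ``tau2`` that reduces to the DerSimonian-Laird
estimator for inverse-variance weights and no covariates.

The exact first two moments of ``Q_a`` under the model are linear /
quadratic in ``tau2`` with coefficients given by traces of products of
``B`` and ``Delta = diag(sigma2_i)``; those traces are precomputed once in
:class:`QuadraticCore` and drive every interval method in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, SingularDesignError

__all__ = [
    "MetaDataset",
    "WeightScheme",
    "QuadraticCore",
    "TauEstimate",
    "VarCoefficients",
    "build_quadratic_core",
    "compute_qa",
    "qa_moments",
    "variance_coefficients",
    "tau2_moment_estimate",
    "dersimonian_laird",
    "RandomEffectsMeta",
    "MetaResults",
]

#: relative condition-number threshold beyond which a design is declared singular
_COND_MAX = 1e12
#: relative tolerance for the projection identity B X = 0
_BX_RTOL = 1e-8
#: relative tolerance for clamping the variance-polynomial discriminant to zero
_DISC_RTOL = 1e-10


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaDataset:
    """Per-study effect estimates with known within-study variances.

    Parameters
    ----------
    y : (n,) array
        Study effect estimates (e.g. log odds ratios).
    sigma2 : (n,) array
        Within-study variances, strictly positive, treated as fixed.
    X : (n, p) array, optional
        Design matrix.  Defaults to a single all-ones column (plain
        meta-analysis).  Must have full column rank with ``n > p``.
    labels : sequence of str, optional
        Study labels, for reporting only.
    """

    y: np.ndarray
    sigma2: np.ndarray
    X: np.ndarray = None  # type: ignore[assignment]
    labels: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        if self.X is None:
            X = np.ones((y.size, 1))
        else:
            X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if X.shape[0] != y.size and X.shape[1] == y.size:
                X = X.T
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "X", X)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
        if y.size != sigma2.size or X.shape[0] != y.size:
            raise ValueError(
                f"inconsistent sizes: y has {y.size}, sigma2 has {sigma2.size}, "
                f"X has {X.shape[0]} rows"
            )
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(sigma2)):
            raise ValueError("y and sigma2 must be finite")
        if np.any(sigma2 <= 0):
            raise ValueError("all within-study variances must be strictly positive")
        if y.size <= X.shape[1]:
            raise ValueError(
                f"need more studies than design columns (n={y.size}, p={X.shape[1]})"
            )

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class WeightScheme:
    """Fixed positive weights a_i used for both the pooled fit and Q_a.

    The weights are regarded as known constants even when derived from the
    within-study variances; this is the standard approximation under which
    the moments of Q_a are exact.
    """

    a: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float).ravel()
        object.__setattr__(self, "a", a)
        if np.any(a <= 0) or not np.all(np.isfinite(a)):
            raise ValueError("all weights must be finite and strictly positive")

    @classmethod
    def inverse_variance(cls, sigma2: Sequence[float]) -> "WeightScheme":
        """a_i = 1/sigma2_i, the fixed-effect (DerSimonian-Laird) weights."""
        return cls(1.0 / np.asarray(sigma2, dtype=float), "inverse-variance")

    @classmethod
    def inverse_se(cls, sigma2: Sequence[float]) -> "WeightScheme":
        """a_i = 1/sigma_i, weights spread more evenly across study sizes."""
        return cls(1.0 / np.sqrt(np.asarray(sigma2, dtype=float)), "inverse-SE")

    @classmethod
    def from_label(cls, label: str, sigma2: Sequence[float]) -> "WeightScheme":
        key = label.lower().replace("_", "-")
        if key in ("inverse-variance", "iv"):
            return cls.inverse_variance(sigma2)
        if key in ("inverse-se", "inv-se"):
            return cls.inverse_se(sigma2)
        raise ValueError(f"unknown weight scheme {label!r}")


@dataclass(frozen=True)
class QuadraticCore:
    """The quadratic-form matrix B with the five traces that fix the
    moments of Q_a: tr(B), tr(B Delta), tr(B Delta B Delta), tr(B Delta B)
    and tr(B^2)."""

    B: np.ndarray
    trB: float
    trBD: float
    trBDBD: float
    trBDB: float
    trB2: float
    df: int  # n - p, the rank of B


@dataclass(frozen=True)
class VarCoefficients:
    """Coefficients of Var(tau2_hat) = C0 + C1 tau2 + C2 tau2^2 and the
    discriminant C1^2 - 4 C0 C2 (non-positive; zero exactly when all
    within-study variances are equal)."""

    C0: float
    C1: float
    C2: float
    disc: float


@dataclass(frozen=True)
class TauEstimate:
    """Moment estimate of the between-study variance.

    ``tau2_untruncated`` may be negative and is the quantity the
    variance-stabilised interval is built from; ``tau2`` is clamped at zero
    for reporting.
    """

    tau2_untruncated: float
    q_a: float
    tau2: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "tau2", max(self.tau2_untruncated, 0.0))


# ---------------------------------------------------------------------------
# core computations
# ---------------------------------------------------------------------------

def build_quadratic_core(
    X: np.ndarray, a: np.ndarray, sigma2: np.ndarray
) -> QuadraticCore:
    """Construct B = A - A X (X'AX)^{-1} X'A and its moment traces.

    Uses the factorisation B = S (I - P) S with S = diag(sqrt(a)) and P the
    orthogonal projector onto the column span of S X, obtained from an SVD.
    This is numerically stable and makes B symmetric and positive
    semi-definite by construction; ``X`` is declared singular when its
    weighted condition number exceeds 1e12.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    a = np.asarray(a, dtype=float).ravel()
    sigma2 = np.asarray(sigma2, dtype=float).ravel()
    n, p = X.shape
    if a.size != n or sigma2.size != n:
        raise ValueError("weight / variance vectors must match the design rows")
    if np.any(a <= 0):
        raise ValueError("all weights must be strictly positive")

    s = np.sqrt(a)
    W = s[:, None] * X
    U, sv, _ = np.linalg.svd(W, full_matrices=False)
    if sv[0] == 0 or sv[-1] <= sv[0] / _COND_MAX:
        raise SingularDesignError(
            f"design matrix is singular or near-singular (cond={sv[0] / max(sv[-1], 1e-300):.3g})"
        )
    # B = S (I - U U') S
    P = U @ U.T
    B = np.diag(a) - s[:, None] * P * s[None, :]
    B = 0.5 * (B + B.T)

    BX = B @ X
    scale = np.linalg.norm(B) * np.linalg.norm(X)
    if np.linalg.norm(BX) > _BX_RTOL * max(scale, 1e-300):
        raise ConsistencyError("projection identity B X = 0 failed numerically")

    BD = B * sigma2[None, :]  # B @ diag(sigma2)
    trB = float(np.trace(B))
    trBD = float(np.trace(BD))
    trBDBD = float(np.sum(BD * BD.T))
    trBDB = float(np.sum(BD * B))  # tr(BDB) = sum_ij (BD)_ij B_ji, B symmetric
    trB2 = float(np.sum(B * B))
    return QuadraticCore(
        B=B, trB=trB, trBD=trBD, trBDBD=trBDBD, trBDB=trBDB, trB2=trB2, df=n - p
    )


def compute_qa(data: MetaDataset, weights: WeightScheme):
    """Weighted-least-squares fit and the heterogeneity statistic Q_a.

    Returns ``(q_a, beta_hat, fitted)``.  Q_a is computed as the weighted
    residual sum of squares; the quadratic-form route ``y'By`` agrees to
    relative 1e-10 (checked in the test suite, not re-verified here).
    """
    a = weights.a
    if a.size != data.n:
        raise ValueError("weights must have one entry per study")
    s = np.sqrt(a)
    W = s[:, None] * data.X
    beta, *_ = np.linalg.lstsq(W, s * data.y, rcond=None)
    fitted = data.X @ beta
    resid = data.y - fitted
    q_a = float(np.sum(a * resid**2))
    return q_a, beta, fitted


def qa_moments(core: QuadraticCore, tau2: float) -> tuple[float, float]:
    """Exact mean and variance of Q_a at between-study variance ``tau2``.

    mean = tr(B Delta) + tau2 tr(B);
    var  = 2 tr(BDBD) + 4 tau2 tr(BDB) + 2 tau2^2 tr(B^2).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    mean = core.trBD + core.trB * tau2
    var = 2.0 * core.trBDBD + 4.0 * tau2 * core.trBDB + 2.0 * tau2**2 * core.trB2
    return mean, var


def variance_coefficients(core: QuadraticCore) -> VarCoefficients:
    """Coefficients of the variance polynomial of the untruncated moment
    estimator, Var = C0 + C1 tau2 + C2 tau2^2.

    The discriminant C1^2 - 4 C0 C2 is non-positive by a Cauchy-Schwarz
    argument on the traces, with equality exactly when Delta is a multiple
    of the identity; values within rounding error of zero are clamped so
    the equal-variance case degrades gracefully.
    """
    if core.trB <= 0:
        raise ValueError("tr(B) must be positive")
    t2 = core.trB**2
    C0 = 2.0 * core.trBDBD / t2
    C1 = 4.0 * core.trBDB / t2
    C2 = 2.0 * core.trB2 / t2
    disc = C1**2 - 4.0 * C0 * C2
    tol = _DISC_RTOL * 4.0 * C0 * C2
    if disc > tol:
        raise ConsistencyError(
            f"variance-polynomial discriminant {disc:.3e} > 0 beyond tolerance"
        )
    # snap to the analytic equality case (Delta proportional to I) so the
    # degenerate square root collapses exactly
    if abs(disc) <= tol:
        disc = 0.0
    return VarCoefficients(C0=C0, C1=C1, C2=C2, disc=disc)


def tau2_moment_estimate(q_a: float, core: QuadraticCore) -> TauEstimate:
    """Solve E(Q_a) = q_a for tau2: the moment estimator
    (Q_a - tr(B Delta)) / tr(B), truncated at zero for reporting."""
    if core.trB <= 0:
        raise ValueError("tr(B) must be positive")
    return TauEstimate(tau2_untruncated=(q_a - core.trBD) / core.trB, q_a=q_a)


def dersimonian_laird(y, sigma2) -> float:
    """Classical DerSimonian-Laird estimate (truncated), textbook form.

    Provided as a convenience; identical to the general moment estimator
    with inverse-variance weights and an intercept-only design.
    """
    y = np.asarray(y, float)
    w = 1.0 / np.asarray(sigma2, float)
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(float((q - (y.size - 1)) / denom), 0.0)


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------

class RandomEffectsMeta:
    """Random-effects meta-analysis (or meta-regression) model.

    Parameters
    ----------
    y, sigma2 : array-like
        Study estimates and their known within-study variances.
    X : array-like, optional
        Design matrix; an intercept-only column when omitted.
    weights : str or array-like
        ``"inverse-variance"`` (default), ``"inverse-se"``, or an explicit
        positive weight vector.

    Examples
    --------
    >>> m = RandomEffectsMeta([0.2, -0.1, 0.5], [0.04, 0.09, 0.05])
    >>> res = m.fit()
    >>> res.tau2  # doctest: +SKIP
    """

    def __init__(self, y, sigma2, X=None, weights="inverse-variance"):
        self.data = MetaDataset(y=np.asarray(y, float), sigma2=np.asarray(sigma2, float), X=X)
        if isinstance(weights, str):
            self.weights = WeightScheme.from_label(weights, self.data.sigma2)
        elif isinstance(weights, WeightScheme):
            self.weights = weights
        else:
            self.weights = WeightScheme(np.asarray(weights, float))
        if self.weights.a.size != self.data.n:
            raise ValueError("weights must have one entry per study")
        self.core = build_quadratic_core(self.data.X, self.weights.a, self.data.sigma2)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        effect: str = "estimate",
        se: str | None = "se",
        variance: str | None = None,
        covariates: Sequence[str] = (),
        weights="inverse-variance",
    ) -> "RandomEffectsMeta":
        """Build the model from a tidy per-study table.

        Exactly one of ``se`` / ``variance`` names the uncertainty column.
        An intercept is always included; ``covariates`` name moderator
        columns appended to it.
        """
        if (se is None) == (variance is None):
            raise ValueError("specify exactly one of se= or variance=")
        y = df[effect].to_numpy(float)
        sigma2 = (
            df[se].to_numpy(float) ** 2 if se is not None else df[variance].to_numpy(float)
        )
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates]
        )
        return cls(y, sigma2, X=X, weights=weights)

    def fit(self) -> "MetaResults":
        q_a, beta, fitted = compute_qa(self.data, self.weights)
        est = tau2_moment_estimate(q_a, self.core)
        coeffs = variance_coefficients(self.core)
        return MetaResults(self, q_a=q_a, beta=beta, fitted=fitted, est=est, coeffs=coeffs)


class MetaResults:
    """Fit results: pooled coefficients, Q_a and the moment estimate of the
    between-study variance, with interval methods attached."""

    def __init__(self, model, q_a, beta, fitted, est, coeffs):
        self.model = model
        self.q_a = q_a
        self.beta = beta
        self.fitted = fitted
        self.estimate = est
        self.coeffs = coeffs

    @property
    def tau2(self) -> float:
        """Truncated (reported) moment estimate of the between-study variance."""
        return self.estimate.tau2

    @property
    def tau2_untruncated(self) -> float:
        return self.estimate.tau2_untruncated

    def conf_int_tau2(self, level: float = 0.95, method: str = "vst"):
        """Confidence interval for tau2.

        method : {"vst", "exact", "qprofile"}
            ``vst`` is the closed-form variance-stabilised (arcsinh)
            interval; ``exact`` inverts the weighted-chi-square
            distribution of Q_a; ``qprofile`` profiles the
            inverse-(sigma2+tau2)-weighted Q statistic.
        """
        from .exact import exact_confidence_interval
        from .qprofile import qprofile_confidence_interval
        from .vst import vst_confidence_interval

        if method == "vst":
            return vst_confidence_interval(self.estimate, self.coeffs, level=level)
        if method == "exact":
            return exact_confidence_interval(
                self.q_a, self.model.core, self.model.data.sigma2, level=level
            )
        if method == "qprofile":
            return qprofile_confidence_interval(self.model.data, level=level)
        raise ValueError(f"unknown method {method!r}")

    def summary(self, level: float = 0.95, methods=("vst", "exact", "qprofile")) -> str:
        d = self.model.data
        lines = [
            "Random-effects meta-" + ("regression" if d.p > 1 else "analysis"),
            f"  studies: {d.n}   design columns: {d.p}   weights: {self.model.weights.label}",
            f"  beta_hat: {np.array2string(np.atleast_1d(self.beta), precision=4)}",
            f"  Q_a = {self.q_a:.4f}  (df = {d.n - d.p})",
            f"  tau2 (moment, truncated)   = {self.tau2:.4f}",
            f"  tau2 (untruncated)         = {self.tau2_untruncated:.4f}",
            f"  {int(level*100)}% confidence intervals for tau2:",
        ]
        for m in methods:
            ci = self.conf_int_tau2(level=level, method=m)
            tag = " (degenerate)" if ci.degenerate else ""
            lines.append(f"    {m:>8}: [{ci.lower:.4f}, {ci.upper:.4f}]{tag}")
        return "\n".join(lines)
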