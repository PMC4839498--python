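"""Variance-stabilised (arcsinh) confidence interval for the
between-study variance.

The untruncated moment estimator ``t = (Q_a - tr(B Delta))/tr(B)`` is
unbiased for ``tau2`` with variance ``g(tau2) = C0 + C1 tau2 + C2 tau2^2``.
The variance-stabilising transformation

    f(x) = \\int^x g(u)^{-1/2} du
         = C2^{-1/2} log( 2 C2 x + C1 + 2 sqrt(C2) sqrt(g(x)) )

turns ``t`` into an approximately standard-normal pivot, so an equal-tailed
100(1-alpha)% interval is ``[f^{-1}(f(t) - z), f^{-1}(f(t) + z)]`` with
``z`` the upper alpha/2 normal quantile.  Because the discriminant
``C1^2 - 4 C0 C2`` is non-positive, ``f`` is defined and increasing on the
whole range the estimator can reach and its inverse is available in closed
form; no iteration is ever needed.  Negative bounds are truncated to zero;
when both bounds are negative the interval is reported as the degenerate
[0, 0] with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import TauEstimate, VarCoefficients

__all__ = ["ConfInterval", "vst_transform", "vst_inverse", "vst_confidence_interval"]


@dataclass(frozen=True)
class ConfInterval:
    """A (possibly truncated) confidence interval for tau2."""

    lower: float
    upper: float
    level: float
    method: str
    z: float = field(default=None)  # type: ignore[assignment]
    lower_truncated: bool = False
    upper_truncated: bool = False
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")
        if self.z is None:
            object.__setattr__(self, "z", float(stats.norm.ppf(0.5 + self.level / 2)))
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "method": self.method,
            "lower_truncated": self.lower_truncated,
            "upper_truncated": self.upper_truncated,
            "degenerate": self.degenerate,
        }


def vst_transform(x, coeffs: VarCoefficients):
    """f(x) = C2^{-1/2} log(2 C2 x + C1 + 2 sqrt(C2 (C2 x^2 + C1 x + C0))).

    Accepts scalars or arrays.  Raises ``ValueError`` when the argument of
    the logarithm is not positive, which can only happen at or beyond the
    lower edge ``-tr(B Delta)/tr(B)`` of the estimator's range when the
    discriminant is zero (all within-study variances equal).
    """
    C0, C1, C2 = coeffs.C0, coeffs.C1, coeffs.C2
    x = np.asarray(x, dtype=float)
    g = C0 + C1 * x + C2 * x**2
    if np.any(g < 0):
        raise ValueError("variance polynomial negative: x outside the feasible range")
    arg = 2.0 * C2 * x + C1 + 2.0 * np.sqrt(C2) * np.sqrt(g)
    if np.any(arg <= 0):
        raise ValueError("log argument non-positive: x outside the domain of f")
    out = np.log(arg) / np.sqrt(C2)
    return float(out) if out.ndim == 0 else out


def vst_inverse(y, coeffs: VarCoefficients):
    """Closed-form inverse of :func:`vst_transform`:

    f^{-1}(y) = [exp(sqrt(C2) y) - 2 C1 + (C1^2 - 4 C0 C2) exp(-sqrt(C2) y)] / (4 C2).

    Total and increasing in ``y`` (the discriminant is non-positive).
    """
    C1, C2 = coeffs.C1, coeffs.C2
    y = np.asarray(y, dtype=float)
    e = np.exp(np.sqrt(C2) * y)
    out = (e - 2.0 * C1 + coeffs.disc / e) / (4.0 * C2)
    return float(out) if out.ndim == 0 else out


def vst_confidence_interval(
    est: TauEstimate, coeffs: VarCoefficients, level: float = 0.95
) -> ConfInterval:
    """Equal-tailed variance-stabilised interval for tau2.

    Built from the *untruncated* estimate; the reported bounds are clamped
    at zero, so the truncated point estimate always lies inside.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2))
    centre = vst_transform(est.tau2_untruncated, coeffs)
    lo = vst_inverse(centre - z, coeffs)
    hi = vst_inverse(centre + z, coeffs)
    degenerate = hi < 0
    return ConfInterval(
        lower=max(lo, 0.0),
        upper=max(hi, 0.0),
        level=level,
        method="vst",
        z=z,
        lower_truncated=lo < 0,
        upper_truncated=hi < 0,
        degenerate=degenerate,
    )
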