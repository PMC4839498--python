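"""Q-profile confidence interval for the between-study variance.

The profiled statistic re-weights the generalised Q with the
tau2-dependent weights 1/(sigma2_i + tau2), refitting the weighted
least-squares coefficients at every candidate tau2:

    Q(tau2) = sum_i (y_i - yhat_i(tau2))^2 / (sigma2_i + tau2).

At the true tau2 this is an exact chi-square(n - p) pivot under the
random-effects model, and it is strictly decreasing in tau2, so the
equal-tailed interval bounds are the roots of Q(tau2) equal to the upper
and lower alpha/2 chi-square quantiles.  Bounds with no non-negative root
are truncated to zero; if even Q(0) is below the lower quantile the
interval degenerates to [0, 0].
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .exceptions import ConvergenceError
from .model import MetaDataset, WeightScheme, compute_qa
from .vst import ConfInterval

__all__ = ["profile_q", "qprofile_confidence_interval"]

_ROOT_XTOL = 1e-8


def profile_q(data: MetaDataset, tau2: float) -> float:
    """Generalised Q at weights 1/(sigma2_i + tau2), coefficients refit."""
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    w = WeightScheme(1.0 / (data.sigma2 + tau2))
    q, _, _ = compute_qa(data, w)
    return q


def qprofile_confidence_interval(data: MetaDataset, level: float = 0.95) -> ConfInterval:
    """Equal-tailed Q-profile interval against chi-square(n - p) quantiles."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    df = data.n - data.p
    q_hi = stats.chi2.ppf(1.0 - alpha / 2, df)  # defines the lower bound
    q_lo = stats.chi2.ppf(alpha / 2, df)  # defines the upper bound
    q0 = profile_q(data, 0.0)

    def solve(target: float) -> float | None:
        if q0 <= target:
            return None
        hi = max(4.0 * (q0 / df + float(np.max(data.sigma2))), 1e-6)
        for _ in range(200):
            if profile_q(data, hi) < target:
                break
            hi *= 2.0
        else:
            raise ConvergenceError("failed to bracket the Q-profile bound")
        return float(
            optimize.brentq(lambda t: profile_q(data, t) - target, 0.0, hi, xtol=_ROOT_XTOL)
        )

    upper = solve(q_lo)
    if upper is None:
        return ConfInterval(
            lower=0.0, upper=0.0, level=level, method="qprofile",
            lower_truncated=True, upper_truncated=True, degenerate=True,
        )
    lower = solve(q_hi)
    return ConfInterval(
        lower=lower if lower is not None else 0.0,
        upper=upper,
        level=level,
        method="qprofile",
        lower_truncated=lower is None,
        upper_truncated=False,
    )
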