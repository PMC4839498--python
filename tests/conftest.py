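import json
import subprocess

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150819)


def random_meta_dataset(rng, n=8, p=1, tau2=0.1):
    """A random full-rank meta-regression dataset drawn from the model."""
    sigma2 = rng.uniform(0.02, 0.6, n)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    beta = rng.standard_normal(p)
    y = X @ beta + rng.standard_normal(n) * np.sqrt(sigma2 + tau2)
    return y, sigma2, X


def run_metafor(y, v, method="DL"):
    """Independent oracle: DL estimate and Q-profile CI from R metafor."""
    script = f"""
suppressMessages(library(metafor))
yi <- c({','.join(map(repr, y))})
vi <- c({','.join(map(repr, v))})
fit <- rma(yi, vi, method="{method}")
ci <- confint(fit)
cat(jsonlite::toJSON(list(tau2=fit$tau2,
    lo=ci$random["tau^2","ci.lb"], hi=ci$random["tau^2","ci.ub"]),
    auto_unbox=TRUE, digits=12))
"""
    out = subprocess.run(
        ["Rscript", "--vanilla", "-e", script],
        capture_output=True, text=True, timeout=120, check=True,
    )
    return json.loads(out.stdout.strip())
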