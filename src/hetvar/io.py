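"""Reading and writing per-study tables, and fixture generation.

Meta-analytic datasets are tiny tables, so the only on-disk format is
delimited text (comma or tab, sniffed) with a header.  Required columns:
a study label, the effect estimate, and exactly one of a standard-error
or a variance column; any remaining numeric columns are treated as
moderators when requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MetaDataset
from .simulation import brockwell_gordon_variances

__all__ = ["read_dataset", "write_dataset", "FixtureSpec", "generate_fixture"]

_STUDY_NAMES = ("study", "label", "id")
_EFFECT_NAMES = ("estimate", "effect", "yi", "y")
_SE_NAMES = ("se", "sei", "stderr", "standard_error")
_VAR_NAMES = ("variance", "vi", "var", "v")


def _find_column(columns, candidates):
    hits = [c for c in columns if c.lower() in candidates]
    return hits[0] if len(hits) == 1 else None


def read_dataset(
    path, se_column: str | None = None, variance_column: str | None = None,
    covariates: Sequence[str] = (),
) -> MetaDataset:
    """Read a delimited per-study table into a :class:`MetaDataset`.

    Column roles are found by conventional names (study/label, estimate/
    effect/yi, se/sei, variance/vi) unless given explicitly.  Standard
    errors are squared to variances; a variance column is used as-is.
    An intercept column is always included; ``covariates`` name moderator
    columns appended to it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]

    if se_column is None and variance_column is None:
        se_column = _find_column(df.columns, _SE_NAMES)
        variance_column = _find_column(df.columns, _VAR_NAMES)
        if (se_column is None) == (variance_column is None):
            raise ValueError(
                f"{path.name}: could not identify exactly one SE or variance column "
                f"among {list(df.columns)}; pass se_column= or variance_column="
            )
    if se_column is not None and variance_column is not None:
        raise ValueError("give either an SE column or a variance column, not both")

    effect_column = _find_column(df.columns, _EFFECT_NAMES)
    if effect_column is None:
        raise ValueError(f"{path.name}: no effect-estimate column found")
    study_column = _find_column(df.columns, _STUDY_NAMES)
    labels = df[study_column].astype(str).tolist() if study_column else None
    if labels is not None and len(set(labels)) != len(labels):
        raise ValueError(f"{path.name}: duplicate study labels")

    unc_column = se_column if se_column is not None else variance_column
    for col in (effect_column, unc_column, *covariates):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path.name}: non-numeric or missing value in column {col!r}, row {row}"
            )
    y = df[effect_column].to_numpy(float)
    if se_column is not None:
        se = df[se_column].to_numpy(float)
        if np.any(se <= 0):
            row = int(np.argmax(se <= 0))
            raise ValueError(f"{path.name}: non-positive SE in row {row}")
        sigma2 = se**2
    else:
        sigma2 = df[variance_column].to_numpy(float)
        if np.any(sigma2 <= 0):
            row = int(np.argmax(sigma2 <= 0))
            raise ValueError(f"{path.name}: non-positive variance in row {row}")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates])
    return MetaDataset(y=y, sigma2=sigma2, X=X, labels=labels)


def write_dataset(data: MetaDataset, path, sep: str = "\t") -> None:
    """Write a :class:`MetaDataset` as delimited text (variance column)."""
    cols = {
        "study": list(data.labels) if data.labels else [f"s{i+1}" for i in range(data.n)],
        "estimate": data.y,
        "variance": data.sigma2,
    }
    for j in range(1, data.p):
        cols[f"x{j}"] = data.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic dataset drawn from the random-effects model."""

    n: int
    tau2: float = 0.0
    beta: tuple = (0.0,)
    sigma2: tuple | str = "brockwell-gordon"
    n_covariates: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least two studies")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        object.__setattr__(self, "beta", tuple(np.atleast_1d(self.beta).astype(float)))
        if len(self.beta) != self.n_covariates + 1:
            raise ValueError("beta must have one entry per design column (incl. intercept)")


def generate_fixture(spec: FixtureSpec):
    """Draw a dataset Y ~ N(X beta, diag(sigma2) + tau2 I).

    Returns ``(dataset, truth)`` where ``truth`` records the generating
    tau2 and beta for parameter-recovery tests.  Deterministic in the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if isinstance(spec.sigma2, str):
        if spec.sigma2 != "brockwell-gordon":
            raise ValueError(f"unknown sigma2 source {spec.sigma2!r}")
        sigma2 = brockwell_gordon_variances(spec.n)
    else:
        sigma2 = np.asarray(spec.sigma2, dtype=float)
        if sigma2.size != spec.n:
            raise ValueError("sigma2 must have one entry per study")
    if spec.n_covariates:
        X = np.column_stack(
            [np.ones(spec.n), rng.standard_normal((spec.n, spec.n_covariates))]
        )
    else:
        X = np.ones((spec.n, 1))
    mean = X @ np.asarray(spec.beta)
    y = mean + rng.standard_normal(spec.n) * np.sqrt(sigma2 + spec.tau2)
    data = MetaDataset(y=y, sigma2=sigma2, X=X)
    truth = {"tau2": spec.tau2, "beta": spec.beta, "sigma2": tuple(sigma2)}
    return data, truth
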