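"""MLR model fitting, random train/test splits, and all-subset search.

The modelling engine of the package is ordinary least squares on a small
descriptor subset (classically four variables for ~40-50 compounds).
Diagnostics follow the conventions of the QSAR validation literature:

* ``R2 = 1 - RSS/TSS`` with TSS about the training mean,
* ``R2_adj = 1 - (1 - R2)(n - 1)/(n - p - 1)``,
* ``RMSE_tr = sqrt(RSS / n)`` (divisor n, the fitting-error convention of
  QSAR validation software; the n - p - 1 variant is available via
  ``rmse_ddof``),
* ``F = [(TSS - RSS)/p] / [RSS/(n - p - 1)]``,
* standardized coefficients ``beta_j = b_j * sd(x_j) / sd(y)``.

:func:`all_subset_search` enumerates every descriptor subset of a fixed
size, scoring each by training R2 and leave-one-out Q2; the exhaustive
enumeration is exact (count equals the binomial coefficient).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Dataset, DescriptorMatrix, ResponseVector, SplitSpec
from .exceptions import (
    InsufficientDataError,
    ParameterError,
    SchemaError,
    SingularDesignError,
    SubsetCapError,
)

__all__ = [
    "FittedModel",
    "SubsetScore",
    "SubsetSearchResult",
    "fit_mlr",
    "predict",
    "random_split",
    "all_subset_search",
]

#: relative singular-value cutoff declaring a design rank-deficient
RANK_RTOL = 1e-10


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expected DescriptorMatrix or DataFrame")


def _as_series(y) -> pd.Series:
    if isinstance(y, ResponseVector):
        return y.series
    if isinstance(y, pd.Series):
        return y
    raise TypeError("expected ResponseVector or Series")


def _align(X, y) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Inner-join descriptors and response on stringified compound IDs."""
    frame = _as_frame(X).copy()
    frame.index = frame.index.astype(str)
    ys = _as_series(y).copy()
    ys.index = ys.index.astype(str)
    ids = [i for i in frame.index if i in set(ys.index)]
    return frame.loc[ids], ys.loc[ids].to_numpy(float), ids


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns expressible (numerically) as combinations of the others."""
    out = []
    full_rank = np.linalg.matrix_rank(X, tol=RANK_RTOL * _spectral_norm(X))
    for j, name in enumerate(names):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest, tol=RANK_RTOL * _spectral_norm(rest)) == full_rank:
            out.append(name)
    return out


def _spectral_norm(X: np.ndarray) -> float:
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[0]) if len(s) else 0.0


def _check_rank(Xa: np.ndarray, names: list[str]) -> None:
    s = np.linalg.svd(Xa, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        dep = _dependent_columns(Xa, ["(intercept)"] + names)
        raise SingularDesignError(
            f"rank-deficient design; linearly dependent columns: {dep}"
        )


@dataclass
class FittedModel:
    """An OLS model on a named descriptor subset, with training diagnostics."""

    descriptor_names: list[str]
    intercept: float
    coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    n_tr: int
    R2: float
    R2_adj: float
    RMSE_tr: float
    F: float
    endpoint: str = "response"
    train_ids: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def equation(self) -> str:
        terms = " ".join(
            f"{c:+.4f}*{n}" for c, n in zip(self.coefficients, self.descriptor_names)
        )
        return f"{self.endpoint} = {self.intercept:.4f} {terms}"

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "descriptor_names": self.descriptor_names,
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "standardized_coefficients": list(
                map(float, self.standardized_coefficients)
            ),
            "n_tr": self.n_tr,
            "R2": self.R2,
            "R2_adj": self.R2_adj,
            "RMSE_tr": self.RMSE_tr,
            "F": self.F,
            "train_ids": self.train_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], float),
            standardized_coefficients=np.asarray(
                d["standardized_coefficients"], float
            ),
            n_tr=int(d["n_tr"]),
            R2=float(d["R2"]),
            R2_adj=float(d["R2_adj"]),
            RMSE_tr=float(d["RMSE_tr"]),
            F=float(d["F"]),
            endpoint=d.get("endpoint", "response"),
            train_ids=list(d.get("train_ids", [])),
        )


def fit_mlr(X_sub, y, rmse_ddof: int = 0) -> FittedModel:
    """Fit ordinary least squares of the response on the given descriptors.

    Parameters
    ----------
    X_sub
        Descriptor columns (DescriptorMatrix or DataFrame), no missing
        values, aligned with ``y`` on compound IDs.
    y
        ResponseVector or Series.
    rmse_ddof
        0 (default): RMSE_tr = sqrt(RSS/n); p + 1: the unbiased-variance
        style divisor n - p - 1.
    """
    frame, yv, ids = _align(X_sub, y)
    Xv = frame.to_numpy(float)
    n, p = Xv.shape
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise SchemaError("fit_mlr requires complete (non-missing) data")
    if n <= p + 1:
        raise InsufficientDataError(
            f"need n > p + 1 training compounds, got n={n} for p={p}"
        )
    names = list(frame.columns)
    Xa = np.column_stack([np.ones(n), Xv])
    _check_rank(Xa, names)

    res = sm.OLS(yv, Xa).fit()
    coefs = res.params[1:]
    rss = float(res.ssr)
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    divisor = n - rmse_ddof if rmse_ddof else n
    rmse = math.sqrt(rss / divisor)
    f_stat = ((tss - rss) / p) / (rss / (n - p - 1))
    sy = float(np.std(yv, ddof=1))
    sx = np.std(Xv, axis=0, ddof=1)
    beta = coefs * sx / sy
    return FittedModel(
        descriptor_names=names,
        intercept=float(res.params[0]),
        coefficients=np.asarray(coefs, float),
        standardized_coefficients=np.asarray(beta, float),
        n_tr=n,
        R2=r2,
        R2_adj=r2_adj,
        RMSE_tr=rmse,
        F=f_stat,
        endpoint=getattr(y, "endpoint", None) or _as_series(y).name or "response",
        train_ids=ids,
    )


def predict(model: FittedModel, X_new) -> np.ndarray:
    """Predicted responses for new compounds (unit-consistent with y)."""
    frame = _as_frame(X_new)
    missing = [n for n in model.descriptor_names if n not in frame.columns]
    if missing:
        raise SchemaError(f"missing descriptor columns: {missing}")
    Xv = frame[model.descriptor_names].to_numpy(float)
    return model.intercept + Xv @ model.coefficients


def random_split(
    dataset: Dataset, test_fraction: float = 0.2, seed: int = 0
) -> SplitSpec:
    """Uniform random train/test assignment, reproducible under ``seed``.

    The test-set size is round(n * test_fraction); both sets must end up
    non-empty.
    """
    if not 0 < test_fraction < 1:
        raise ParameterError(f"test_fraction must be in (0, 1), got {test_fraction}")
    ids = dataset.compound_ids
    n = len(ids)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 compounds to split, got {n}")
    n_test = int(round(n * test_fraction))
    if n_test in (0, n):
        raise ParameterError(
            f"test_fraction {test_fraction} yields a {n_test}-compound test set"
        )
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    return SplitSpec(
        {cid: ("test" if i in test_idx else "train") for i, cid in enumerate(ids)}
    )


@dataclass
class SubsetScore:
    descriptors: tuple[str, ...]
    R2: float
    Q2_LOO: float


@dataclass
class SubsetSearchResult:
    ranked: list[SubsetScore]
    k_sub: int
    n_evaluated: int
    sort_key: str

    @property
    def best(self) -> SubsetScore:
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptors": [",".join(s.descriptors) for s in self.ranked],
                "R2": [s.R2 for s in self.ranked],
                "Q2_LOO": [s.Q2_LOO for s in self.ranked],
            }
        )


def _score_subset(Xa: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
    """(R2, Q2_LOO) for one intercept-augmented design, or NaNs if singular.

    Uses the closed-form leave-one-out identity e_i / (1 - h_ii) so each
    subset costs a single least-squares solve.
    """
    n = len(yv)
    gram = Xa.T @ Xa
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    s = np.linalg.svd(Xa, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        return np.nan, np.nan
    coef = ginv @ (Xa.T @ yv)
    resid = yv - Xa @ coef
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss
    h = np.einsum("ij,jk,ik->i", Xa, ginv, Xa)
    press = float(((resid / (1.0 - h)) ** 2).sum())
    return r2, 1.0 - press / tss


def all_subset_search(
    X,
    y,
    k_sub: int = 4,
    sort_key: str = "Q2_LOO",
    cap: int = 1_000_000,
) -> SubsetSearchResult:
    """Exhaustively score every ``k_sub``-descriptor OLS model.

    Every subset of the candidate descriptors is fitted and scored by
    training R2 and leave-one-out Q2.  The ranking sorts by ``sort_key``
    (default Q2_LOO), breaking ties by the other statistic and then by
    subset name order.  Refuses to enumerate more than ``cap`` subsets.
    """
    if sort_key not in ("R2", "Q2_LOO"):
        raise ParameterError(f"sort_key must be 'R2' or 'Q2_LOO', got {sort_key!r}")
    frame, yv, _ = _align(X, y)
    names = list(frame.columns)
    m = len(names)
    if m < k_sub:
        raise ParameterError(f"{m} candidate descriptors < subset size {k_sub}")
    n_total = math.comb(m, k_sub)
    if n_total > cap:
        raise SubsetCapError(
            f"C({m},{k_sub}) = {n_total} subsets exceeds cap {cap}; "
            "prefilter the descriptor matrix first"
        )
    Xv = frame.to_numpy(float)
    n = len(yv)
    if n <= k_sub + 1:
        raise InsufficientDataError(f"need n > k_sub + 1, got n={n}, k_sub={k_sub}")
    ones = np.ones((n, 1))
    scores: list[SubsetScore] = []
    for combo in itertools.combinations(range(m), k_sub):
        Xa = np.concatenate([ones, Xv[:, combo]], axis=1)
        r2, q2 = _score_subset(Xa, yv)
        scores.append(SubsetScore(tuple(names[j] for j in combo), r2, q2))

    primary = "Q2_LOO" if sort_key == "Q2_LOO" else "R2"
    secondary = "R2" if primary == "Q2_LOO" else "Q2_LOO"

    def key(s: SubsetScore):
        a, b = getattr(s, primary), getattr(s, secondary)
        # NaN-scored (singular) subsets sink to the bottom
        a = -math.inf if math.isnan(a) else a
        b = -math.inf if math.isnan(b) else b
        return (-a, -b, s.descriptors)

    return SubsetSearchResult(
        ranked=sorted(scores, key=key),
        k_sub=k_sub,
        n_evaluated=len(scores),
        sort_key=sort_key,
    )
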