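"""Leverage-based applicability domain (Williams plot data).

A prediction is trusted only for compounds structurally similar to the
training set.  Similarity is measured by the leverage (hat value)

    h_i = x_i^T (X^T X)^(-1) x_i

computed from the intercept-augmented training design X.  The warning
leverage is fixed at ``h* = 3k/n`` where k counts model parameters
(descriptors + intercept by default) and n the training compounds.
Residuals are standardized by the leave-one-out RMSE: training compounds
use their LOO-predicted residual, test compounds their externally
predicted residual.  An outlier is a compound exceeding *both* the
leverage and the |standardized residual| > 2 thresholds (the conjunction
rule); an OR mode is available since Williams-plot practice often treats
either exceedance alone as leaving the domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .exceptions import ParameterError, SingularDesignError
from .modeling import FittedModel, RANK_RTOL, _as_frame, predict
from .validation_internal import loo_cv

__all__ = ["ADResult", "leverages", "warning_leverage", "ad_assess"]


def leverages(X_train, X_query=None) -> np.ndarray:
    """Hat values of query rows w.r.t. an intercept-augmented training design.

    With ``X_query=None`` the training leverages themselves are returned
    (each in [0, 1], summing to the number of parameters).  Query rows
    outside the training space may exceed 1.
    """
    Xtr = _as_frame(X_train) if not isinstance(X_train, np.ndarray) else pd.DataFrame(X_train)
    cols = list(Xtr.columns)
    A = np.column_stack([np.ones(len(Xtr)), Xtr.to_numpy(float)])
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        raise SingularDesignError("singular X^T X in leverage computation")
    ginv = np.linalg.inv(A.T @ A)
    if X_query is None:
        Q = A
    else:
        Xq = _as_frame(X_query) if not isinstance(X_query, np.ndarray) else pd.DataFrame(X_query, columns=cols)
        Q = np.column_stack([np.ones(len(Xq)), Xq[cols].to_numpy(float)])
    return np.einsum("ij,jk,ik->i", Q, ginv, Q)


def warning_leverage(n_params: int, n_train: int) -> float:
    """The warning leverage ``h* = 3 k / n``.

    ``n_params`` counts the model parameters including the intercept
    (descriptors + 1 in the default convention).
    """
    if n_params < 1:
        raise ParameterError("n_params must be >= 1")
    if n_train <= n_params:
        raise ParameterError(
            f"need n_train > n_params, got n_train={n_train}, n_params={n_params}"
        )
    return 3.0 * n_params / n_train


@dataclass
class ADResult:
    """Per-compound Williams-plot table plus the warning leverage."""

    table: pd.DataFrame  # columns: id, set, leverage, std_residual, outlier
    h_star: float
    rmse_cv: float
    rule: str

    @property
    def outlier_ids(self) -> list[str]:
        return self.table.loc[self.table["outlier"], "id"].tolist()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["h_star"] = self.h_star
        out.to_csv(path, index=False)


def ad_assess(
    model: FittedModel,
    dataset: Dataset,
    rule: str = "and",
    residual_threshold: float = 2.0,
    count_intercept: bool = True,
) -> ADResult:
    """Assess the applicability domain of a fitted model over a dataset.

    The dataset must carry the split the model was trained on.  For
    training compounds the standardized residual is the LOO residual over
    RMSE_cv; for test compounds, the prediction residual over the same
    RMSE_cv.  ``rule`` is ``"and"`` (outlier = both thresholds exceeded,
    the default conjunction) or ``"or"`` (either exceedance flags).
    """
    if rule not in ("and", "or"):
        raise ParameterError("rule must be 'and' or 'or'")
    if dataset.split is None:
        raise ParameterError("ad_assess needs a dataset with a train/test split")
    train = dataset.subset("train")
    Xtr = train.descriptors.select(model.descriptor_names).frame
    ytr = train.response.series

    q2, rmse_cv, loo_pred = loo_cv(Xtr, ytr)
    h_tr = leverages(Xtr)
    n_params = model.p + (1 if count_intercept else 0)
    h_star = warning_leverage(n_params, len(Xtr))
    std_tr = (ytr.to_numpy() - loo_pred) / rmse_cv

    rows = [
        pd.DataFrame(
            {
                "id": train.compound_ids,
                "set": "train",
                "leverage": h_tr,
                "std_residual": std_tr,
            }
        )
    ]
    try:
        test = dataset.subset("test")
    except Exception:
        test = None
    if test is not None:
        Xte = test.descriptors.select(model.descriptor_names).frame
        pred = predict(model, Xte)
        h_te = leverages(Xtr, Xte)
        std_te = (test.response.values - pred) / rmse_cv
        rows.append(
            pd.DataFrame(
                {
                    "id": test.compound_ids,
                    "set": "test",
                    "leverage": h_te,
                    "std_residual": std_te,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    high_h = table["leverage"] > h_star
    big_r = table["std_residual"].abs() > residual_threshold
    table["outlier"] = (high_h & big_r) if rule == "and" else (high_h | big_r)
    table["exceeds_leverage"] = high_h
    table["exceeds_residual"] = big_r
    return ADResult(table=table, h_star=h_star, rmse_cv=rmse_cv, rule=rule)
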