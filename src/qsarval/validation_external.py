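"""External predictivity statistics for observed/predicted pairs.

Given a test set never used in fitting, predictive power is summarised by
the three external explained-variance statistics, which differ only in the
reference variance of the denominator:

* ``Q2_F1 = 1 - SS_res / sum_test (y - mean(y_train))^2``
* ``Q2_F2 = 1 - SS_res / sum_test (y - mean(y_test))^2``
* ``Q2_F3 = 1 - [SS_res / n_test] / [sum_train (y - mean(y_train))^2 / n_train]``

plus Lin's concordance correlation coefficient (CCC), the rm2 metrics
(which shrink the squared correlation by its gap to the through-origin
determination coefficient, in both regression directions), and the
Golbraikh-Tropsha through-origin slopes k, k' and determination
coefficients R0^2, R0'^2.

Direction conventions (fixed by reproducing the published reference values
of the bundled benchmark):

* ``k`` is the through-origin slope of observed on predicted,
  ``k' = sum(y yhat)/sum(y^2)`` that of predicted on observed;
* ``R0^2`` is the through-origin determination coefficient with the
  *predicted* values as dependent variable (paired with k'), ``R0'^2``
  with the observed values as dependent (paired with k);
* the unprimed ``rm^2`` uses the observed-on-predicted through-origin fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import PairedPredictions
from .exceptions import UndefinedStatisticError

__all__ = [
    "ExternalValidationReport",
    "q2_f1",
    "q2_f2",
    "q2_f3",
    "ccc",
    "rm2_metrics",
    "golbraikh_tropsha",
    "rmse",
    "r2_pearson",
    "external_report",
]

_EPS = 1e-300


def _obs_pred(pairs: PairedPredictions, n_min: int = 2) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) < n_min:
        raise UndefinedStatisticError(f"statistic needs >= {n_min} pairs")
    return np.asarray(pairs.observed, float), np.asarray(pairs.predicted, float)


def rmse(pairs: PairedPredictions) -> float:
    """Root mean square error of the predictions (divisor n)."""
    y, yh = _obs_pred(pairs, n_min=1)
    return float(np.sqrt(((y - yh) ** 2).mean()))


def r2_pearson(pairs: PairedPredictions) -> float:
    """Squared Pearson correlation of observed vs predicted."""
    y, yh = _obs_pred(pairs)
    if np.ptp(y) == 0 or np.ptp(yh) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    return float(np.corrcoef(y, yh)[0, 1] ** 2)


def q2_f1(test: PairedPredictions, train_mean: float) -> float:
    """External Q2 with the training-set observed mean as reference."""
    y, yh = _obs_pred(test)
    denom = float(((y - train_mean) ** 2).sum())
    if denom <= _EPS:
        raise UndefinedStatisticError(
            "Q2_F1 undefined: test responses all equal the training mean"
        )
    return 1.0 - float(((y - yh) ** 2).sum()) / denom


def q2_f2(test: PairedPredictions) -> float:
    """External Q2 with the test-set observed mean as reference."""
    y, yh = _obs_pred(test)
    denom = float(((y - y.mean()) ** 2).sum())
    if denom <= _EPS:
        raise UndefinedStatisticError("Q2_F2 undefined: constant test responses")
    return 1.0 - float(((y - yh) ** 2).sum()) / denom


def q2_f3(test: PairedPredictions, train: PairedPredictions) -> float:
    """External Q2 comparing test MSE to the training response variance."""
    y, yh = _obs_pred(test)
    ytr = np.asarray(train.observed, float)
    denom = float(((ytr - ytr.mean()) ** 2).sum()) / len(ytr)
    if denom <= _EPS:
        raise UndefinedStatisticError("Q2_F3 undefined: constant training responses")
    return 1.0 - float(((y - yh) ** 2).mean()) / denom


def ccc(pairs: PairedPredictions) -> float:
    """Lin's concordance correlation coefficient.

    ``2 S_xy / (S_xx + S_yy + n (xbar - ybar)^2)``; penalises both scatter
    about the identity line and location/scale shift, so CCC = 1 only for
    exact agreement.
    """
    y, yh = _obs_pred(pairs)
    n = len(y)
    sxy = float(((y - y.mean()) * (yh - yh.mean())).sum())
    denom = (
        float(((y - y.mean()) ** 2).sum())
        + float(((yh - yh.mean()) ** 2).sum())
        + n * (y.mean() - yh.mean()) ** 2
    )
    if denom <= _EPS:
        raise UndefinedStatisticError("CCC undefined: both vectors constant and equal")
    return 2.0 * sxy / denom


def _r0_through_origin(dep: np.ndarray, indep: np.ndarray) -> float:
    """Determination coefficient of the least-squares fit of dep = s*indep."""
    ss_indep = float((indep * indep).sum())
    if ss_indep <= _EPS:
        raise UndefinedStatisticError("through-origin fit undefined: zero regressor")
    s = float((dep * indep).sum()) / ss_indep
    ss_tot = float(((dep - dep.mean()) ** 2).sum())
    if ss_tot <= _EPS:
        raise UndefinedStatisticError("through-origin R0^2 undefined: constant vector")
    return 1.0 - float(((dep - s * indep) ** 2).sum()) / ss_tot


def rm2_metrics(pairs: PairedPredictions, scaled: bool = False) -> tuple[float, float]:
    """The rm2 pair: ``(mean, absolute difference)`` of both directions.

    ``rm2 = r2 * (1 - sqrt(max(0, r2 - r0^2)))`` where r0^2 is the
    through-origin determination coefficient — observed regressed on
    predicted for the unprimed variant, the reverse for the primed one.
    With ``scaled=True`` both vectors are first min-max scaled to [0, 1]
    jointly per vector (the later variant of the metric); default off.
    """
    if len(pairs) < 3:
        raise UndefinedStatisticError("rm2 metrics need >= 3 pairs")
    y, yh = _obs_pred(pairs)
    if scaled:
        def mm(v):
            if np.ptp(v) == 0:
                raise UndefinedStatisticError("cannot min-max scale a constant vector")
            return (v - v.min()) / np.ptp(v)

        y, yh = mm(y), mm(yh)
    if np.ptp(y) == 0 or np.ptp(yh) == 0:
        raise UndefinedStatisticError("rm2 undefined for a constant vector")
    r2 = float(np.corrcoef(y, yh)[0, 1] ** 2)
    r0_sq = _r0_through_origin(y, yh)       # observed on predicted
    r0_sq_rev = _r0_through_origin(yh, y)   # predicted on observed
    rm2 = r2 * (1.0 - np.sqrt(max(0.0, r2 - r0_sq)))
    rm2_rev = r2 * (1.0 - np.sqrt(max(0.0, r2 - r0_sq_rev)))
    return float((rm2 + rm2_rev) / 2.0), float(abs(rm2 - rm2_rev))


def golbraikh_tropsha(
    pairs: PairedPredictions,
) -> tuple[float, float, float, float, float, float]:
    """Golbraikh-Tropsha external-validation quantities.

    Returns ``(k, k_prime, R0_2, R0_prime_2, gt_ratio, gt_ratio_prime)``:
    the two through-origin slopes, the two through-origin determination
    coefficients (see the module docstring for direction conventions), and
    the ratios ``(R2 - R0^2)/R2`` in both directions.
    """
    if len(pairs) < 3:
        raise UndefinedStatisticError("Golbraikh-Tropsha needs >= 3 pairs")
    y, yh = _obs_pred(pairs)
    ss_y, ss_yh = float((y * y).sum()), float((yh * yh).sum())
    if ss_y <= _EPS or ss_yh <= _EPS:
        raise UndefinedStatisticError("zero sum of squares in through-origin slope")
    cross = float((y * yh).sum())
    k = cross / ss_yh
    k_prime = cross / ss_y
    r0_2 = _r0_through_origin(yh, y)        # predicted on observed
    r0_prime_2 = _r0_through_origin(y, yh)  # observed on predicted
    r2 = r2_pearson(pairs)
    gt_ratio = (r2 - r0_2) / r2
    gt_ratio_prime = (r2 - r0_prime_2) / r2
    return k, k_prime, r0_2, r0_prime_2, gt_ratio, gt_ratio_prime


@dataclass
class ExternalValidationReport:
    """Every external statistic for one model, or None with a reason.

    A statistic whose denominator degenerates is reported as None and the
    reason recorded under ``undefined``; nothing is silently omitted.
    """

    n_test: int
    RMSE_ext: Optional[float] = None
    R2_ext: Optional[float] = None
    Q2_F1: Optional[float] = None
    Q2_F2: Optional[float] = None
    Q2_F3: Optional[float] = None
    CCC: Optional[float] = None
    rm2_avg: Optional[float] = None
    rm2_delta: Optional[float] = None
    k: Optional[float] = None
    k_prime: Optional[float] = None
    R0_2: Optional[float] = None
    R0_prime_2: Optional[float] = None
    gt_ratio: Optional[float] = None
    gt_ratio_prime: Optional[float] = None
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_test RMSE_ext R2_ext Q2_F1 Q2_F2 Q2_F3 CCC rm2_avg rm2_delta "
                "k k_prime R0_2 R0_prime_2 gt_ratio gt_ratio_prime"
            ).split()
        }
        d["undefined"] = dict(self.undefined)
        return d


def external_report(
    test: PairedPredictions, train: PairedPredictions
) -> ExternalValidationReport:
    """Compute the full external-validation suite for a test set.

    ``train`` supplies the training observed values needed by Q2_F1 (its
    mean) and Q2_F3 (its variance).  Statistics whose preconditions fail
    are set to None with the reason recorded.
    """
    rep = ExternalValidationReport(n_test=len(test))
    rep.RMSE_ext = rmse(test)
    train_mean = float(np.asarray(train.observed, float).mean())

    def attempt(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UndefinedStatisticError as exc:
            rep.undefined[name] = str(exc)
            return None

    rep.R2_ext = attempt("R2_ext", r2_pearson, test)
    rep.Q2_F1 = attempt("Q2_F1", q2_f1, test, train_mean)
    rep.Q2_F2 = attempt("Q2_F2", q2_f2, test)
    rep.Q2_F3 = attempt("Q2_F3", q2_f3, test, train)
    rep.CCC = attempt("CCC", ccc, test)
    rm = attempt("rm2", rm2_metrics, test)
    if rm is not None:
        rep.rm2_avg, rep.rm2_delta = rm
    gt = attempt("golbraikh_tropsha", golbraikh_tropsha, test)
    if gt is not None:
        (rep.k, rep.k_prime, rep.R0_2, rep.R0_prime_2,
         rep.gt_ratio, rep.gt_ratio_prime) = gt
    return rep
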