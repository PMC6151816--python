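"""Model-acceptance criteria and descriptor sign-change diagnostics.

A model is accepted only when every threshold holds, with strict
inequalities exactly as conventionally stated:

* fit: R2 > 0.7
* internal: Q2_LOO > 0.6, Q2_LMO > 0.6, R2 - Q2_LOO < 0.1
* external: Q2_F1, Q2_F2, Q2_F3 > 0.7, rm2_avg > 0.65, CCC > 0.85
* Golbraikh-Tropsha: (R2_ext - R0^2)/R2_ext < 0.1 in either regression
  direction, and 0.85 <= k <= 1.15 for either slope.

Values within ``BORDERLINE_MARGIN`` of a threshold are annotated as
borderline (published tables contain values printed exactly at a
boundary, e.g. CCC = 0.8500 against "CCC > 0.85"); the verdict itself
stays strict.  Missing statistics make a criterion "not evaluable",
which is not a pass.

The descriptor diagnostics check that each model descriptor keeps a real
relationship with the response across the data split: |r| >= 0.3 to the
response on the complete and training sets, |standardized coefficient|
>= 0.001 on both fits, and no sign change along either chain
sign(r_c) = sign(r_t) = sign(r_e) and sign(r_c) = sign(beta_c) = sign(beta_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .data import Dataset
from .exceptions import ParameterError
from .modeling import fit_mlr
from .prefilter import pearson_or_zero

__all__ = [
    "Criterion",
    "CriteriaVerdict",
    "DescriptorDiagnostic",
    "evaluate_criteria",
    "sign_change_check",
]

BORDERLINE_MARGIN = 0.005


@dataclass
class Criterion:
    name: str
    description: str
    observed: Optional[float]
    passed: Optional[bool]  # None = not evaluable
    borderline: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "observed": self.observed,
            "passed": self.passed,
            "borderline": self.borderline,
        }


@dataclass
class CriteriaVerdict:
    criteria: list[Criterion] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(c.passed is True for c in self.criteria)

    def to_dict(self) -> dict:
        return {
            "criteria": [c.to_dict() for c in self.criteria],
            "overall_pass": self.overall_pass,
        }

    def __getitem__(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)


def _get(source, attr: str) -> Optional[float]:
    if source is None:
        return None
    if isinstance(source, dict):
        v = source.get(attr)
    else:
        v = getattr(source, attr, None)
    return None if v is None else float(v)


def _strict(name, desc, value, test_fn, *thresholds) -> Criterion:
    if value is None or any(t is None for t in thresholds):
        return Criterion(name, desc, value, None)
    passed = bool(test_fn(value))
    borderline = any(abs(value - t) <= BORDERLINE_MARGIN for t in thresholds if isinstance(t, float))
    return Criterion(name, desc, value, passed, borderline)


def evaluate_criteria(fit=None, internal=None, external=None) -> CriteriaVerdict:
    """Evaluate the acceptance thresholds on fit/internal/external reports.

    Each argument may be a report object or a plain mapping of statistic
    names; any may be omitted, in which case its criteria are marked not
    evaluable.  The Golbraikh-Tropsha ratio and slope conditions pass if
    either direction passes.
    """
    v = CriteriaVerdict()
    r2 = _get(fit, "R2")
    q2_loo = _get(internal, "Q2_LOO")
    q2_lmo = _get(internal, "Q2_LMO")
    v.criteria.append(_strict("R2", "R2 > 0.7", r2, lambda x: x > 0.7, 0.7))
    v.criteria.append(
        _strict("Q2_LOO", "Q2_LOO > 0.6", q2_loo, lambda x: x > 0.6, 0.6)
    )
    v.criteria.append(
        _strict("Q2_LMO", "Q2_LMO > 0.6", q2_lmo, lambda x: x > 0.6, 0.6)
    )
    gap = None if (r2 is None or q2_loo is None) else r2 - q2_loo
    v.criteria.append(
        _strict("R2_minus_Q2_LOO", "R2 - Q2_LOO < 0.1", gap, lambda x: x < 0.1, 0.1)
    )
    for stat, thr in (("Q2_F1", 0.7), ("Q2_F2", 0.7), ("Q2_F3", 0.7)):
        v.criteria.append(
            _strict(stat, f"{stat} > {thr}", _get(external, stat),
                    lambda x, t=thr: x > t, thr)
        )
    v.criteria.append(
        _strict("rm2_avg", "mean rm2 > 0.65", _get(external, "rm2_avg"),
                lambda x: x > 0.65, 0.65)
    )
    v.criteria.append(
        _strict("CCC", "CCC > 0.85", _get(external, "CCC"), lambda x: x > 0.85, 0.85)
    )

    # Golbraikh-Tropsha: either direction suffices for each condition
    gt, gtp = _get(external, "gt_ratio"), _get(external, "gt_ratio_prime")
    if gt is None and gtp is None:
        v.criteria.append(Criterion("gt_ratio", "(R2-R0^2)/R2 < 0.1 (either)", None, None))
    else:
        vals = [x for x in (gt, gtp) if x is not None]
        best = min(vals)
        passed = best < 0.1
        v.criteria.append(
            Criterion(
                "gt_ratio",
                "(R2-R0^2)/R2 < 0.1 (either direction)",
                best,
                passed,
                abs(best - 0.1) <= BORDERLINE_MARGIN,
            )
        )
    k, kp = _get(external, "k"), _get(external, "k_prime")
    if k is None and kp is None:
        v.criteria.append(Criterion("k_slope", "0.85 <= k or k' <= 1.15", None, None))
    else:
        ok = any(x is not None and 0.85 <= x <= 1.15 for x in (k, kp))
        near = any(
            x is not None and (abs(x - 0.85) <= BORDERLINE_MARGIN or abs(x - 1.15) <= BORDERLINE_MARGIN)
            for x in (k, kp)
        )
        shown = k if k is not None else kp
        v.criteria.append(
            Criterion("k_slope", "0.85 <= k <= 1.15 or 0.85 <= k' <= 1.15",
                      shown, ok, near)
        )
    return v


@dataclass
class DescriptorDiagnostic:
    """Per-descriptor split-stability diagnostics (one row per descriptor).

    Columns of ``table``: r_c, r_t, r_e (Pearson r to the response on the
    complete/training/test sets), beta_c, beta_t (standardized coefficients
    of the complete-set and training-set fits), the individual condition
    flags, and ``evaluable``.
    """

    table: pd.DataFrame

    @property
    def all_pass(self) -> bool:
        t = self.table
        return bool(t["evaluable"].all() and t["all_conditions"].all())

    def to_dict(self) -> dict:
        return self.table.to_dict(orient="index")


def _sign(x: float) -> int:
    # zero sign fails any sign-equality chain
    return 0 if x == 0 else (1 if x > 0 else -1)


def sign_change_check(
    dataset: Dataset,
    subset: list[str],
    r_min: float = 0.3,
    beta_min: float = 0.001,
) -> DescriptorDiagnostic:
    """Check descriptor realness conditions across the data split.

    Requires a dataset with a split.  Fits the subset on the complete set
    and on the training set, computes the five per-descriptor quantities,
    and evaluates the magnitude and sign-chain conditions.  Correlations
    needing fewer than 3 points (e.g. a 2-compound test set) make the
    descriptor's row not evaluable rather than failing it.
    """
    if dataset.split is None:
        raise ParameterError("sign_change_check needs a dataset with a split")
    train = dataset.subset("train")
    test = dataset.subset("test")
    Xc = dataset.descriptors.select(subset).frame
    yc = dataset.response.series

    fit_c = fit_mlr(Xc, dataset.response)
    fit_t = fit_mlr(train.descriptors.select(subset).frame, train.response)

    rows = {}
    for j, name in enumerate(subset):
        r_c, d1 = pearson_or_zero(Xc[name].to_numpy(), yc.to_numpy())
        r_t, d2 = pearson_or_zero(
            train.descriptors.frame[name].to_numpy(), train.response.values
        )
        r_e, d3 = pearson_or_zero(
            test.descriptors.frame[name].to_numpy(), test.response.values
        )
        beta_c = float(fit_c.standardized_coefficients[j])
        beta_t = float(fit_t.standardized_coefficients[j])
        evaluable = not (d1 or d2 or d3)
        mag_r = abs(r_c) >= r_min and abs(r_t) >= r_min
        mag_beta = abs(beta_c) >= beta_min and abs(beta_t) >= beta_min
        sign_r = _sign(r_c) == _sign(r_t) == _sign(r_e) != 0
        sign_beta = _sign(r_c) == _sign(beta_c) == _sign(beta_t) != 0
        rows[name] = {
            "r_c": r_c, "r_t": r_t, "r_e": r_e,
            "beta_c": beta_c, "beta_t": beta_t,
            "magnitude_r": mag_r, "magnitude_beta": mag_beta,
            "sign_chain_r": sign_r, "sign_chain_beta": sign_beta,
            "all_conditions": mag_r and mag_beta and sign_r and sign_beta,
            "evaluable": evaluable,
        }
    return DescriptorDiagnostic(pd.DataFrame.from_dict(rows, orient="index"))
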