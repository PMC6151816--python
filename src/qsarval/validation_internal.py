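"""Internal validation: leave-one-out, leave-many-out, and Y-scrambling.

LOO uses the exact hat-matrix identity for OLS — the residual of compound i
when it is left out equals ``e_i / (1 - h_ii)`` from the full fit — so the
cross-validation costs one least-squares solve instead of n refits.  LMO
repeatedly holds out a random fraction of compounds (default 30%, 1000
iterations), refits, and averages the per-iteration external Q2.
Y-scrambling refits after randomly permuting the response; a model whose
scrambled-response R2 stays near 0 and Q2 falls below 0 is unlikely to owe
its fit to chance correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InsufficientDataError,
    ParameterError,
    SingularDesignError,
)
from .modeling import RANK_RTOL, _align

__all__ = [
    "InternalValidationReport",
    "loo_cv",
    "lmo_cv",
    "y_scrambling",
    "internal_report",
]


@dataclass
class InternalValidationReport:
    Q2_LOO: float
    RMSE_cv: float
    Q2_LMO: float
    R2_Yscr: float
    Q2_Yscr: float
    lmo_iterations: int
    yscr_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "Q2_LOO": self.Q2_LOO,
            "RMSE_cv": self.RMSE_cv,
            "Q2_LMO": self.Q2_LMO,
            "R2_Yscr": self.R2_Yscr,
            "Q2_Yscr": self.Q2_Yscr,
            "lmo_iterations": self.lmo_iterations,
            "yscr_iterations": self.yscr_iterations,
            "seed": self.seed,
        }


def _aligned(X_sub, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    frame, yv, ids = _align(X_sub, y)
    return frame.to_numpy(float), yv, ids


def _augment(Xv: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(Xv)), Xv])


def _ols(Xa: np.ndarray, yv: np.ndarray, context: str) -> np.ndarray:
    s = np.linalg.svd(Xa, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        raise SingularDesignError(f"singular design during {context}")
    coef, *_ = np.linalg.lstsq(Xa, yv, rcond=None)
    return coef


def loo_cv(X_sub, y) -> tuple[float, float, np.ndarray]:
    """Leave-one-out cross-validation.

    Returns ``(Q2_LOO, RMSE_cv, loo_predictions)`` where
    ``Q2_LOO = 1 - PRESS/TSS`` (TSS about the full training mean) and
    ``RMSE_cv = sqrt(PRESS/n)``.  The i-th prediction is made by a model
    that never saw compound i, via the closed-form hat-matrix identity.
    """
    Xv, yv, _ = _aligned(X_sub, y)
    n, p = Xv.shape
    if n <= p + 2:
        raise InsufficientDataError(f"LOO needs n > p + 2, got n={n}, p={p}")
    Xa = _augment(Xv)
    coef = _ols(Xa, yv, "LOO cross-validation")
    fitted = Xa @ coef
    ginv = np.linalg.inv(Xa.T @ Xa)
    h = np.einsum("ij,jk,ik->i", Xa, ginv, Xa)
    if np.any(h >= 1.0 - 1e-12):
        bad = int(np.argmax(h))
        raise SingularDesignError(
            f"leaving out case index {bad} makes the refit singular (h_ii ~ 1)"
        )
    loo_resid = (yv - fitted) / (1.0 - h)
    loo_pred = yv - loo_resid
    press = float(loo_resid @ loo_resid)
    tss = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - press / tss, float(np.sqrt(press / n)), loo_pred


def lmo_cv(
    X_sub,
    y,
    leave_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int = 0,
    tss_mean: str = "kept",
) -> float:
    """Leave-many-out cross-validation; returns the mean Q2 over iterations.

    Each iteration holds out ``round(n * leave_fraction)`` random compounds,
    refits on the rest, and computes ``1 - PRESS/TSS`` on the held-out set.
    ``tss_mean`` selects the reference mean in TSS: ``"kept"`` (default) uses
    the mean of that iteration's fitting subset; ``"full"`` the overall mean.
    """
    if not 0 < leave_fraction <= 0.5:
        raise ParameterError(f"leave_fraction must be in (0, 0.5], got {leave_fraction}")
    if tss_mean not in ("kept", "full"):
        raise ParameterError("tss_mean must be 'kept' or 'full'")
    Xv, yv, _ = _aligned(X_sub, y)
    n, p = Xv.shape
    n_out = int(round(n * leave_fraction))
    if n_out == 0:
        raise ParameterError(
            f"leave_fraction {leave_fraction} leaves out 0 of {n} compounds"
        )
    if n - n_out <= p + 1:
        raise InsufficientDataError(
            f"kept set of {n - n_out} too small for p={p} descriptors"
        )
    rng = np.random.default_rng(seed)
    full_mean = yv.mean()
    q2s = np.empty(iterations)
    for it in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        keep = np.setdiff1d(np.arange(n), out)
        Xa = _augment(Xv[keep])
        coef = _ols(Xa, yv[keep], f"LMO iteration {it}")
        pred = _augment(Xv[out]) @ coef
        ref = yv[keep].mean() if tss_mean == "kept" else full_mean
        press = float(((yv[out] - pred) ** 2).sum())
        tss = float(((yv[out] - ref) ** 2).sum())
        q2s[it] = 1.0 - press / tss
    return float(q2s.mean())


def y_scrambling(
    X_sub,
    y,
    iterations: int = 300,
    seed: int = 0,
    permutations=None,
) -> tuple[float, float]:
    """Response-permutation test; returns ``(mean R2_Yscr, mean Q2_Yscr)``.

    Each iteration permutes y at random, refits the model, and records the
    training R2 and leave-one-out Q2 of the scrambled fit.  ``permutations``
    may supply an explicit sequence of index arrays (overriding the RNG),
    which is useful for controls.
    """
    Xv, yv, _ = _aligned(X_sub, y)
    n, p = Xv.shape
    if n <= p + 2:
        raise InsufficientDataError(f"Y-scrambling needs n > p + 2, got n={n}")
    Xa = _augment(Xv)
    ginv = np.linalg.inv(Xa.T @ Xa)
    h = np.einsum("ij,jk,ik->i", Xa, ginv, Xa)
    proj = ginv @ Xa.T
    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(iterations)]
    else:
        permutations = [np.asarray(p_, dtype=int) for p_ in permutations]
    r2s, q2s = [], []
    for perm in permutations:
        ys = yv[perm]
        resid = ys - Xa @ (proj @ ys)
        tss = float(((ys - ys.mean()) ** 2).sum())
        r2s.append(1.0 - float(resid @ resid) / tss)
        press = float(((resid / (1.0 - h)) ** 2).sum())
        q2s.append(1.0 - press / tss)
    return float(np.mean(r2s)), float(np.mean(q2s))


def internal_report(
    X_sub,
    y,
    leave_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    yscr_iterations: int = 300,
    seed: int = 0,
) -> InternalValidationReport:
    """Run the full internal-validation battery on one descriptor subset."""
    q2_loo, rmse_cv, _ = loo_cv(X_sub, y)
    q2_lmo = lmo_cv(
        X_sub, y, leave_fraction=leave_fraction, iterations=lmo_iterations, seed=seed
    )
    r2_yscr, q2_yscr = y_scrambling(X_sub, y, iterations=yscr_iterations, seed=seed)
    return InternalValidationReport(
        Q2_LOO=q2_loo,
        RMSE_cv=rmse_cv,
        Q2_LMO=q2_lmo,
        R2_Yscr=r2_yscr,
        Q2_Yscr=q2_yscr,
        lmo_iterations=lmo_iterations,
        yscr_iterations=yscr_iterations,
        seed=seed,
    )
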