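"""Descriptor refinement: the four pre-modelling reduction rules.

Raw descriptor matrices (e.g. Dragon output, thousands of columns) are
reduced before subset search by four sequential rules:

1. drop columns with sample standard deviation below ``sd_min`` (near
   constant);
2. drop columns with at least one missing value;
3. for every pair with absolute Pearson correlation >= ``pair_r_max``,
   drop one member of the pair;
4. drop columns whose absolute Pearson correlation with the response is
   below ``resp_r_min``.

The rules are applied strictly in this order, each on the survivors of the
previous one.  Rule 3 keeps the member with the larger |r| to the response
(ties: the earlier column in input order survives) so the reduction is
deterministic and keeps the more informative variable.

Pearson correlations with fewer than 3 points, or against a constant
vector, are undefined; they are treated as 0 and recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DescriptorMatrix, ResponseVector
from .exceptions import InsufficientDataError

__all__ = ["PrefilterReport", "prefilter_descriptors", "pearson_or_zero"]


def pearson_or_zero(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Pearson r, or (0, degenerate=True) when undefined.

    Undefined means fewer than 3 paired points after NaN removal, or either
    vector constant.
    """
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


@dataclass
class PrefilterReport:
    """Record of every removal and the rule responsible.

    The four removal lists plus ``surviving`` partition the input
    descriptor names.  ``removed_pairwise`` maps each dropped name to the
    retained partner that triggered the drop; ``removed_low_response_corr``
    maps each dropped name to its |r| with the response.
    """

    removed_constant: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_pairwise: dict[str, str] = field(default_factory=dict)
    removed_low_response_corr: dict[str, float] = field(default_factory=dict)
    surviving: list[str] = field(default_factory=list)
    degenerate_correlations: list[str] = field(default_factory=list)
    empty_result: bool = False

    def to_dict(self) -> dict:
        return {
            "removed_constant": self.removed_constant,
            "removed_missing": self.removed_missing,
            "removed_pairwise": self.removed_pairwise,
            "removed_low_response_corr": self.removed_low_response_corr,
            "surviving": self.surviving,
            "degenerate_correlations": self.degenerate_correlations,
            "empty_result": self.empty_result,
        }

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_constant)
            + len(self.removed_missing)
            + len(self.removed_pairwise)
            + len(self.removed_low_response_corr)
        )


def prefilter_descriptors(
    X: DescriptorMatrix,
    y: ResponseVector,
    sd_min: float = 0.0001,
    pair_r_max: float = 0.8,
    resp_r_min: float = 0.3,
) -> tuple[DescriptorMatrix, PrefilterReport]:
    """Apply the four refinement rules to a descriptor matrix.

    Compounds are first inner-joined to the non-missing responses; rules
    operate on that aligned matrix.  Returns the reduced matrix (original
    column order preserved) and a :class:`PrefilterReport`.  Removing every
    column is not an error: the report's ``empty_result`` flag is set.
    """
    yv = y.dropna()
    ids = [i for i in X.compound_ids if i in set(yv.compound_ids)]
    if len(ids) < 3:
        raise InsufficientDataError(
            f"prefiltering needs >= 3 compounds with responses, got {len(ids)}"
        )
    frame = X.frame.loc[ids]
    yarr = yv.series.loc[ids].to_numpy()
    report = PrefilterReport()

    # rule 1: (near-)constant columns, sample SD with ddof=1 on observed cells
    survivors: list[str] = []
    for name in frame.columns:
        col = frame[name].to_numpy()
        obs = col[~np.isnan(col)]
        sd = float(np.std(obs, ddof=1)) if len(obs) > 1 else 0.0
        if sd < sd_min:
            report.removed_constant.append(name)
        else:
            survivors.append(name)

    # rule 2: any missing value
    remaining = []
    for name in survivors:
        if np.isnan(frame[name].to_numpy()).any():
            report.removed_missing.append(name)
        else:
            remaining.append(name)
    survivors = remaining

    # rule 3: pairwise |r| >= pair_r_max; keep the member more correlated
    # with the response, scanning pairs in input order
    resp_r: dict[str, float] = {}
    for name in survivors:
        r, degen = pearson_or_zero(frame[name].to_numpy(), yarr)
        resp_r[name] = r
        if degen:
            report.degenerate_correlations.append(name)
    dropped: set[str] = set()
    for i, a in enumerate(survivors):
        if a in dropped:
            continue
        for b in survivors[i + 1 :]:
            if b in dropped:
                continue
            r_ab, _ = pearson_or_zero(frame[a].to_numpy(), frame[b].to_numpy())
            if abs(r_ab) >= pair_r_max:
                # drop the partner with the smaller |r| to y; ties drop the
                # later column (b)
                if abs(resp_r[a]) < abs(resp_r[b]):
                    report.removed_pairwise[a] = b
                    dropped.add(a)
                    break
                report.removed_pairwise[b] = a
                dropped.add(b)
    survivors = [n for n in survivors if n not in dropped]

    # rule 4: |r| to the response below resp_r_min
    remaining = []
    for name in survivors:
        if abs(resp_r[name]) < resp_r_min:
            report.removed_low_response_corr[name] = abs(resp_r[name])
        else:
            remaining.append(name)
    survivors = remaining

    report.surviving = survivors
    report.empty_result = not survivors
    reduced = DescriptorMatrix(X.frame[survivors]) if survivors else DescriptorMatrix(
        X.frame[[]].astype(float)
    )
    return reduced, report
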