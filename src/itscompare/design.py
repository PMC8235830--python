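"""Segmented-regression design matrix (Huitema–McKean parameterisation).

The model for a single interruption at time ``T_I`` is

    Y_t = b0 + b1*t + b2*D_t + b3*(t - T_I)*D_t + e_t

where ``D_t`` is 0 before the interruption and 1 from ``T_I`` on, so b2
is the immediate level change at the interruption and b3 the change in
slope.  A declared transition window receives its own level indicator
and within-window trend so that b2/b3 still contrast the pre segment
with the post segment while the transition points are absorbed by their
own segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .datasets import TimeSeriesDataset

__all__ = ["SegmentedDesign", "DesignError", "EffectEstimates", "build_design",
           "extract_changes"]

LEVEL_ROLE = "level_change"
SLOPE_ROLE = "slope_change"


class DesignError(ValueError):
    """Raised for rank-deficient or mislabelled designs."""


@dataclass(frozen=True)
class SegmentedDesign:
    """Design matrix with column-role labels.

    ``roles`` maps role name -> column index.  Core roles are
    ``intercept``, ``trend``, ``level_change`` (b2) and ``slope_change``
    (b3); transition designs add ``transition_level`` and
    ``transition_trend``.
    """

    X: np.ndarray
    roles: Dict[str, int]
    interruption_time: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column(self, role: str) -> np.ndarray:
        if role not in self.roles:
            raise DesignError(f"design has no column with role {role!r}")
        return self.X[:, self.roles[role]]


@dataclass(frozen=True)
class EffectEstimates:
    """Level- and slope-change effects mapped from fitted coefficients."""

    level_change: float
    slope_change: float
    level_se: float | None = None
    slope_se: float | None = None
    level_ci: tuple[float, float] | None = None
    slope_ci: tuple[float, float] | None = None
    level_p: float | None = None
    slope_p: float | None = None
    level_df: float | None = None
    slope_df: float | None = None


def build_design(dataset: TimeSeriesDataset) -> SegmentedDesign:
    """Construct the segmented design matrix for one dataset.

    Columns (in order): intercept, trend ``t``, post-interruption level
    indicator ``D_t``, slope-change ``(t - T_I) * D_t`` (zero at ``T_I``
    itself), and — when the dataset declares a transition window — a
    transition level indicator and a within-transition trend starting at
    1 on the first transition point.

    Raises
    ------
    DesignError
        If the resulting matrix is rank deficient; the message names the
        offending (linearly dependent) column role.
    """
    t = dataset.t.astype(float)
    ti = dataset.interruption_time
    d = (dataset.t >= ti).astype(float)
    slope = np.where(dataset.t > ti, t - ti, 0.0)

    cols = [np.ones_like(t), t, d, slope]
    roles = {"intercept": 0, "trend": 1, LEVEL_ROLE: 2, SLOPE_ROLE: 3}

    if dataset.transition is not None:
        a, b = dataset.transition
        in_trans = (dataset.t >= a) & (dataset.t <= b)
        trans_level = in_trans.astype(float)
        trans_trend = np.where(in_trans, t - (a - 1), 0.0)
        cols += [trans_level, trans_trend]
        roles["transition_level"] = 4
        roles["transition_trend"] = 5

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column by greedy rank growth
        offending = "unknown"
        acc = np.empty((X.shape[0], 0))
        for role, idx in sorted(roles.items(), key=lambda kv: kv[1]):
            cand = np.column_stack([acc, X[:, idx]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                offending = role
                break
            acc = cand
        raise DesignError(
            f"{dataset.series_id}: design matrix is rank deficient "
            f"(rank {rank} < {X.shape[1]}); offending column: {offending}"
        )
    return SegmentedDesign(X=X, roles=dict(roles), interruption_time=ti)


def extract_changes(coefficients: np.ndarray, design: SegmentedDesign) -> EffectEstimates:
    """Map a fitted coefficient vector to level/slope-change point values.

    Lookup is by role label, so transition columns (and any column
    reordering recorded in ``design.roles``) are transparently ignored.
    """
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (design.p,):
        raise DesignError(
            f"coefficient vector of length {beta.shape} does not conform to "
            f"{design.p}-column design"
        )
    for role in (LEVEL_ROLE, SLOPE_ROLE):
        if role not in design.roles:
            raise DesignError(f"design is missing required role {role!r}")
    return EffectEstimates(
        level_change=float(beta[design.roles[LEVEL_ROLE]]),
        slope_change=float(beta[design.roles[SLOPE_ROLE]]),
    )
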