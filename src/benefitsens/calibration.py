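"""Translating an interpretable risk-difference bound into a delta_xy grid.

Positing a grid for delta_xy directly requires reasoning on the logit scale.
A more interpretable route is to bound

    A_x = max_Z | p{Y(x)=1 | Z, Y=1, X=1-x} - p{Y(x)=1 | Z, Y=0, X=1-x} |,

the largest conditional risk difference in the counterfactual outcome between
factual responders and non-responders of the opposite arm.  Conditional
independence of the potential outcomes given Z forces A_x = 0.  A posited
bound Ã_x implies |expit(alpha_xy) - expit(beta_xy)| <= Ã_x and hence the
delta grid

    delta_xy <= logit{Ã_x + expit(beta_xy)} - beta_xy      (if Ã_x + expit(beta_xy) < 1)
    delta_xy >= logit{expit(beta_xy) - Ã_x} - beta_xy      (if expit(beta_xy) - Ã_x > 0)

When a side condition fails the corresponding endpoint is replaced by a
±``fallback`` sentinel (default 5 log-odds units) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._guards import expit, logit
from .cells import CellIndex

__all__ = ["CalibrationSpec", "DeltaGrid", "delta_grid_from_A", "A_from_full_table"]


@dataclass(frozen=True)
class CalibrationSpec:
    """A posited bound on the absolute conditional risk difference.

    ``A`` may be a single magnitude in [0, 1] or an ``(A_lo, A_hi)`` pair for
    asymmetric bounds (the lower endpoint uses A_lo, the upper A_hi).
    ``fallback`` is the sentinel magnitude (log-odds units) substituted when a
    limit cannot be formed.
    """

    cell: CellIndex
    A: float | tuple[float, float]
    fallback: float = 5.0

    def __post_init__(self):
        object.__setattr__(self, "cell", CellIndex.of(self.cell))
        lo, hi = self.a_pair
        for v, name in ((lo, "A_lo"), (hi, "A_hi")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.fallback > 0:
            raise ValueError(f"fallback must be positive, got {self.fallback}")

    @property
    def a_pair(self) -> tuple[float, float]:
        if isinstance(self.A, tuple):
            return float(self.A[0]), float(self.A[1])
        return float(self.A), float(self.A)


@dataclass(frozen=True)
class DeltaGrid:
    """A delta_xy interval with flags recording any fallback endpoints."""

    cell: CellIndex
    lower: float
    upper: float
    lower_fallback: bool = False
    upper_fallback: bool = False

    @property
    def flags(self) -> list[str]:
        out = []
        if self.lower_fallback:
            out.append("lower_fallback")
        if self.upper_fallback:
            out.append("upper_fallback")
        return out

    def contains(self, delta: float) -> bool:
        return self.lower <= delta <= self.upper

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x": self.cell.x,
                    "y": self.cell.y,
                    "delta_lower": self.lower,
                    "delta_upper": self.upper,
                    "lower_fallback": self.lower_fallback,
                    "upper_fallback": self.upper_fallback,
                }
            ]
        )


def delta_grid_from_A(spec: CalibrationSpec, beta_xy: float) -> DeltaGrid:
    """The delta_xy grid implied by the posited risk-difference bound."""
    if not math.isfinite(beta_xy):
        raise ValueError(f"beta_xy must be finite, got {beta_xy}")
    a_lo, a_hi = spec.a_pair
    e = float(expit(beta_xy))
    up_arg = a_hi + e
    lo_arg = e - a_lo
    if up_arg < 1.0:
        upper, up_fb = float(logit(up_arg)) - beta_xy, False
    else:
        upper, up_fb = spec.fallback, True
    if lo_arg > 0.0:
        lower, lo_fb = float(logit(lo_arg)) - beta_xy, False
    else:
        lower, lo_fb = -spec.fallback, True
    return DeltaGrid(spec.cell, lower, upper, lower_fallback=lo_fb, upper_fallback=up_fb)


def A_from_full_table(table: pd.DataFrame, x: int, arm_col: str = "X") -> float:
    """A_x counted from a complete potential-outcome table (testing oracle).

    The table must list, per subject, the treatment arm and both potential
    outcomes in columns ``Y0`` and ``Y1``.  Conditioning is on the opposite
    arm's factual outcome Y = Y(1-x); A_x is the absolute difference of the
    counterfactual outcome rates between its Y=1 and Y=0 strata.
    """
    if x not in (0, 1):
        raise ValueError(f"arm must be 0 or 1, got {x}")
    for col in (arm_col, "Y0", "Y1"):
        if col not in table.columns:
            raise ValueError(f"table must contain a {col!r} column")
    opp = table[table[arm_col] == 1 - x]
    factual = opp["Y1"] if (1 - x) == 1 else opp["Y0"]
    counterf = opp[f"Y{x}"]
    rates = []
    for level in (1, 0):
        stratum = counterf[factual == level]
        if len(stratum) == 0:
            raise ValueError(
                f"A_{x} undefined: no subjects with X={1 - x}, Y={level}"
            )
        rates.append(float(np.mean(stratum)))
    return abs(rates[0] - rates[1])
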