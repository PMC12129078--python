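"""The four (x, y) sensitivity cells and the marginal parameter delta_xy.

The sensitivity analysis anchors at conditional independence of the potential
outcomes given baseline covariates Z, i.e. Y(0) ⊥ Y(1) | Z.  For a fixed arm
x and factual outcome level y it contrasts

    alpha_xy = logit p{Y(x)=1 | Y=y, X=1-x}          (unidentified)
    beta_xy  = logit E{p(Y=1|X=x, Z) | Y=y, X=1-x}   (identified)

via delta_xy = alpha_xy - beta_xy.  Under conditional independence delta_xy=0
for every cell, regardless of the dimension of Z — delta_xy is a *marginal*
parameter.  Given any one (delta_xy, beta_xy) pair plus the observed outcome
margins, the probability of benefit pi is identified; the four cell-specific
recovery formulas, cell conversions, delta ranges, and the always-existing
variation-independent cell live here.

Not implemented (by design): the probability-scale variant
delta'_xy = expit(alpha_xy) - expit(beta_xy).  It shares the anchoring at 0
but its range (-expit(beta_xy), 1-expit(beta_xy)) depends on the observed
data, which defeats the purpose of a data-free grid.  Likewise, no parameter
can be variation independent of the *full* observed distribution p(X, Y, Z)
(a nonexistence result, not a computable object); the practical consequence —
a posited delta may be incompatible with the data — is surfaced by
:func:`pi_from_delta` via clipping plus an ``IncompatibleValueWarning``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

from ._guards import IncompatibleValueWarning, expit, logit
from .core import JointPotentialDist, MarginalPair, np_bounds

__all__ = [
    "CellIndex",
    "CellParams",
    "ObservedMargins",
    "pi_from_delta",
    "alpha_xy_from_joint",
    "convert_alpha_cell",
    "convert_delta_cell",
    "delta_bounds",
    "variation_independent_cell",
    "ALL_CELLS",
]


class CellIndex(NamedTuple):
    """Sensitivity cell: arm x whose counterfactual is probed, conditioning
    on the factual outcome level y in the opposite arm."""

    x: int
    y: int

    @classmethod
    def of(cls, cell) -> "CellIndex":
        c = cls(*cell)
        if c.x not in (0, 1) or c.y not in (0, 1):
            raise ValueError(f"cell indices must be 0/1, got {tuple(cell)}")
        return c

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"(x={self.x}, y={self.y})"


ALL_CELLS = (CellIndex(1, 0), CellIndex(0, 1), CellIndex(1, 1), CellIndex(0, 0))


@dataclass(frozen=True)
class CellParams:
    """(alpha_xy, beta_xy, delta_xy) triple for one sensitivity cell."""

    cell: CellIndex
    alpha_xy: float
    beta_xy: float

    @property
    def delta_xy(self) -> float:
        return self.alpha_xy - self.beta_xy

    @property
    def risk_difference(self) -> float:
        """Probability-scale contrast Delta_xy = expit(alpha) - expit(beta)."""
        return float(expit(self.alpha_xy) - expit(self.beta_xy))


@dataclass(frozen=True)
class ObservedMargins:
    """Observed outcome probabilities per arm, p(Y=1|X=x).

    Under randomization these coincide with the potential-outcome marginals,
    so the class converts to :class:`MarginalPair`.
    """

    pY1_X1: float
    pY1_X0: float

    def __post_init__(self):
        for v, name in ((self.pY1_X1, "pY1_X1"), (self.pY1_X0, "pY1_X0")):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")

    def p(self, y: int, x: int) -> float:
        """p(Y=y | X=x)."""
        p1 = self.pY1_X1 if x == 1 else self.pY1_X0
        return p1 if y == 1 else 1.0 - p1

    @property
    def marginals(self) -> MarginalPair:
        return MarginalPair(p0=self.pY1_X0, p1=self.pY1_X1)

    @classmethod
    def from_marginals(cls, m: MarginalPair) -> "ObservedMargins":
        return cls(pY1_X1=m.p1, pY1_X0=m.p0)


def pi_from_delta(cell, delta: float, beta: float, obs: ObservedMargins) -> float:
    """Probability of benefit recovered from one (delta_xy, beta_xy) pair.

    The cell-specific identification formulas are

        (1,0): p(Y=0|X=0) * expit(delta + beta)
        (0,1): p(Y=1|X=1) * {1 - expit(delta + beta)}
        (1,1): p(Y=1|X=1) - p(Y=1|X=0) * expit(delta + beta)
        (0,0): p(Y=0|X=0) - p(Y=0|X=1) * {1 - expit(delta + beta)}

    A delta that is incompatible with the observed distribution can push the
    raw value outside [0, 1]; the result is clipped and an
    ``IncompatibleValueWarning`` is emitted (never silently returned).
    """
    cell = CellIndex.of(cell)
    if not math.isfinite(beta):
        raise ValueError(f"beta_xy must be finite, got {beta}")
    e = float(expit(delta + beta))
    if cell == (1, 0):
        raw = obs.p(0, 0) * e
    elif cell == (0, 1):
        raw = obs.p(1, 1) * (1.0 - e)
    elif cell == (1, 1):
        raw = obs.p(1, 1) - obs.p(1, 0) * e
    else:  # (0, 0)
        raw = obs.p(0, 0) - obs.p(0, 1) * (1.0 - e)
    if raw < 0.0 or raw > 1.0:
        warnings.warn(
            f"pi from delta_{cell.x}{cell.y}={delta:.4g} fell outside [0,1] "
            f"(raw {raw:.4g}); the posited delta is incompatible with the "
            "observed distribution — result clipped",
            IncompatibleValueWarning,
            stacklevel=2,
        )
    return min(max(raw, 0.0), 1.0)


def alpha_xy_from_joint(j: JointPotentialDist, cell) -> float:
    """alpha_xy implied by a full joint (marginal over Z).

    Uses expit(alpha_10) = p01/(1-p0), expit(alpha_01) = (p1-p01)/p1,
    expit(alpha_11) = (p1-p01)/p0, expit(alpha_00) = (p0-p1+p01)/(1-p1);
    the identity alpha = alpha_x1 - alpha_x0 then holds for both arms.
    """
    cell = CellIndex.of(cell)
    p0, p1, pi = j.p0, j.p1, j.pi
    if cell == (1, 0):
        num, den = pi, 1.0 - p0
    elif cell == (0, 1):
        num, den = p1 - pi, p1
    elif cell == (1, 1):
        num, den = p1 - pi, p0
    else:
        num, den = p0 - p1 + pi, 1.0 - p1
    if den <= 0.0:
        raise ValueError(f"alpha_{cell.x}{cell.y} undefined: degenerate joint")
    ratio = num / den
    if not 0.0 < ratio < 1.0:
        raise ValueError(
            f"alpha_{cell.x}{cell.y} undefined: probability ratio {ratio} not in (0,1)"
        )
    return float(logit(ratio))


class IncompatibleAlphaError(ValueError):
    """A posited alpha_xy contradicts the observed outcome margins."""


def _checked_logit(arg: float, label: str) -> float:
    if not 0.0 < arg < 1.0:
        raise IncompatibleAlphaError(
            f"converting {label}: logit argument {arg:.6g} outside (0,1); the "
            "posited value is incompatible with the observed margins"
        )
    return float(logit(arg))


def convert_alpha_cell(from_cell, alpha_xy: float, obs: ObservedMargins) -> dict:
    """Map alpha_xy of one cell to the two adjacent cells (same x / same y).

    Returns ``{(x, 1-y): alpha, (1-x, y): alpha}``.  Both published maps are
    involutive given the margins: converting back recovers the input.
    """
    cell = CellIndex.of(from_cell)
    x, y = cell
    rho_xy = obs.marginals.rho(x, y)
    # alpha_{x, 1-y}
    factor = obs.p(y, 1 - x) / obs.p(1 - y, 1 - x)
    a_flip_y = _checked_logit(
        factor * (rho_xy - float(expit(alpha_xy))), f"alpha_{x}{y} -> alpha_{x}{1 - y}"
    )
    # alpha_{1-x, y}: uses expit(alpha_xy) when y=1, 1-expit(alpha_{x,1-y}) when y=0
    rho_ot = obs.marginals.rho(1 - x, y)
    inner = float(expit(alpha_xy)) if y == 1 else 1.0 - float(expit(a_flip_y))
    a_flip_x = _checked_logit(rho_ot * inner, f"alpha_{x}{y} -> alpha_{1 - x}{y}")
    return {CellIndex(x, 1 - y): a_flip_y, CellIndex(1 - x, y): a_flip_x}


def convert_delta_cell(
    from_cell, delta: float, betas: dict, obs: ObservedMargins
) -> dict:
    """Translate a delta_xy into the other three cells' deltas.

    ``betas`` maps each cell to its beta_xy (all four needed).  Uses the
    alpha-scale conversions plus delta_xy = alpha_xy - beta_xy.
    """
    from_cell = CellIndex.of(from_cell)
    betas = {CellIndex.of(c): b for c, b in betas.items()}
    alphas = {from_cell: delta + betas[from_cell]}
    adj = convert_alpha_cell(from_cell, alphas[from_cell], obs)
    alphas.update(adj)
    missing = [c for c in ALL_CELLS if c not in alphas][0]
    # reach the diagonal cell through one of the adjacent ones
    via = CellIndex(missing.x, 1 - missing.y)
    alphas[missing] = convert_alpha_cell(via, alphas[via], obs)[missing]
    return {c: alphas[c] - betas[c] for c in ALL_CELLS if c != from_cell}


def delta_bounds(cell, m: MarginalPair, beta_xy: float) -> tuple[float, float]:
    """Range of delta_xy compatible with the observed margins (possibly ±inf).

    These are the nonparametric pi bounds pushed through the cell's
    identification formula; endpoints where the logit argument hits 0 or 1
    are ±inf.  Increasing beta_xy by c shifts both endpoints by -c.
    """
    cell = CellIndex.of(cell)
    p0, p1 = m.p0, m.p1
    lo_pi, hi_pi = np_bounds(m)
    if cell == (1, 0):
        args = (lo_pi / (1 - p0), hi_pi / (1 - p0))
    elif cell == (0, 1):
        args = ((p1 - hi_pi) / p1, (p1 - lo_pi) / p1)
    elif cell == (1, 1):
        args = ((p1 - hi_pi) / p0, (p1 - lo_pi) / p0)
    else:
        args = ((p0 - p1 + lo_pi) / (1 - p1), (p0 - p1 + hi_pi) / (1 - p1))

    # boundary equalities (e.g. p1 = 1-p0) can land a ulp inside (0,1) by
    # float association; treat anything within 1e-12 of the ends as infinite
    def _edge(a: float) -> float:
        if a <= 1e-12:
            return -math.inf
        if a >= 1.0 - 1e-12:
            return math.inf
        return float(logit(a))

    return _edge(args[0]) - beta_xy, _edge(args[1]) - beta_xy


#: fixed tie-break precedence when several cells qualify on boundary equalities
_VI_PRECEDENCE = (CellIndex(0, 1), CellIndex(1, 0), CellIndex(1, 1), CellIndex(0, 0))


def variation_independent_cell(m: MarginalPair) -> CellIndex:
    """The cell whose delta has unrestricted range (-inf, inf).

    Exactly one of the four conditions holds up to boundary equalities:
    p1<=p0<=1-p1 -> (0,1); 1-p0<=p1<=p0 -> (1,0); p0<=p1<=1-p0 -> (1,1);
    1-p1<=p0<=p1 -> (0,0).  Ties are broken by the fixed precedence
    (0,1) > (1,0) > (1,1) > (0,0).
    """
    p0, p1 = m.p0, m.p1
    qualifies = {
        CellIndex(0, 1): p1 <= p0 <= 1 - p1,
        CellIndex(1, 0): 1 - p0 <= p1 <= p0,
        CellIndex(1, 1): p0 <= p1 <= 1 - p0,
        CellIndex(0, 0): 1 - p1 <= p0 <= p1,
    }
    for cell in _VI_PRECEDENCE:
        if qualifies[cell]:
            return cell
    raise AssertionError("unreachable: the four conditions cover the unit square")
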