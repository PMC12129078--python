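"""Joint distribution of the two potential outcomes of a binary treatment.

For a binary outcome Y and binary randomized treatment X, write Y(0), Y(1) for
the potential outcomes and p_ab = p{Y(0)=a, Y(1)=b}.  The probability of
benefit is pi = p01.  Its marginals p0 = p{Y(0)=1} and p1 = p{Y(1)=1} are
identified in a randomized trial, but the joint is not; it is pinned down by
one extra degree of freedom, conveniently parameterized by the (marginal) log
odds ratio

    alpha = log(p11 * p00 / (p10 * p01)),

which is variation independent of the observed (X, Y) distribution.  This
module houses the sharp nonparametric (Fréchet-type) bounds on pi and the
bidirectional map between (p0, p1, alpha) and the joint: the map inverts a
quadratic in p11 (a Plackett-type inversion), with alpha = 0 giving the
independence product p0*p1 and alpha → ±inf the Fréchet extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._guards import validate_prob

__all__ = [
    "MarginalPair",
    "JointPotentialDist",
    "np_bounds",
    "p11_from_alpha",
    "joint_from_marginals_alpha",
    "pi_from_alpha",
    "alpha_of_joint",
]

# below this, Eq-(4)-style inversion divides by e^alpha - 1 ~ alpha and loses
# precision; the independence limit p0*p1 is exact to O(alpha)
_ALPHA_INDEP_TOL = 1e-6
# beyond this the inversion is indistinguishable from the Fréchet extremes
# (error < e^-300) and e^(2*alpha) would approach overflow
_ALPHA_INF_CUTOFF = 300.0


@dataclass(frozen=True)
class MarginalPair:
    """Identified marginals (p0, p1) of the potential outcomes.

    p0 = p{Y(0)=1}, estimable as p(Y=1|X=0); p1 = p{Y(1)=1}, estimable as
    p(Y=1|X=1).  Boundary values are accepted (the bounds are total on the
    unit square); operations that require an interior point check separately.
    """

    p0: float
    p1: float

    def __post_init__(self):
        object.__setattr__(self, "p0", validate_prob(self.p0, "p0"))
        object.__setattr__(self, "p1", validate_prob(self.p1, "p1"))

    @property
    def interior(self) -> bool:
        return 0.0 < self.p0 < 1.0 and 0.0 < self.p1 < 1.0

    def rho(self, x: int, y: int) -> float:
        """rho_xy = p(Y=1|X=x) / p(Y=y|X=1-x); under randomization these are
        the marginals of the potential outcomes."""
        num = self.p1 if x == 1 else self.p0
        other = self.p1 if (1 - x) == 1 else self.p0
        den = other if y == 1 else 1.0 - other
        if den == 0.0:
            raise ZeroDivisionError(f"rho_{x}{y} undefined: p(Y={y}|X={1 - x}) = 0")
        return num / den

    def frechet_box(self) -> tuple[float, float]:
        """Attainable range of p11 = p{Y(0)=1, Y(1)=1}."""
        return max(0.0, self.p0 + self.p1 - 1.0), min(self.p0, self.p1)


@dataclass(frozen=True)
class JointPotentialDist:
    """The 2x2 joint p_ab = p{Y(0)=a, Y(1)=b} with pi and alpha as views."""

    p00: float
    p01: float
    p10: float
    p11: float

    def __post_init__(self):
        cells = (self.p00, self.p01, self.p10, self.p11)
        for name, c in zip(("p00", "p01", "p10", "p11"), cells):
            validate_prob(c, name)
        if abs(sum(cells) - 1.0) > 1e-12:
            raise ValueError(f"joint cells must sum to 1, got {sum(cells)!r}")

    @property
    def pi(self) -> float:
        """Probability of benefit, p{Y(0)=0, Y(1)=1}."""
        return self.p01

    @property
    def p0(self) -> float:
        return self.p10 + self.p11

    @property
    def p1(self) -> float:
        return self.p01 + self.p11

    @property
    def marginals(self) -> MarginalPair:
        return MarginalPair(self.p0, self.p1)

    @property
    def alpha(self) -> float:
        """Log odds ratio between Y(0) and Y(1); requires all cells > 0."""
        if min(self.p00, self.p01, self.p10, self.p11) <= 0.0:
            raise ValueError("alpha undefined: joint has a zero cell")
        return math.log(self.p11 * self.p00 / (self.p10 * self.p01))


def np_bounds(m: MarginalPair) -> tuple[float, float]:
    """Sharp nonparametric bounds max(0, p1-p0) <= pi <= min(p1, 1-p0)."""
    return max(0.0, m.p1 - m.p0), min(m.p1, 1.0 - m.p0)


def _require_interior(m: MarginalPair) -> None:
    if not m.interior:
        raise ValueError(
            "odds-ratio inversion needs 0 < p0, p1 < 1 "
            f"(got p0={m.p0}, p1={m.p1}); alpha is undefined on the boundary"
        )


def p11_from_alpha(m: MarginalPair, alpha: float) -> float:
    """Invert the odds-ratio relation: the p11 with marginals m and log OR alpha.

    Solves the quadratic p11*p00/(p10*p01) = e^alpha, taking the root inside
    the Fréchet box.  alpha = 0 returns the independence product; +inf/-inf
    sentinels return the upper/lower Fréchet extremes.
    """
    _require_interior(m)
    p0, p1 = m.p0, m.p1
    lo, hi = m.frechet_box()
    if math.isnan(alpha):
        raise ValueError("alpha must not be NaN")
    if alpha >= _ALPHA_INF_CUTOFF or alpha == math.inf:
        return hi
    if alpha <= -_ALPHA_INF_CUTOFF or alpha == -math.inf:
        return lo
    if abs(alpha) < _ALPHA_INDEP_TOL:
        return p0 * p1
    ea = math.exp(alpha)
    # D has only nonnegative terms; compute the dominant term as a square
    # (hypot-style) so it cannot cancel or spuriously overflow
    sqrt_d = math.hypot(
        ea * (p0 - p1),
        math.sqrt(2.0 * ea * (p0 * (1 - p0) + p1 * (1 - p1)) + (p0 + p1 - 1.0) ** 2),
    )
    p11 = ((p0 + p1) * (ea - 1.0) + 1.0 - sqrt_d) / (2.0 * (ea - 1.0))
    # clip float drift back into the attainable box
    return min(max(p11, lo), hi)


def joint_from_marginals_alpha(m: MarginalPair, alpha: float) -> JointPotentialDist:
    """Reconstruct the full joint from (p0, p1, alpha)."""
    p11 = p11_from_alpha(m, alpha)
    p10 = m.p0 - p11
    p01 = m.p1 - p11
    p00 = 1.0 - m.p1 - m.p0 + p11
    clip = lambda v: min(max(v, 0.0), 1.0)  # noqa: E731 - float drift only
    return JointPotentialDist(p00=clip(p00), p01=clip(p01), p10=clip(p10), p11=clip(p11))


def pi_from_alpha(m: MarginalPair, alpha: float) -> float:
    """Probability of benefit pi = p1 - p11 implied by (p0, p1, alpha).

    Strictly decreasing in alpha; its alpha → ±inf limits are the
    nonparametric bounds of :func:`np_bounds`.
    """
    pi = m.p1 - p11_from_alpha(m, alpha)
    lo, hi = np_bounds(m)
    return min(max(pi, lo), hi)


def alpha_of_joint(j: JointPotentialDist) -> float:
    """Log odds ratio of a joint distribution (all four cells must be > 0)."""
    return j.alpha


def alpha_from_pi(m: MarginalPair, pi: float) -> float:
    """Inverse of :func:`pi_from_alpha`: the alpha matching a compatible pi.

    Returns ±inf at the nonparametric bounds.
    """
    _require_interior(m)
    lo, hi = np_bounds(m)
    if not (lo - 1e-12 <= pi <= hi + 1e-12):
        raise ValueError(f"pi={pi} outside the nonparametric bounds [{lo}, {hi}]")
    p11 = m.p1 - pi
    p10 = m.p0 - p11
    p00 = 1.0 - m.p0 - m.p1 + p11
    if min(p11, pi, p10, p00) <= 0.0:
        return math.inf if pi <= lo + 1e-12 else -math.inf
    return math.log(p11 * p00 / (p10 * pi))
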