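"""Numerically guarded probability/logit primitives shared across the package.

Finite samples routinely produce empirical proportions of exactly 0 or 1, and
chained transforms can push probabilities a few ulp outside [0, 1].  Every
logit/expit in the package routes through this module so that such events are
clipped consistently and surfaced as warnings rather than silently returning
±inf or NaN.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit as _expit
from scipy.special import logit as _logit

#: clip window for guarded logits
PROB_EPS = 1e-12
#: float-safe validation tolerance for probabilities
VALIDATION_TOL = 1e-12


class GuardWarning(UserWarning):
    """A probability was clipped into its valid domain before a transform."""


class IncompatibleValueWarning(UserWarning):
    """A posited sensitivity-parameter value produced an out-of-range result."""


def expit(x):
    """Inverse logit; total on the extended real line."""
    return _expit(x)


def logit(p):
    """Unguarded logit; callers must ensure p in [0, 1] (0/1 map to ∓inf)."""
    with np.errstate(divide="ignore"):
        return _logit(p)


def guarded_logit(p, what: str = "probability"):
    """Logit with inputs clipped to [PROB_EPS, 1-PROB_EPS], warning on clips."""
    p_arr = np.asarray(p, dtype=float)
    clipped = np.clip(p_arr, PROB_EPS, 1.0 - PROB_EPS)
    if np.any(p_arr != clipped):
        warnings.warn(
            f"{what} clipped to [{PROB_EPS}, 1-{PROB_EPS}] before logit",
            GuardWarning,
            stacklevel=2,
        )
    out = _logit(clipped)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def validate_prob(p: float, name: str = "probability", *, open_unit: bool = False) -> float:
    """Validate a scalar probability with float-safe strictness.

    Values within VALIDATION_TOL outside [0, 1] are clipped; anything further
    out is rejected.  With ``open_unit`` the boundaries 0 and 1 are rejected.
    """
    p = float(p)
    if not np.isfinite(p):
        raise ValueError(f"{name} must be finite, got {p}")
    if p < -VALIDATION_TOL or p > 1.0 + VALIDATION_TOL:
        raise ValueError(f"{name} must lie in [0, 1], got {p}")
    p = min(max(p, 0.0), 1.0)
    if open_unit and (p <= 0.0 or p >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1), got {p}")
    return p
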