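"""Synthetic trial generator and analytic-truth engine.

Data-generating process (univariate standard-normal covariate):

    Z ~ N(0, 1)
    X | Z ~ Bernoulli(0.5)                      (randomized treatment)
    p{Y(x)=1 | Z} = expit(a0 + aX*x + aZ*Z)
    log OR{Y(0), Y(1) | Z} = alpha_Z(Z)         (conditional dependence)
    Y = Y(X)                                    (consistency)

Given (p0(z), p1(z), alpha_Z(z)) the conditional joint of {Y(0), Y(1)} is
recovered by the odds-ratio inversion of :mod:`benefitsens.core`; marginal
truths (pi, the cell parameters alpha_xy/beta_xy/delta_xy, the marginal log
odds ratio) follow by integrating over Z with Gauss-Hermite quadrature.

Three preset scenarios are provided:

    I      a0=1, aX=1, aZ=0,  alpha_Z = 0      (independent potential outcomes)
    II     a0=1, aX=0, aZ=-1, alpha_Z = 0.2+z  (null average effect)
    III    a0=1, aX=2, aZ=-2, alpha_Z = 0.2+z  (strong effect + confounded dependence)
    IIImis Scenario III data, but the analysis model misspecifies the
           covariate as log|Z|

Structural identities of the presets (useful as oracle checks): in I,
beta_x1 = beta_x0; in II, beta_1y = beta_0y; in III, beta_1y - beta_0y = aX.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import roots_hermitenorm

from ._guards import expit, logit
from .calibration import CalibrationSpec, delta_grid_from_A
from .cells import ALL_CELLS, CellIndex, alpha_xy_from_joint
from .core import JointPotentialDist, MarginalPair, np_bounds, p11_from_alpha
from .estimation import (
    ModelFitError,
    TrialData,
    estimate_beta,
    estimate_pi,
    fit_outcome_model,
    marginalized_bounds,
    sensitivity_curve,
)

__all__ = [
    "ScenarioConfig",
    "TruthSet",
    "SCENARIOS",
    "scenario",
    "conditional_joint",
    "sample_trial",
    "truth_by_quadrature",
    "true_A",
    "run_simulation_study",
    "run_bounds_coverage_study",
    "run_calibration_coverage_study",
]


def _p11_cond(p0z, p1z, az) -> np.ndarray:
    """Vectorized p11 of the conditional joint across covariate values.

    At a degenerate margin (p0 or p1 hits 0/1 in float at extreme covariate
    values) the joint collapses and p11 = p0*p1 exactly, whatever alpha; the
    same product is the |alpha| -> 0 limit.  Elsewhere this mirrors
    :func:`benefitsens.core.p11_from_alpha`.
    """
    p0z = np.asarray(p0z, dtype=float)
    p1z = np.asarray(p1z, dtype=float)
    az = np.asarray(az, dtype=float)
    lo = np.maximum(0.0, p0z + p1z - 1.0)
    hi = np.minimum(p0z, p1z)
    out = p0z * p1z  # boundary margins and the independence limit
    degenerate = (p0z <= 0.0) | (p0z >= 1.0) | (p1z <= 0.0) | (p1z >= 1.0)
    out = np.where(~degenerate & (az >= 300.0), hi, out)
    out = np.where(~degenerate & (az <= -300.0), lo, out)
    mid = ~degenerate & (np.abs(az) >= 1e-6) & (np.abs(az) < 300.0)
    if np.any(mid):
        p0m, p1m, am = p0z[mid], p1z[mid], az[mid]
        ea = np.exp(am)
        d = (
            (ea * (p0m - p1m)) ** 2
            + 2.0 * ea * (p0m * (1 - p0m) + p1m * (1 - p1m))
            + (p0m + p1m - 1.0) ** 2
        )
        p11m = ((p0m + p1m) * (ea - 1.0) + 1.0 - np.sqrt(d)) / (2.0 * (ea - 1.0))
        vals = np.array(out)
        vals[mid] = np.clip(p11m, lo[mid], hi[mid])
        out = vals
    return out


def _affine(c0: float, c1: float) -> Callable[[np.ndarray], np.ndarray]:
    def f(z):
        return c0 + c1 * np.asarray(z, dtype=float)

    f.coefficients = (c0, c1)  # type: ignore[attr-defined]
    return f


@dataclass(frozen=True)
class ScenarioConfig:
    """Data-generating parameters for one simulation scenario.

    ``alpha_z`` maps covariate values to the conditional log odds ratio of
    the potential outcomes; config files restrict it to an affine form
    ``c0 + c1*z`` but the API accepts any callable.  ``model`` chooses the
    analysis model: 'correct' fits Y ~ X + Z, 'misspecified' fits
    Y ~ X + log|Z|.
    """

    a0: float
    aX: float
    aZ: float
    alpha_z: Callable[[np.ndarray], np.ndarray]
    n: int = 500
    reps: int = 1000
    seed: int | None = None
    model: str = "correct"
    name: str = "custom"

    def __post_init__(self):
        for v, nm in ((self.a0, "a0"), (self.aX, "aX"), (self.aZ, "aZ")):
            if not math.isfinite(v):
                raise ValueError(f"{nm} must be finite")
        if self.model not in ("correct", "misspecified"):
            raise ValueError(f"model must be 'correct' or 'misspecified', got {self.model!r}")

    def marginal_prob(self, x: int, z) -> np.ndarray:
        """p{Y(x)=1 | Z=z}."""
        return np.asarray(expit(self.a0 + self.aX * x + self.aZ * np.asarray(z, float)))


SCENARIOS: dict[str, ScenarioConfig] = {
    "I": ScenarioConfig(1.0, 1.0, 0.0, _affine(0.0, 0.0), name="I"),
    "II": ScenarioConfig(1.0, 0.0, -1.0, _affine(0.2, 1.0), name="II"),
    "III": ScenarioConfig(1.0, 2.0, -2.0, _affine(0.2, 1.0), name="III"),
    "IIImis": ScenarioConfig(
        1.0, 2.0, -2.0, _affine(0.2, 1.0), model="misspecified", name="IIImis"
    ),
}


def scenario(name: str, **overrides) -> ScenarioConfig:
    """A preset scenario, optionally with n/reps/seed overrides."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; presets: {sorted(SCENARIOS)}")
    return replace(SCENARIOS[name], **overrides)


def conditional_joint(z: float, config: ScenarioConfig) -> JointPotentialDist:
    """Joint of {Y(0), Y(1)} given Z=z implied by the scenario."""
    m = MarginalPair(
        p0=float(config.marginal_prob(0, z)), p1=float(config.marginal_prob(1, z))
    )
    alpha = float(np.asarray(config.alpha_z(z)))
    p11 = p11_from_alpha(m, alpha)
    return JointPotentialDist(
        p00=1.0 - m.p0 - m.p1 + p11, p01=m.p1 - p11, p10=m.p0 - p11, p11=p11
    )


def sample_trial(
    config: ScenarioConfig,
    seed: int | np.random.Generator | None = None,
    with_potentials: bool = False,
) -> TrialData:
    """Draw one trial of n subjects; deterministic given the seed.

    Per subject: Z ~ N(0,1); {Y(0), Y(1)} from the conditional joint at Z;
    X a fair coin; Y = Y(X).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    n = config.n
    z = rng.standard_normal(n)
    p0z = config.marginal_prob(0, z)
    p1z = config.marginal_prob(1, z)
    az = np.asarray(config.alpha_z(z), dtype=float)
    p11z = _p11_cond(p0z, p1z, az)
    # draw Y(0) from its margin, then Y(1) | Y(0) from the conditional joint
    u0, u1, ux = rng.random(n), rng.random(n), rng.random(n)
    y0 = (u0 < p0z).astype(int)
    p1_given = np.where(y0 == 1, p11z / p0z, (p1z - p11z) / (1.0 - p0z))
    y1 = (u1 < p1_given).astype(int)
    x = (ux < 0.5).astype(int)
    y = np.where(x == 1, y1, y0)
    df = pd.DataFrame({"X": x, "Y": y, "Z": z})
    if with_potentials:
        df["Y0"], df["Y1"] = y0, y1
    return TrialData(df, covariates=["Z"])


@dataclass(frozen=True)
class TruthSet:
    """Analytically integrated truths for a scenario."""

    pi: float
    p0: float
    p1: float
    alpha: float
    joint: JointPotentialDist
    alpha_xy: dict = field(default_factory=dict)
    beta_xy: dict = field(default_factory=dict)
    delta_xy: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 3) -> dict:
        """Truth values at reporting precision (full precision kept in fields)."""
        return {
            "pi": round(self.pi, ndigits),
            "p0": round(self.p0, ndigits),
            "p1": round(self.p1, ndigits),
            "alpha": round(self.alpha, ndigits),
            "beta_xy": {f"{c.x}{c.y}": round(v, ndigits) for c, v in self.beta_xy.items()},
            "delta_xy": {f"{c.x}{c.y}": round(v, ndigits) for c, v in self.delta_xy.items()},
        }


class QuadratureError(RuntimeError):
    """Doubling the node count moved an integral by more than the tolerance."""


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for the standard normal weight."""
    x, w = roots_hermitenorm(n_nodes)
    return x, w / math.sqrt(2.0 * math.pi)


def _integrate_truths(config: ScenarioConfig, n_nodes: int) -> dict:
    z, w = _gh_nodes(n_nodes)
    p0z = config.marginal_prob(0, z)
    p1z = config.marginal_prob(1, z)
    az = np.asarray(config.alpha_z(z), dtype=float)
    p11z = _p11_cond(p0z, p1z, az)
    cells = {
        "p11": float(p11z @ w),
        "p01": float((p1z - p11z) @ w),
        "p10": float((p0z - p11z) @ w),
        "p00": float((1.0 - p0z - p1z + p11z) @ w),
    }
    betas = {}
    for c in ALL_CELLS:
        pred = config.marginal_prob(c.x, z)
        p_arm = config.marginal_prob(1 - c.x, z)
        wt = (p_arm if c.y == 1 else 1.0 - p_arm) * w
        betas[c] = float(logit((pred @ wt) / wt.sum()))
    return {"cells": cells, "betas": betas}


def truth_by_quadrature(
    config: ScenarioConfig, n_nodes: int = 201, tol: float = 1e-8
) -> TruthSet:
    """Integrate the conditional joint and the beta weights over Z ~ N(0,1).

    A fixed Gauss-Hermite rule is used and checked by doubling the node
    count; disagreement beyond ``tol`` raises :class:`QuadratureError`.
    """
    coarse = _integrate_truths(config, n_nodes)
    fine = _integrate_truths(config, 2 * n_nodes + 1)
    drift = max(
        max(abs(coarse["cells"][k] - fine["cells"][k]) for k in coarse["cells"]),
        max(abs(coarse["betas"][c] - fine["betas"][c]) for c in ALL_CELLS),
    )
    if drift > tol:
        raise QuadratureError(
            f"quadrature not converged: doubling nodes moved results by {drift:.3g}"
        )
    cells, betas = fine["cells"], fine["betas"]
    joint = JointPotentialDist(**cells)
    alphas = {c: alpha_xy_from_joint(joint, c) for c in ALL_CELLS}
    return TruthSet(
        pi=joint.pi,
        p0=joint.p0,
        p1=joint.p1,
        alpha=joint.alpha,
        joint=joint,
        alpha_xy=alphas,
        beta_xy=betas,
        delta_xy={c: alphas[c] - betas[c] for c in ALL_CELLS},
    )


def true_A(config: ScenarioConfig, x: int, z_range: tuple[float, float] = (-8.0, 8.0),
           n_grid: int = 4001) -> float:
    """True A_x: the largest conditional counterfactual risk difference.

    Maximizes |p{Y(x)=1 | Z=z, Y=1, X=1-x} - p{Y(x)=1 | Z=z, Y=0, X=1-x}|
    over a fine z grid; by randomization and consistency the conditioning
    event {Y=y, X=1-x} given Z=z is {Y(1-x)=y}.
    """
    z = np.linspace(*z_range, n_grid)
    diffs = np.empty(n_grid)
    for i, zi in enumerate(z):
        j = conditional_joint(float(zi), config)
        if x == 1:
            # p{Y(1)=1 | Y(0)=y}
            p_y1 = j.p11 / (j.p10 + j.p11)
            p_y0 = j.p01 / (j.p00 + j.p01)
        else:
            p_y1 = j.p11 / (j.p01 + j.p11)
            p_y0 = j.p10 / (j.p00 + j.p10)
        diffs[i] = abs(p_y1 - p_y0)
    return float(diffs.max())


# ---------------------------------------------------------------------------
# replication studies


def _rep_rngs(config: ScenarioConfig, seed: int | None):
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    return [np.random.default_rng(s) for s in master.spawn(config.reps)]


def _analysis_data(data: TrialData, config: ScenarioConfig) -> TrialData:
    """Apply the scenario's analysis-model covariate (mis)specification."""
    if config.model == "correct":
        return data
    df = data.df.copy()
    df["Zmis"] = np.log(np.abs(df["Z"].to_numpy()))
    return TrialData(df, covariates=["Zmis"])


def run_simulation_study(
    config: ScenarioConfig,
    cells=ALL_CELLS,
    seed: int | None = None,
    inference: str = "sandwich",
) -> pd.DataFrame:
    """Replicate the full estimation pipeline at the true delta of each cell.

    Per replicate: draw a trial, fit the (possibly misspecified) logistic
    model, and for every requested cell estimate beta, pi (at the true
    delta_xy of the *data-generating* scenario) and its SE/CI.  Returns one
    row per cell with the truth, mean estimate, empirical SE, mean estimated
    SE, 95% coverage, and the beta summaries.  Replicate failures are logged
    and counted, not fatal.  Reproducible given the seed.
    """
    cells = [CellIndex.of(c) for c in cells]
    truth = truth_by_quadrature(config)
    acc = {c: {"pi": [], "se": [], "cover": [], "beta": []} for c in cells}
    failures = 0
    for rng in _rep_rngs(config, seed):
        try:
            data = sample_trial(config, seed=rng)
            data.require_four_cells()
            adata = _analysis_data(data, config)
            model = fit_outcome_model(adata)
            for c in cells:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = estimate_pi(
                        adata, model, c, truth.delta_xy[c], method=inference
                    )
                acc[c]["pi"].append(est.value)
                acc[c]["se"].append(est.se)
                acc[c]["cover"].append(est.ci[0] <= truth.pi <= est.ci[1])
                acc[c]["beta"].append(est.beta_hat)
        except (ModelFitError, ValueError):
            failures += 1
    def _sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    rows = []
    for c in cells:
        a = {k: np.asarray(v, dtype=float) for k, v in acc[c].items()}
        rows.append(
            {
                "scenario": config.name,
                "x": c.x,
                "y": c.y,
                "pi_true": truth.pi,
                "mean_pi_hat": a["pi"].mean(),
                "emp_se_pi": _sd(a["pi"]),
                "mean_se_hat": a["se"].mean(),
                "coverage": a["cover"].mean(),
                "beta_true": truth.beta_xy[c],
                "mean_beta_hat": a["beta"].mean(),
                "emp_se_beta": _sd(a["beta"]),
                "delta_true": truth.delta_xy[c],
                "n_reps": len(a["pi"]),
                "n_failures": failures,
            }
        )
    return pd.DataFrame(rows)


def run_bounds_coverage_study(config: ScenarioConfig, seed: int | None = None) -> dict:
    """Coverage of pi_true by marginal and covariate-marginalized bounds (%)."""
    truth = truth_by_quadrature(config)
    marg, margz = [], []
    failures = 0
    for rng in _rep_rngs(config, seed):
        try:
            data = sample_trial(config, seed=rng)
            lo, hi = np_bounds(data.margins().marginals)
            marg.append(lo <= truth.pi <= hi)
            model = fit_outcome_model(_analysis_data(data, config))
            lo_z, hi_z = marginalized_bounds(_analysis_data(data, config), model)
            margz.append(lo_z <= truth.pi <= hi_z)
        except (ModelFitError, ValueError):
            failures += 1
    return {
        "marginal_pct": 100.0 * float(np.mean(marg)),
        "marginalized_pct": 100.0 * float(np.mean(margz)),
        "n_reps": len(marg),
        "n_failures": failures,
    }


def run_calibration_coverage_study(
    config: ScenarioConfig,
    A_values: dict | None = None,
    fallback: float = 5.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Grid-calibration coverage study.

    Per replicate and cell: build the delta grid from the *true* A_x and the
    replicate's estimated beta_xy (with ±``fallback`` sentinels where a limit
    fails), then record whether the true delta_xy lies in the grid and
    whether the true pi lies in the spanned CI interval over the grid
    endpoints.  Returns one row per cell with coverage percentages and
    fallback counts.
    """
    truth = truth_by_quadrature(config)
    if A_values is None:
        A_values = {1: true_A(config, 1), 0: true_A(config, 0)}
    acc = {
        c: {"delta_in": [], "pi_in": [], "lo_fb": 0, "up_fb": 0} for c in ALL_CELLS
    }
    failures = 0
    for rng in _rep_rngs(config, seed):
        try:
            data = sample_trial(config, seed=rng)
            data.require_four_cells()
            adata = _analysis_data(data, config)
            model = fit_outcome_model(adata)
            for c in ALL_CELLS:
                beta_hat = estimate_beta(adata, model, c)
                grid = delta_grid_from_A(
                    CalibrationSpec(cell=c, A=A_values[c.x], fallback=fallback),
                    beta_hat,
                )
                acc[c]["delta_in"].append(grid.contains(truth.delta_xy[c]))
                acc[c]["lo_fb"] += grid.lower_fallback
                acc[c]["up_fb"] += grid.upper_fallback
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    curve = sensitivity_curve(
                        adata, model, c, [grid.lower, grid.upper], method="sandwich"
                    )
                acc[c]["pi_in"].append(
                    curve.spanned[0] <= truth.pi <= curve.spanned[1]
                )
        except (ModelFitError, ValueError):
            failures += 1
    rows = []
    for c in ALL_CELLS:
        n_ok = len(acc[c]["delta_in"])
        rows.append(
            {
                "scenario": config.name,
                "x": c.x,
                "y": c.y,
                "A_true": A_values[c.x],
                "delta_grid_coverage_pct": 100.0 * float(np.mean(acc[c]["delta_in"])),
                "pi_spanned_coverage_pct": 100.0 * float(np.mean(acc[c]["pi_in"])),
                "n_lower_fallback": acc[c]["lo_fb"],
                "n_upper_fallback": acc[c]["up_fb"],
                "n_reps": n_ok,
                "n_failures": failures,
            }
        )
    return pd.DataFrame(rows)
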