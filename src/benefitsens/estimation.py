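"""Estimation and inference for the probability of benefit at a given delta.

Workflow: fit a logistic outcome model p(Y=1|X, Z), form the plug-in

    beta_hat_xy = logit{ mean of p_hat(Y=1|X=x, Z_i) over the (Y=y, X=1-x) stratum },

and plug (delta, beta_hat, empirical outcome margins) into the cell-specific
identification formula for pi.  The sensitivity parameter delta is treated as
*known* throughout: statistical uncertainty (sandwich M-estimation or the
nonparametric bootstrap) is kept separate from sensitivity uncertainty by
construction.

The sandwich stacks the estimating equations of every plug-in ingredient —
logistic score, the stratum-mean prediction, the per-arm outcome proportions,
and the pi formula itself — and propagates the variance through the bread
matrix.  The bootstrap refits the whole pipeline per resample and is the
default whenever the model is not a jointly fitted logistic regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._guards import GuardWarning, IncompatibleValueWarning, expit, guarded_logit
from .cells import ALL_CELLS, CellIndex, ObservedMargins, pi_from_delta

__all__ = [
    "TrialData",
    "OutcomeModel",
    "PiEstimate",
    "ModelFitError",
    "fit_outcome_model",
    "estimate_beta",
    "estimate_pi",
    "sandwich_se",
    "bootstrap_ci",
    "ivw_combine",
    "sensitivity_curve",
    "marginalized_bounds",
    "select_cell",
]

Z_NORM = 1.959963984540054  # 97.5% standard-normal quantile


class ModelFitError(RuntimeError):
    """Outcome-model fitting failed (separation, singular design, ...)."""


# ---------------------------------------------------------------------------
# data container


@dataclass
class TrialData:
    """Subject-level trial records: binary X and Y plus covariate columns.

    Missing values are rejected at construction; so are non-binary treatment
    or outcome codes.  Four-cell analyses additionally require all (X, Y)
    combinations to be populated — checked by :meth:`require_four_cells`.
    """

    df: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        for col in ["X", "Y", *self.covariates]:
            if col not in self.df.columns:
                raise ValueError(f"column {col!r} missing from data")
        sub = self.df[["X", "Y", *self.covariates]]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad}; impute or drop upstream")
        for col in ("X", "Y"):
            vals = set(pd.unique(self.df[col]))
            if not vals <= {0, 1}:
                raise ValueError(
                    f"{col} must be coded 0/1, found values {sorted(vals)}; recode first"
                )
        counts = self.df["X"].value_counts()
        if counts.get(0, 0) == 0 or counts.get(1, 0) == 0:
            raise ValueError("both treatment arms must be non-empty")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        treatment: str = "X",
        outcome: str = "Y",
        covariates: list[str] | None = None,
    ) -> "TrialData":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (treatment, outcome)]
        out = df[[treatment, outcome, *covariates]].rename(
            columns={treatment: "X", outcome: "Y"}
        )
        return cls(out, covariates=list(covariates))

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df["X"].to_numpy(dtype=float)

    @property
    def Y(self) -> np.ndarray:
        return self.df["Y"].to_numpy(dtype=float)

    def margins(self) -> ObservedMargins:
        return ObservedMargins(
            pY1_X1=float(self.Y[self.X == 1].mean()),
            pY1_X0=float(self.Y[self.X == 0].mean()),
        )

    def cell_counts(self) -> pd.Series:
        return self.df.groupby(["X", "Y"]).size()

    def require_four_cells(self) -> None:
        counts = self.cell_counts()
        missing = [
            (x, y) for x in (0, 1) for y in (0, 1) if counts.get((x, y), 0) == 0
        ]
        if missing:
            raise ValueError(
                f"empty (X, Y) cells {missing}: a four-cell analysis needs every "
                "treatment-by-outcome combination populated"
            )

    def stratum_mask(self, cell: CellIndex) -> np.ndarray:
        """Subjects with Y=y and X=1-x for the given sensitivity cell."""
        return (self.Y == cell.y) & (self.X == 1 - cell.x)

    def resample(self, rng: np.random.Generator) -> "TrialData":
        idx = rng.integers(0, self.n, self.n)
        return TrialData(self.df.iloc[idx].reset_index(drop=True), self.covariates)


# ---------------------------------------------------------------------------
# outcome model


@dataclass
class OutcomeModel:
    """Fitted logistic outcome model with a fit/predict contract.

    ``mode='joint'`` fits a single logistic regression of Y on X and the
    covariates over the whole sample (needed for the sandwich); ``'per-arm'``
    fits Y on the covariates separately within each arm.  ``formula`` is a
    patsy right-hand side; when ``None`` a plain main-effects design is built
    directly (numerically identical, cheaper inside simulation loops).
    """

    mode: str
    formula: str | None
    covariates: list[str]
    params: np.ndarray | dict
    _design_info: object | None = None
    _colnames: list[str] | None = None

    def predict(self, data: TrialData, arm: int) -> np.ndarray:
        """p_hat(Y=1 | X=arm, Z_i) for every subject i in ``data``."""
        if self.mode == "joint":
            return np.asarray(expit(self.design(data, arm) @ self.params))
        gamma = self.params[arm]
        w = self._arm_design(data)
        return np.asarray(expit(w @ gamma))

    def design(self, data: TrialData, arm: int | None = None) -> np.ndarray:
        """Joint-mode design matrix, with X overridden to ``arm`` if given."""
        if self.mode != "joint":
            raise ValueError("design() is only defined for joint-mode models")
        if self._design_info is not None:
            import patsy

            df = data.df if arm is None else data.df.assign(X=float(arm))
            (mat,) = patsy.build_design_matrices([self._design_info], df)
            return np.asarray(mat)
        x = data.X if arm is None else np.full(data.n, float(arm))
        cols = [np.ones(data.n), x]
        cols += [data.df[c].to_numpy(dtype=float) for c in self.covariates]
        return np.column_stack(cols)

    def _arm_design(self, data: TrialData) -> np.ndarray:
        if self._design_info is not None:
            import patsy

            (mat,) = patsy.build_design_matrices([self._design_info], data.df)
            return np.asarray(mat)
        cols = [np.ones(data.n)]
        cols += [data.df[c].to_numpy(dtype=float) for c in self.covariates]
        return np.column_stack(cols)


def _fit_glm(y: np.ndarray, w: np.ndarray, context: str) -> np.ndarray:
    if np.linalg.matrix_rank(w) < w.shape[1]:
        raise ModelFitError(f"singular design matrix while fitting {context}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, w, family=sm.families.Binomial()).fit()
    except Exception as exc:  # separation, non-convergence
        raise ModelFitError(f"logistic fit failed for {context}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ModelFitError(f"non-finite coefficients while fitting {context}")
    return np.asarray(res.params)


def fit_outcome_model(
    data: TrialData, formula: str | None = None, mode: str = "joint"
) -> OutcomeModel:
    """Fit the logistic outcome model p(Y=1 | X, Z) by maximum likelihood.

    ``formula`` is a patsy right-hand side over the data's columns, e.g.
    ``"X + Z"`` or ``"X + np.log(np.abs(Z))"`` (joint mode) / ``"Z"``
    (per-arm mode).  ``None`` uses main effects of X (joint only) and every
    covariate column.  With no covariates the model reduces to arm-specific
    sample proportions.
    """
    if mode not in ("joint", "per-arm"):
        raise ValueError(f"mode must be 'joint' or 'per-arm', got {mode!r}")
    if formula is not None:
        import patsy

        mat = patsy.dmatrix(formula, data.df, return_type="matrix")
        design_info = mat.design_info
        w_all = np.asarray(mat)
    else:
        design_info = None
        w_all = None

    if mode == "joint":
        if w_all is None:
            model = OutcomeModel("joint", None, data.covariates, np.empty(0))
            w_all = model.design(data)
        params = _fit_glm(data.Y, w_all, "the joint outcome model")
        return OutcomeModel(
            "joint", formula, data.covariates, params, _design_info=design_info
        )

    params = {}
    for arm in (0, 1):
        mask = data.X == arm
        if design_info is not None:
            w = w_all[mask]
        else:
            cols = [np.ones(int(mask.sum()))]
            cols += [data.df.loc[mask, c].to_numpy(dtype=float) for c in data.covariates]
            w = np.column_stack(cols)
        params[arm] = _fit_glm(data.Y[mask], w, f"the X={arm} arm model")
    return OutcomeModel(
        "per-arm", formula, data.covariates, params, _design_info=design_info
    )


# ---------------------------------------------------------------------------
# point estimation


def estimate_beta(data: TrialData, model: OutcomeModel, cell) -> float:
    """Plug-in beta_hat_xy: guarded logit of the mean model prediction
    p_hat(Y=1|X=x, Z_i) over the (Y=y, X=1-x) stratum."""
    cell = CellIndex.of(cell)
    mask = data.stratum_mask(cell)
    if not mask.any():
        raise ValueError(
            f"beta_{cell.x}{cell.y} undefined: no subjects with "
            f"Y={cell.y}, X={1 - cell.x}"
        )
    preds = model.predict(data, arm=cell.x)[mask]
    return float(guarded_logit(float(preds.mean()), f"mean prediction for beta_{cell.x}{cell.y}"))


@dataclass(frozen=True)
class PiEstimate:
    """A probability-of-benefit estimate at a fixed delta, with inference."""

    value: float
    se: float
    ci: tuple[float, float]
    cell: CellIndex
    delta: float
    beta_hat: float
    method: str
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")
        if not (self.ci[0] <= self.value <= self.ci[1]):
            raise ValueError("confidence interval must contain the point estimate")


def _point_pi(data: TrialData, model: OutcomeModel, cell: CellIndex, delta: float):
    obs = data.margins()
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        beta_hat = estimate_beta(data, model, cell)
        value = pi_from_delta(cell, delta, beta_hat, obs)
    for w in caught:
        if issubclass(w.category, (IncompatibleValueWarning, GuardWarning)):
            flags.append(str(w.message))
            warnings.warn_explicit(
                w.message, w.category, w.filename, w.lineno
            )
    return value, beta_hat, flags


def estimate_pi(
    data: TrialData,
    model: OutcomeModel,
    cell,
    delta: float,
    method: str = "sandwich",
    B: int = 1000,
    seed: int | None = None,
) -> PiEstimate:
    """Estimate pi at the supplied delta, with a 95% Wald interval.

    ``method``: ``'sandwich'`` (joint logistic models), ``'bootstrap'``
    (any model; B resamples, model refitted each time), or ``'none'``
    (point estimate only, se = 0).
    """
    cell = CellIndex.of(cell)
    value, beta_hat, flags = _point_pi(data, model, cell, delta)
    if method == "none":
        se, ci = 0.0, (value, value)
    elif method == "sandwich":
        se = sandwich_se(data, model, cell, delta)
        ci = (value - Z_NORM * se, value + Z_NORM * se)
    elif method == "bootstrap":
        se, ci, _ci_pct, n_redrawn = bootstrap_ci(
            data, (model.formula, model.mode), cell, delta, B=B, seed=seed
        )
        if n_redrawn:
            flags.append(f"{n_redrawn} bootstrap resamples redrawn (empty stratum)")
    else:
        raise ValueError(f"unknown inference method {method!r}")
    return PiEstimate(
        value=value,
        se=se,
        ci=ci,
        cell=cell,
        delta=delta,
        beta_hat=beta_hat,
        method=method,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# sandwich variance


def _pi_formula_derivs(cell: CellIndex, delta: float, e: float, m0: float, m1: float):
    """Value and partials of the pi formula w.r.t. (e, m0, m1), where
    e = expit(beta) is the stratum-mean prediction."""
    h = float(expit(delta + math.log(e / (1.0 - e))))
    hp = h * (1.0 - h) / (e * (1.0 - e))  # dh/de
    if cell == (1, 0):
        g = (1.0 - m0) * h
        de, dm0, dm1 = (1.0 - m0) * hp, -h, 0.0
    elif cell == (0, 1):
        g = m1 * (1.0 - h)
        de, dm0, dm1 = -m1 * hp, 0.0, 1.0 - h
    elif cell == (1, 1):
        g = m1 - m0 * h
        de, dm0, dm1 = -m0 * hp, -h, 1.0
    else:  # (0, 0)
        g = (1.0 - m0) - (1.0 - m1) * (1.0 - h)
        de, dm0, dm1 = (1.0 - m1) * hp, -1.0, 1.0 - h
    return g, de, dm0, dm1


def sandwich_se(data: TrialData, model: OutcomeModel, cell, delta: float) -> float:
    """M-estimation sandwich standard error of pi_hat at fixed delta.

    Stacks the logistic score, the stratum-mean prediction equation behind
    the beta plug-in, the two arm-wise outcome-proportion equations, and the
    pi identification formula; delta enters as a known constant.  Requires a
    jointly fitted logistic model (use the bootstrap otherwise).
    """
    cell = CellIndex.of(cell)
    if model.mode != "joint":
        raise ValueError(
            "sandwich_se requires a jointly fitted logistic model; "
            "use bootstrap_ci for per-arm or custom models"
        )
    n = data.n
    y_out = data.Y
    w_obs = model.design(data)
    w_cf = model.design(data, arm=cell.x)
    gamma = np.asarray(model.params, dtype=float)
    k = w_obs.shape[1]

    mu = np.asarray(expit(w_obs @ gamma))
    px = np.asarray(expit(w_cf @ gamma))
    s = data.stratum_mask(cell).astype(float)
    i0 = (data.X == 0).astype(float)
    i1 = (data.X == 1).astype(float)

    e = float((s * px).sum() / s.sum())
    m0 = float((i0 * y_out).sum() / i0.sum())
    m1 = float((i1 * y_out).sum() / i1.sum())
    _, dg_de, dg_dm0, dg_dm1 = _pi_formula_derivs(cell, delta, e, m0, m1)

    p = k + 4  # gamma, e, m0, m1, pi
    psi = np.zeros((n, p))
    psi[:, :k] = (y_out - mu)[:, None] * w_obs
    psi[:, k] = s * (px - e)
    psi[:, k + 1] = i0 * (y_out - m0)
    psi[:, k + 2] = i1 * (y_out - m1)
    # pi equation: g(e, m0, m1) - pi == 0 identically at the solution

    bread = np.zeros((p, p))
    bread[:k, :k] = -(w_obs * (mu * (1 - mu))[:, None]).T @ w_obs / n
    bread[k, :k] = (s * px * (1 - px)) @ w_cf / n
    bread[k, k] = -s.mean()
    bread[k + 1, k + 1] = -i0.mean()
    bread[k + 2, k + 2] = -i1.mean()
    bread[k + 3, k] = dg_de
    bread[k + 3, k + 1] = dg_dm0
    bread[k + 3, k + 2] = dg_dm1
    bread[k + 3, k + 3] = -1.0

    meat = psi.T @ psi / n
    try:
        binv = np.linalg.solve(bread, np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ModelFitError(
            "singular bread matrix in the sandwich variance; "
            "consider bootstrap inference instead"
        ) from exc
    var = binv @ meat @ binv.T / n
    return float(math.sqrt(max(var[-1, -1], 0.0)))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(
    data: TrialData,
    model_spec: tuple[str | None, str],
    cell,
    delta: float,
    B: int = 1000,
    seed: int | None = None,
    max_redraws: int = 100,
):
    """Nonparametric bootstrap of the whole pipeline (refit per resample).

    Returns ``(se, ci_normal, ci_percentile, n_redrawn)``.  Resamples with an
    empty (Y=y, X=1-x) stratum or a failed refit are redrawn and counted.
    Deterministic given ``seed``.
    """
    cell = CellIndex.of(cell)
    if B < 2:
        raise ValueError("B must be at least 2")
    formula, mode = model_spec
    rng = np.random.default_rng(seed)
    point = _point_pi(data, fit_outcome_model(data, formula, mode), cell, delta)[0]
    values = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for attempt in range(max_redraws):
            boot = data.resample(rng)
            if not boot.stratum_mask(cell).any() or boot.Y[boot.X == 0].size == 0:
                n_redrawn += 1
                continue
            try:
                bm = fit_outcome_model(boot, formula, mode)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    values[b] = _point_pi(boot, bm, cell, delta)[0]
                break
            except (ModelFitError, ValueError):
                n_redrawn += 1
        else:
            raise RuntimeError(
                f"bootstrap resample {b} failed {max_redraws} consecutive redraws"
            )
    se = float(values.std(ddof=1))
    ci_normal = (point - Z_NORM * se, point + Z_NORM * se)
    ci_pct = tuple(float(q) for q in np.quantile(values, [0.025, 0.975]))
    return se, ci_normal, ci_pct, n_redrawn


# ---------------------------------------------------------------------------
# combination across cells, curves, bounds


def ivw_combine(
    estimates: list[PiEstimate],
    data: TrialData | None = None,
    model_spec: tuple[str | None, str] | None = None,
    B: int = 200,
    seed: int | None = None,
) -> PiEstimate:
    """Inverse-variance-weighted combination of per-cell estimates.

    Weights are 1/se^2; estimates with non-finite or zero SE are excluded
    with a warning.  When ``data`` and ``model_spec`` are supplied the
    combined SE is obtained by bootstrapping the whole combination pipeline
    (per resample: refit, re-link the deltas across cells from the first
    estimate's cell, re-estimate, re-combine); otherwise the naive
    1/sqrt(sum of weights) SE is reported and flagged as such.
    """
    usable = [est for est in estimates if math.isfinite(est.se) and est.se > 0]
    if len(usable) < 2:
        raise ValueError("ivw_combine needs at least two estimates with finite SE")
    if len(usable) < len(estimates):
        warnings.warn(
            f"{len(estimates) - len(usable)} estimate(s) dropped from the "
            "combination (non-finite or zero SE)",
            UserWarning,
            stacklevel=2,
        )
    w = np.array([1.0 / est.se**2 for est in usable])
    v = np.array([est.value for est in usable])
    value = float((w * v).sum() / w.sum())
    flags: tuple[str, ...] = ()
    if data is not None and model_spec is not None:
        se = _ivw_bootstrap_se(data, model_spec, usable, B=B, seed=seed)
        method = "ivw+bootstrap"
    else:
        se = float(1.0 / math.sqrt(w.sum()))
        method = "ivw"
        flags = ("naive SE: ignores cross-cell correlation",)
    lead = usable[0]
    return PiEstimate(
        value=value,
        se=se,
        ci=(value - Z_NORM * se, value + Z_NORM * se),
        cell=lead.cell,
        delta=lead.delta,
        beta_hat=lead.beta_hat,
        method=method,
        flags=flags,
    )


def _ivw_bootstrap_se(data, model_spec, estimates, B, seed):
    from .cells import convert_delta_cell

    formula, mode = model_spec
    base = estimates[0]
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        boot = data.resample(rng)
        try:
            boot.require_four_cells()
            bm = fit_outcome_model(boot, formula, mode)
            betas = {c: estimate_beta(boot, bm, c) for c in ALL_CELLS}
            deltas = {base.cell: base.delta}
            deltas.update(
                convert_delta_cell(base.cell, base.delta, betas, boot.margins())
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ests = [
                    estimate_pi(boot, bm, c, deltas[c], method="sandwich")
                    for c in ALL_CELLS
                ]
                usable = [e for e in ests if math.isfinite(e.se) and e.se > 0]
                wts = np.array([1.0 / e.se**2 for e in usable])
                vals.append(sum(wt * e.value for wt, e in zip(wts, usable)) / wts.sum())
        except (ValueError, ModelFitError):
            continue
    if len(vals) < 2:
        raise RuntimeError("ivw bootstrap produced fewer than 2 usable resamples")
    return float(np.std(vals, ddof=1))


@dataclass(frozen=True)
class SensitivityCurve:
    """Ordered (delta, PiEstimate) pairs plus the spanned uncertainty interval."""

    points: tuple[tuple[float, PiEstimate], ...]
    spanned: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "delta": d,
                    "pi_hat": est.value,
                    "se": est.se,
                    "ci_low": est.ci[0],
                    "ci_high": est.ci[1],
                    "beta_hat": est.beta_hat,
                    "flags": ";".join(est.flags),
                }
                for d, est in self.points
            ]
        )


def sensitivity_curve(
    data: TrialData,
    model: OutcomeModel,
    cell,
    delta_grid,
    method: str = "sandwich",
    endpoints_only: bool = False,
    B: int = 1000,
    seed: int | None = None,
) -> SensitivityCurve:
    """Evaluate pi_hat along a delta grid and report the spanned interval.

    pi is monotone in delta (increasing for y=0 cells, decreasing for y=1),
    so ``endpoints_only`` evaluates just min/max of the grid — the spanned
    interval (min lower CI bound, max upper CI bound) is unchanged.
    """
    cell = CellIndex.of(cell)
    grid = sorted(float(d) for d in delta_grid)
    if not grid:
        raise ValueError("delta grid must be non-empty")
    if endpoints_only and len(grid) > 2:
        grid = [grid[0], grid[-1]]
    points = tuple(
        (d, estimate_pi(data, model, cell, d, method=method, B=B, seed=seed))
        for d in grid
    )
    spanned = (
        min(est.ci[0] for _, est in points),
        max(est.ci[1] for _, est in points),
    )
    return SensitivityCurve(points=points, spanned=spanned)


def marginalized_bounds(data: TrialData, model: OutcomeModel) -> tuple[float, float]:
    """Covariate-marginalized nonparametric bounds for pi.

    Averages the conditional sharp bounds over the empirical Z distribution:
    lower = mean_i max{0, p_hat(1|1,Z_i) - p_hat(1|0,Z_i)},
    upper = mean_i min{p_hat(1|1,Z_i), 1 - p_hat(1|0,Z_i)}.
    With no covariates this equals the marginal bounds on the sample margins.
    """
    p1z = model.predict(data, arm=1)
    p0z = model.predict(data, arm=0)
    lower = float(np.maximum(0.0, p1z - p0z).mean())
    upper = float(np.minimum(p1z, 1.0 - p0z).mean())
    return lower, upper


def select_cell(data: TrialData, strategy: str = "variation-independent") -> CellIndex:
    """Default cell-selection strategies.

    ``'variation-independent'`` picks the cell whose delta range is
    unconstrained by the estimated margins; ``'largest-stratum'`` picks the
    cell whose (Y=y, X=1-x) stratum has the most subjects.
    """
    from .cells import variation_independent_cell

    if strategy == "variation-independent":
        return variation_independent_cell(data.margins().marginals)
    if strategy == "largest-stratum":
        return max(ALL_CELLS, key=lambda c: int(data.stratum_mask(c).sum()))
    raise ValueError(f"unknown cell-selection strategy {strategy!r}")
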