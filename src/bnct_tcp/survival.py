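"""Cell-survival curve models and constrained fitting to clonogenic data.

Four ln-survival models are provided:

* **LQ** — linear-quadratic, ``lnS = -(alpha*d + beta*d**2)``.
* **USC** — universal survival curve: LQ below a transition dose ``DT``,
  multi-target straight line ``lnS = -(d - Dq)/D0`` above it.  With the
  smooth-join constraint (value and slope continuous at ``DT``) the model
  has three free parameters ``(alpha, D0, Dq)``; ``beta`` and ``DT`` follow
  from ``beta = (1 - alpha*D0)**2 / (4*Dq*D0)`` and
  ``DT = 2*Dq / (1 - alpha*D0)``.
* **LQL** — linear-quadratic-linear: LQ below ``DT``, straight line above
  with slope ``gamma = alpha + 2*beta*DT`` (the LQ slope at ``DT``), so the
  curve is continuous and once-differentiable by construction.
* **PLQ** — Pade linear-quadratic, ``lnS = -(alpha*d + beta*d**2)/(1 + gamma*d)``,
  a rational softening of LQ that reduces to LQ at ``gamma = 0``.

Note that smooth-join USC and LQL parametrize the *same* family of curves
(the map ``(alpha, D0, Dq) -> (alpha, beta, DT)`` is a bijection on the
valid domain), so on any dataset their best attainable fit coincides; see
:func:`compare_models` for how ties are resolved.

Fits are least squares in lnS space.  Model quality is compared by the
standard error of the estimate (SEE), ``sqrt(SSR / (N - p))`` with ``p``
free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "SurvivalParamsLQ",
    "SurvivalParamsUSC",
    "SurvivalParamsLQL",
    "SurvivalParamsPLQ",
    "SurvivalDataset",
    "FitResult",
    "SCC_USC_PARAMS",
    "MODEL_KINDS",
    "ln_survival_lq",
    "ln_survival_usc",
    "ln_survival_lql",
    "ln_survival_plq",
    "ln_survival",
    "usc_transition_dose",
    "fit_survival_model",
    "standard_error_of_estimate",
    "compare_models",
    "read_survival_data",
    "write_survival_data",
]

DEFAULT_FIT_SEED = 20240229


def _check_dose(d):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    return d


@dataclass(frozen=True)
class SurvivalParamsLQ:
    """Linear-quadratic coefficients: alpha [1/Gy], beta [1/Gy^2]."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


@dataclass(frozen=True)
class SurvivalParamsUSC:
    """Universal survival curve coefficients.

    alpha [1/Gy] and beta [1/Gy^2] govern the low-dose LQ branch; the
    multi-target branch above the transition dose ``dt`` [Gy] is the line
    ``lnS = -(d - dq)/d0`` with slope ``-1/d0`` and extrapolation intercept
    ``dq`` (the quasi-threshold dose).  A smooth join requires
    ``dt = 2*dq/(1 - alpha*d0)``; this is validated to 1e-3 relative, as is
    continuity of lnS at ``dt``.
    """

    alpha: float
    beta: float
    d0: float
    dq: float
    dt: float

    def __post_init__(self):
        for name in ("alpha", "beta", "d0", "dq", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha * self.d0 >= 1:
            raise ValueError("alpha*d0 must be < 1 for a valid transition dose")
        dt_expected = usc_transition_dose(self.alpha, self.d0, self.dq)
        if abs(self.dt - dt_expected) > 1e-3 * dt_expected:
            raise ValueError(
                f"dt={self.dt} inconsistent with smooth join "
                f"2*dq/(1-alpha*d0)={dt_expected:.6g}"
            )
        lq = -(self.alpha * self.dt + self.beta * self.dt**2)
        mt = -(self.dt - self.dq) / self.d0
        if abs(lq - mt) > 1e-3 * abs(lq):
            raise ValueError("lnS not continuous at dt within 1e-3 relative")

    @classmethod
    def from_smooth_join(cls, alpha: float, d0: float, dq: float) -> "SurvivalParamsUSC":
        """Build a USC parameter set from the three free parameters,
        deriving beta and dt from the two continuity conditions."""
        if alpha * d0 >= 1:
            raise ValueError("alpha*d0 must be < 1")
        beta = (1 - alpha * d0) ** 2 / (4 * dq * d0)
        dt = usc_transition_dose(alpha, d0, dq)
        return cls(alpha=alpha, beta=beta, d0=d0, dq=dq, dt=dt)

    def to_lql(self) -> "SurvivalParamsLQL":
        """Equivalent LQL parametrization of the same curve."""
        return SurvivalParamsLQL.from_lq(self.alpha, self.beta, self.dt)


@dataclass(frozen=True)
class SurvivalParamsLQL:
    """Linear-quadratic-linear coefficients; gamma [1/Gy] is the LQ slope
    at the transition dose, making the curve C1 at ``dt``."""

    alpha: float
    beta: float
    dt: float
    gamma: float

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        expected = self.alpha + 2 * self.beta * self.dt
        if abs(self.gamma - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("gamma must equal alpha + 2*beta*dt")

    @classmethod
    def from_lq(cls, alpha: float, beta: float, dt: float) -> "SurvivalParamsLQL":
        return cls(alpha=alpha, beta=beta, dt=dt, gamma=alpha + 2 * beta * dt)

    def to_usc(self) -> SurvivalParamsUSC:
        """Equivalent smooth-join USC parametrization (always valid:
        d0 = 1/gamma gives alpha*d0 < 1 and dq = beta*dt^2/gamma > 0)."""
        d0 = 1.0 / self.gamma
        dq = self.beta * self.dt**2 / self.gamma
        return SurvivalParamsUSC.from_smooth_join(self.alpha, d0, dq)


@dataclass(frozen=True)
class SurvivalParamsPLQ:
    """Pade linear-quadratic coefficients: lnS = -(alpha*d + beta*d^2)/(1 + gamma*d)."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")


def usc_transition_dose(alpha: float, d0: float, dq: float) -> float:
    """Transition dose of the smooth-join USC model, ``2*dq/(1 - alpha*d0)``.

    This is the unique dose at which the LQ branch and the multi-target
    line agree in both value and slope.
    """
    if dq <= 0 or d0 <= 0:
        raise ValueError("d0 and dq must be positive")
    if alpha * d0 >= 1:
        raise ValueError("alpha*d0 >= 1: no valid transition dose")
    return 2 * dq / (1 - alpha * d0)


#: Published USC coefficients for squamous cell carcinoma (FaDu line):
#: alpha = 0.2111 /Gy, beta = 0.0890 /Gy^2, D0 = 0.9603 Gy, Dq = 1.8588 Gy,
#: DT = 4.6628 Gy.
SCC_USC_PARAMS = SurvivalParamsUSC(
    alpha=0.2111, beta=0.0890, d0=0.9603, dq=1.8588, dt=4.6628
)


def ln_survival_lq(d, p: SurvivalParamsLQ):
    """lnS for the LQ model, ``-(alpha*d + beta*d**2)``."""
    d = _check_dose(d)
    out = -(p.alpha * d + p.beta * d**2)
    return out if out.ndim else float(out)


def ln_survival_usc(d, p: SurvivalParamsUSC):
    """lnS for the USC model: LQ branch for d <= dt, multi-target line above."""
    d = _check_dose(d)
    lq = -(p.alpha * d + p.beta * d**2)
    mt = -(d - p.dq) / p.d0
    out = np.where(d <= p.dt, lq, mt)
    return out if out.ndim else float(out)


def ln_survival_lql(d, p: SurvivalParamsLQL):
    """lnS for the LQL model: LQ below dt, straight line of slope -gamma above."""
    d = _check_dose(d)
    lq = -(p.alpha * d + p.beta * d**2)
    lin = -(p.alpha * p.dt + p.beta * p.dt**2 + p.gamma * (d - p.dt))
    out = np.where(d <= p.dt, lq, lin)
    return out if out.ndim else float(out)


def ln_survival_plq(d, p: SurvivalParamsPLQ):
    """lnS for the PLQ model, ``-(alpha*d + beta*d**2)/(1 + gamma*d)``."""
    d = _check_dose(d)
    denom = 1 + p.gamma * d
    if np.any(denom <= 0):
        raise ValueError("1 + gamma*d must be positive")
    out = -(p.alpha * d + p.beta * d**2) / denom
    return out if out.ndim else float(out)


_LN_SURVIVAL = {
    SurvivalParamsLQ: ln_survival_lq,
    SurvivalParamsUSC: ln_survival_usc,
    SurvivalParamsLQL: ln_survival_lql,
    SurvivalParamsPLQ: ln_survival_plq,
}


def ln_survival(d, params):
    """Dispatch lnS evaluation on the parameter type."""
    return _LN_SURVIVAL[type(params)](d, params)


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class SurvivalDataset:
    """Clonogenic assay data: dose [Gy] vs surviving fraction in (0, 1]."""

    dose: np.ndarray
    survival: np.ndarray
    weight: Optional[np.ndarray] = None

    def __post_init__(self):
        dose = np.asarray(self.dose, dtype=float)
        survival = np.asarray(self.survival, dtype=float)
        if dose.shape != survival.shape or dose.ndim != 1:
            raise ValueError("dose and survival must be 1-D arrays of equal length")
        order = np.argsort(dose)
        dose, survival = dose[order], survival[order]
        if np.any(np.diff(dose) <= 0):
            raise ValueError("doses must be strictly increasing after sorting")
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        if np.any(survival <= 0) or np.any(survival > 1):
            raise ValueError("surviving fractions must lie in (0, 1]")
        w = self.weight
        if w is not None:
            w = np.asarray(w, dtype=float)[order]
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "survival", survival)
        object.__setattr__(self, "weight", w)

    def __len__(self):
        return self.dose.size

    @property
    def ln_survival(self) -> np.ndarray:
        return np.log(self.survival)


def read_survival_data(source: Union[str, Path]) -> SurvivalDataset:
    """Read a delimited survival table with columns dose_Gy, survival_fraction.

    Comma or tab separated (auto-detected); lines starting with ``#`` ignored.
    """
    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    missing = {"dose_Gy", "survival_fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"survival file missing columns: {sorted(missing)}")
    weight = df["weight"].to_numpy() if "weight" in df.columns else None
    return SurvivalDataset(
        dose=df["dose_Gy"].to_numpy(),
        survival=df["survival_fraction"].to_numpy(),
        weight=weight,
    )


def write_survival_data(data: SurvivalDataset, sink: Union[str, Path]) -> None:
    cols = {"dose_Gy": data.dose, "survival_fraction": data.survival}
    if data.weight is not None:
        cols["weight"] = data.weight
    pd.DataFrame(cols).to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# fitting

#: Model kinds in canonical (registry) order; also the tie-break order used
#: by :func:`compare_models`.
MODEL_KINDS = ("lq", "usc", "lql", "plq")

_N_FREE = {"lq": 2, "usc": 3, "lql": 3, "plq": 3}


@dataclass
class FitResult:
    """Outcome of a least-squares fit in lnS space."""

    model_kind: str
    params: object
    see: float
    residuals: np.ndarray = field(repr=False)
    n_points: int
    n_free_params: int
    sse: float
    message: str = ""

    def predict_ln_survival(self, d):
        return ln_survival(d, self.params)


class FitError(RuntimeError):
    """Raised when no restart of the optimizer converges; carries the
    best-so-far diagnostics in ``.diagnostics``."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def _weighted(res, w):
    return res if w is None else res * np.sqrt(w)


def _fit_lq(data: SurvivalDataset) -> tuple:
    y = data.ln_survival
    X = np.column_stack([-data.dose, -data.dose**2])
    if data.weight is not None:
        sw = np.sqrt(data.weight)[:, None]
        sol = optimize.lsq_linear(X * sw, y * sw[:, 0], bounds=(0, np.inf))
    else:
        sol = optimize.lsq_linear(X, y, bounds=(0, np.inf))
    alpha, beta = sol.x
    params = SurvivalParamsLQ(alpha=max(alpha, 0.0), beta=max(beta, 0.0))
    return params, "converged"


def _lhs_starts(bounds_lo, bounds_hi, n, seed):
    sampler = qmc.LatinHypercube(d=len(bounds_lo), seed=seed)
    u = sampler.random(n)
    lo, hi = np.asarray(bounds_lo), np.asarray(bounds_hi)
    return lo + u * (hi - lo)


def _best_local(fun, starts, lo, hi):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(
                fun, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # singular starts etc.
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _tail_line_start(data):
    """Heuristic (D0, Dq) start from a straight-line fit to the upper-dose
    half of the lnS data."""
    n = len(data)
    k = max(3, n // 2)
    d, y = data.dose[-k:], data.ln_survival[-k:]
    slope, intercept = np.polyfit(d, y, 1)
    if slope >= 0:
        return None
    d0 = -1.0 / slope
    dq = intercept * d0
    if dq <= 0:
        return None
    return d0, dq


def _fit_usc(data: SurvivalDataset, n_restarts, seed, extra_starts=()):
    """Fit the smooth-join USC family with free (alpha, u=alpha*d0, dq)."""
    y, d, w = data.ln_survival, data.dose, data.weight

    def unpack(x):
        alpha, u, dq = x
        d0 = u / alpha
        beta = alpha * (1 - u) ** 2 / (4 * dq * u)
        dt = 2 * dq / (1 - u)
        return alpha, beta, d0, dq, dt

    def fun(x):
        alpha, beta, d0, dq, dt = unpack(x)
        pred = np.where(d <= dt, -(alpha * d + beta * d**2), -(d - dq) / d0)
        return _weighted(pred - y, w)

    lo = np.array([1e-6, 1e-4, 1e-3])
    hi = np.array([5.0, 1 - 1e-6, 60.0])
    starts = list(_lhs_starts([0.02, 0.05, 0.3], [1.0, 0.9, 8.0], n_restarts, seed))
    tail = _tail_line_start(data)
    if tail is not None:
        d0_h, dq_h = tail
        lq, _ = _fit_lq(data)
        alpha_h = max(lq.alpha, 1e-4)
        if alpha_h * d0_h < 1 - 1e-6:
            starts.append([alpha_h, alpha_h * d0_h, dq_h])
    starts.extend(extra_starts)
    best = _best_local(fun, starts, lo, hi)
    if best is None:
        raise FitError("USC fit failed to converge from any start")
    alpha, beta, d0, dq, dt = unpack(best.x)
    return SurvivalParamsUSC(alpha=alpha, beta=beta, d0=d0, dq=dq, dt=dt), "converged"


def _usc_to_x(p: SurvivalParamsUSC):
    return [p.alpha, p.alpha * p.d0, p.dq]


def _fit_lql(data: SurvivalDataset, n_restarts, seed, extra_starts=()):
    """Fit LQL with free (alpha, beta, dt); gamma tied to the LQ slope at dt."""
    y, d, w = data.ln_survival, data.dose, data.weight

    def fun(x):
        alpha, beta, dt = x
        gamma = alpha + 2 * beta * dt
        pred = np.where(
            d <= dt,
            -(alpha * d + beta * d**2),
            -(alpha * dt + beta * dt**2 + gamma * (d - dt)),
        )
        return _weighted(pred - y, w)

    dmax = data.dose.max()
    lo = np.array([0.0, 1e-6, 1e-2])
    hi = np.array([5.0, 5.0, max(2 * dmax, 10.0)])
    starts = list(
        _lhs_starts([0.02, 0.01, 0.3], [1.0, 0.5, dmax], n_restarts, seed)
    )
    lq, _ = _fit_lq(data)
    for q in (0.3, 0.5, 0.7):
        starts.append([max(lq.alpha, 1e-3), max(lq.beta, 1e-3), q * dmax])
    starts.extend(extra_starts)
    best = _best_local(fun, starts, lo, hi)
    if best is None:
        raise FitError("LQL fit failed to converge from any start")
    alpha, beta, dt = best.x
    return SurvivalParamsLQL.from_lq(alpha, beta, dt), "converged"


def _lql_to_x(p: SurvivalParamsLQL):
    return [p.alpha, p.beta, p.dt]


def _fit_plq(data: SurvivalDataset, n_restarts, seed):
    y, d, w = data.ln_survival, data.dose, data.weight

    def fun(x):
        alpha, beta, gamma = x
        return _weighted(-(alpha * d + beta * d**2) / (1 + gamma * d) - y, w)

    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([5.0, 5.0, 5.0])
    starts = list(_lhs_starts([0.02, 0.01, 0.0], [1.0, 0.5, 0.5], n_restarts, seed))
    lq, _ = _fit_lq(data)
    starts.append([max(lq.alpha, 1e-3), max(lq.beta, 1e-3), 1e-3])
    best = _best_local(fun, starts, lo, hi)
    if best is None:
        raise FitError("PLQ fit failed to converge from any start")
    alpha, beta, gamma = best.x
    return SurvivalParamsPLQ(alpha=alpha, beta=beta, gamma=gamma), "converged"


def fit_survival_model(
    data: SurvivalDataset,
    model_kind: str,
    *,
    n_restarts: int = 10,
    seed: int = DEFAULT_FIT_SEED,
    _extra_starts=(),
) -> FitResult:
    """Least-squares fit of one survival model to clonogenic data in lnS space.

    For the USC model the transition dose is not free: beta and dt are
    derived from (alpha, d0, dq) by the smooth-join constraints.  Nonlinear
    models are fitted by bounded trust-region least squares from seeded
    Latin-hypercube restarts plus data-driven heuristic starts.
    """
    model_kind = model_kind.lower()
    if model_kind not in _N_FREE:
        raise ValueError(f"unknown model kind {model_kind!r}")
    p_free = _N_FREE[model_kind]
    if len(data) < p_free + 2:
        raise ValueError(
            f"need at least {p_free + 2} points to fit {model_kind}, got {len(data)}"
        )
    if model_kind == "lq":
        params, msg = _fit_lq(data)
    elif model_kind == "usc":
        params, msg = _fit_usc(data, n_restarts, seed, _extra_starts)
    elif model_kind == "lql":
        params, msg = _fit_lql(data, n_restarts, seed, _extra_starts)
    else:
        params, msg = _fit_plq(data, n_restarts, seed)
    residuals = data.ln_survival - ln_survival(data.dose, params)
    sse = float(np.sum(_weighted(residuals, data.weight) ** 2))
    see = math.sqrt(sse / (len(data) - p_free))
    return FitResult(
        model_kind=model_kind,
        params=params,
        see=see,
        residuals=residuals,
        n_points=len(data),
        n_free_params=p_free,
        sse=sse,
        message=msg,
    )


def standard_error_of_estimate(data: SurvivalDataset, model_kind: str, params) -> float:
    """SEE = sqrt( sum (lnS_obs - lnS_pred)^2 / (N - p) ), p free parameters."""
    model_kind = model_kind.lower()
    p = _N_FREE[model_kind]
    n = len(data)
    if n <= p:
        raise ValueError(f"need more than {p} points, got {n}")
    res = data.ln_survival - ln_survival(data.dose, params)
    sse = float(np.sum(_weighted(res, data.weight) ** 2))
    return math.sqrt(sse / (n - p))


#: SEE differences at or below this are treated as ties in compare_models.
SEE_TIE_TOL = 1e-8


def compare_models(
    data: SurvivalDataset,
    *,
    n_restarts: int = 10,
    seed: int = DEFAULT_FIT_SEED,
) -> list[FitResult]:
    """Fit all four models and rank them by ascending SEE.

    USC and LQL describe the same curve family, so their fits are
    cross-seeded from each other's optimum to ensure both reach the shared
    minimum.  SEE ties (|diff| <= 1e-8) are broken by fewer free parameters,
    then by the registry order LQ, USC, LQL, PLQ.  A model whose fit fails
    is ranked last with infinite SEE.
    """
    results: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for kind in MODEL_KINDS:
        try:
            results[kind] = fit_survival_model(
                data, kind, n_restarts=n_restarts, seed=seed
            )
        except (FitError, ValueError) as err:
            failures[kind] = str(err)
    if not results:
        raise ValueError(
            "no model could be fitted: " + "; ".join(
                f"{k}: {m}" for k, m in failures.items()
            )
        )

    # cross-seed the equivalent USC/LQL parametrizations
    if "usc" in results and "lql" in results:
        usc_fit, lql_fit = results["usc"], results["lql"]
        try:
            refit = fit_survival_model(
                data, "lql", n_restarts=0, seed=seed,
                _extra_starts=[_lql_to_x(usc_fit.params.to_lql())],
            )
            if refit.sse < lql_fit.sse:
                results["lql"] = refit
        except (FitError, ValueError):
            pass
        try:
            refit = fit_survival_model(
                data, "usc", n_restarts=0, seed=seed,
                _extra_starts=[_usc_to_x(results["lql"].params.to_usc())],
            )
            if refit.sse < usc_fit.sse:
                results["usc"] = refit
        except (FitError, ValueError):
            pass

    for kind, msg in failures.items():
        results[kind] = FitResult(
            model_kind=kind,
            params=None,
            see=math.inf,
            residuals=np.array([]),
            n_points=len(data),
            n_free_params=_N_FREE[kind],
            sse=math.inf,
            message=f"fit failed: {msg}",
        )

    order = {k: i for i, k in enumerate(MODEL_KINDS)}
    ranked = sorted(results.values(), key=lambda r: r.see)
    # regroup ties deterministically
    out: list[FitResult] = []
    i = 0
    while i < len(ranked):
        j = i
        while j + 1 < len(ranked) and ranked[j + 1].see - ranked[i].see <= SEE_TIE_TOL:
            j += 1
        group = sorted(
            ranked[i : j + 1],
            key=lambda r: (r.n_free_params, order[r.model_kind]),
        )
        out.extend(group)
        i = j + 1
    return out
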