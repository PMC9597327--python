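"""Measurement-model helpers and parameter estimation.

The measurement helpers convert raw assay readings into the model's
variables: UV absorbance to medium nitrate-nitrogen, the nitrogen-depletion
balance to the cell quota, and optical density to the biomass absorption
coefficient.

Calibration minimizes a weighted root-mean-square error between predicted
and observed biomass, medium nitrogen and quota over the sampling days,
using a derivative-free Nelder-Mead simplex.  The weights deliberately
emphasize the late growth phase (cultures are harvested near the end of a
batch): biomass residuals are weighted by the day-mean biomass, quota
residuals by the reciprocal day-mean quota, nitrogen residuals are
unweighted.  Parameters are log-transformed internally to enforce
positivity and the quota bounds are reparameterized as
``(Q_min, Q_max - Q_min)`` so that ``Q_min < Q_max`` by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import CultureState, KineticParameters, ReactorConfig, literature_initial_parameters
from .simulator import LightSchedule, SimulationOptions, predict_states

__all__ = [
    "ObservationSet",
    "FitSettings",
    "FitReport",
    "CorrelationFit",
    "nitrate_to_nitrogen",
    "quota_from_depletion",
    "ka_from_od",
    "weighted_nrmse",
    "fit_parameters",
    "estimate_initial_parameters",
    "fit_empirical_correlations",
]

#: nitrate assay calibration factor (absorbance per mg NO3 L^-1)
NITRATE_CALIBRATION = 0.06007
#: molecular weights of nitrogen and nitrate
MW_N, MW_NO3 = 14.0, 62.0
VARIABLES = ("X", "N", "Q")


# ---------------------------------------------------------------------------
# Measurement models
# ---------------------------------------------------------------------------

def nitrate_to_nitrogen(abs220: float, abs275: float, dilution_factor: float = 1.0) -> float:
    """Medium nitrogen (mg N L⁻¹) from UV absorbance at 220/275 nm.

    ``N = (14/62) * DF * (ABS220 - 2*ABS275) / 0.06007``; the 275 nm
    reading corrects for dissolved organic matter.  If the corrected
    absorbance is negative (organic interference exceeding the nitrate
    signal) a warning is issued and the concentration is floored at zero.
    """
    corrected = abs220 - 2.0 * abs275
    if corrected < 0:
        warnings.warn(
            f"ABS220 ({abs220}) < 2*ABS275 ({2 * abs275}): organic-matter "
            "interference; flooring nitrogen at 0",
            stacklevel=2,
        )
        return 0.0
    return (MW_N / MW_NO3) * dilution_factor * corrected / NITRATE_CALIBRATION


def quota_from_depletion(N0: float, N: float, DCW: float) -> float:
    """Nitrogen quota (mg N mg⁻¹ DCW) from the medium depletion balance,
    ``Q = (N0 - N) / DCW``: all nitrogen lost from the medium is assumed
    to reside in the biomass."""
    if DCW <= 0:
        raise ValueError(f"DCW must be > 0, got {DCW!r}")
    if N > N0:
        raise ValueError(f"N={N!r} exceeds initial N0={N0!r}: impossible uptake")
    return (N0 - N) / DCW


def ka_from_od(abs550: float, DCW: float) -> float:
    """Biomass absorption coefficient (L mg⁻¹ m⁻¹) from a 550 nm optical
    density in a 10 mm cuvette: ``Ka = ABS550 / (0.01 * DCW)``."""
    if DCW <= 0:
        raise ValueError(f"DCW must be > 0, got {DCW!r}")
    if abs550 < 0:
        raise ValueError("abs550 must be >= 0")
    return abs550 / (0.01 * DCW)


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Replicated measurements of X, N, Q on sampling days.

    ``data`` is tidy with columns ``day, replicate, variable, value``
    (variable in {X, N, Q}).  ``nitrogen_N0`` records the initial medium
    nitrogen, ``initial_biomass`` the known inoculum biomass — both are
    experiment metadata used by the fitting procedure, not fitted.
    """

    data: pd.DataFrame
    nitrogen_N0: float | None = None
    initial_biomass: float | None = None
    reactor_id: str = ""

    def __post_init__(self) -> None:
        required = {"day", "replicate", "variable", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        bad = set(self.data["variable"]) - set(VARIABLES)
        if bad:
            raise ValueError(f"unknown observation variables: {sorted(bad)}")
        if (self.data["value"] < 0).any():
            raise ValueError("negative measurements in observation set")

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.data["day"].unique())

    @property
    def variables(self) -> list[str]:
        return [v for v in VARIABLES if v in set(self.data["variable"])]

    @property
    def n_replicates(self) -> int:
        return int(self.data.groupby(["day", "variable"])["replicate"].nunique().max())

    def day_means(self, variable: str) -> pd.Series:
        sub = self.data[self.data["variable"] == variable]
        return sub.groupby("day")["value"].mean()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        nitrogen_N0: float | None = None,
        initial_biomass: float | None = None,
        reactor_id: str = "",
    ) -> "ObservationSet":
        return cls(
            data=pd.read_csv(path),
            nitrogen_N0=nitrogen_N0,
            initial_biomass=initial_biomass,
            reactor_id=reactor_id,
        )


def _weights(obs: ObservationSet) -> dict[str, pd.Series]:
    """Late-phase-emphasizing weights per variable and day.

    Biomass: the day-mean biomass (grows along the batch).  Quota: the
    reciprocal day-mean quota (the quota falls along the batch).
    Nitrogen: 1.  Day means are taken over the available replicates.
    """
    w: dict[str, pd.Series] = {}
    for var in obs.variables:
        means = obs.day_means(var)
        if var == "X":
            w[var] = means
        elif var == "Q":
            w[var] = 1.0 / means
        else:
            w[var] = pd.Series(1.0, index=means.index)
    return w


def weighted_nrmse(obs: ObservationSet, predicted: pd.DataFrame) -> float:
    """Weighted root-mean-square misfit between observations and a model
    trajectory sampled at the observation days.

    ``predicted`` is indexed by day with one column per observed variable.
    Returns ``sqrt( (1/(p q m)) * sum_k sum_j sum_i w_{k,j} (pred - obs)^2 )``
    where p = number of variables, q = number of days, m = replicate count.
    """
    variables = obs.variables
    days = obs.days
    missing = [
        (d, v)
        for v in variables
        for d in days
        if v not in predicted.columns or d not in predicted.index or pd.isna(predicted.loc[d, v])
    ]
    if missing:
        raise ValueError(f"missing predictions for (day, variable): {missing}")
    w = _weights(obs)
    p = len(variables)
    q = len(days)
    m = obs.n_replicates
    total = 0.0
    for var in variables:
        sub = obs.data[obs.data["variable"] == var]
        pred = predicted[var]
        for day, group in sub.groupby("day"):
            resid = group["value"].to_numpy() - float(pred.loc[day])
            total += float(w[var].loc[day]) * float(np.sum(resid**2))
    return float(np.sqrt(total / (p * q * m)))


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

#: parameters shown by one-at-a-time sensitivity analysis to be
#: essentially non-identifiable from batch growth data
WEAKLY_IDENTIFIED = ("K_d", "K_N", "U_max")


@dataclass
class FitSettings:
    """Options for :func:`fit_parameters`.

    ``free`` lists the parameters being fitted (any subset of the eight
    kinetic constants; the empirical-correlation coefficients are held
    fixed).  ``max_iter`` caps the simplex's outer iterations per start;
    ``restarts`` re-launches the simplex from a jittered copy of the best
    point, which makes the derivative-free search robust to the ridges of
    the weighted objective.  ``rel_ftol``/``stall_window`` implement the
    stop-when-flat rule: the fit is flagged converged when the objective
    improves by less than ``rel_ftol`` over ``stall_window`` outer
    iterations.
    """

    free: tuple[str, ...] = ("mu_max", "K_I", "n", "Q_min", "Q_max")
    max_iter: int = 50
    restarts: int = 1
    rel_ftol: float = 0.01
    stall_window: int = 15
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-8
    q0_policy: str = "replete"  # inoculum quota = candidate Q_max


@dataclass
class FitReport:
    fitted: KineticParameters
    initial: KineticParameters
    nrmse_path: list[float]
    converged: bool
    n_iterations: int
    final_nrmse: float
    initial_nrmse: float
    residual_rms: dict[str, float] = field(default_factory=dict)

    def iteration_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(len(self.nrmse_path)), "nrmse": self.nrmse_path}
        )


def _pack(p: KineticParameters, free: tuple[str, ...]) -> np.ndarray:
    """Log-parameterize; the (Q_min, Q_max) pair becomes (Q_min, Q_max - Q_min)."""
    vals = []
    for name in free:
        if name == "Q_max":
            vals.append(p.Q_max - p.Q_min)
        else:
            vals.append(getattr(p, name))
    v = np.asarray(vals, dtype=float)
    if np.any(v <= 0):
        raise ValueError("free parameters must be strictly positive at the start")
    return np.log(v)


def _unpack(theta: np.ndarray, base: KineticParameters, free: tuple[str, ...]) -> KineticParameters:
    changes: dict[str, float] = {}
    vals = np.exp(theta)
    for name, v in zip(free, vals):
        changes[name] = float(v)
    if "Q_max" in changes:
        q_min = changes.get("Q_min", base.Q_min)
        changes["Q_max"] = q_min + changes["Q_max"]
    return base.replace(**changes)


def fit_parameters(
    obs: ObservationSet,
    reactor: ReactorConfig,
    schedule: LightSchedule,
    init: KineticParameters,
    settings: FitSettings | None = None,
) -> FitReport:
    """Estimate kinetic parameters by Nelder-Mead minimization of the
    weighted NRMSE.

    The initial culture state is taken from the observation metadata
    (``initial_biomass``, ``nitrogen_N0``); the inoculum quota is the
    candidate ``Q_max`` (nutrient-replete inoculum) unless
    ``settings.q0_policy`` says otherwise.  Parameters outside
    ``settings.free`` are frozen at their ``init`` values.
    """
    settings = settings or FitSettings()
    init.validate()
    if len(obs.days) < 2:
        raise ValueError("insufficient data: need observations on at least 2 days")
    if len(obs.variables) < 2:
        raise ValueError("insufficient data: need at least 2 observed variables")
    if obs.nitrogen_N0 is None or obs.initial_biomass is None:
        raise ValueError("observation metadata must define nitrogen_N0 and initial_biomass")
    unknown = set(settings.free) - set(KineticParameters.ODE_FIELDS)
    if unknown:
        raise ValueError(f"cannot fit unknown/frozen fields: {sorted(unknown)}")

    days = obs.days.astype(float)
    sim_options = SimulationOptions(rtol=settings.rtol, atol=settings.atol, points_per_day=1)
    rng = np.random.default_rng(settings.seed)
    variables = obs.variables

    def objective(theta: np.ndarray) -> float:
        try:
            p = _unpack(theta, init, settings.free)
            p.validate()
            q0 = p.Q_max if settings.q0_policy == "replete" else min(init.Q_max, p.Q_max)
            state0 = CultureState(X=obs.initial_biomass, N=obs.nitrogen_N0, Q=q0, t=0.0)
            pred = predict_states(state0, reactor, schedule, p, days, sim_options)
        except (ValueError, RuntimeError):
            return 1e6
        if not np.isfinite(pred).all():
            return 1e6
        frame = pd.DataFrame(pred, index=days, columns=["X", "N", "Q"])
        return weighted_nrmse(obs, frame[variables])

    theta0 = _pack(init, settings.free)
    running_best = {"f": np.inf}

    def tracked_objective(theta: np.ndarray) -> float:
        f = objective(theta)
        if f < running_best["f"]:
            running_best["f"] = f
        return f

    f0 = tracked_objective(theta0)
    # best-so-far objective recorded once per outer simplex iteration
    path: list[float] = [f0]
    best_theta, best_f = theta0.copy(), f0

    theta_start = theta0.copy()
    for restart in range(settings.restarts + 1):
        res = optimize.minimize(
            tracked_objective,
            theta_start,
            method="Nelder-Mead",
            callback=lambda xk: path.append(running_best["f"]),
            options=dict(maxiter=settings.max_iter, xatol=1e-7, fatol=1e-11, adaptive=True),
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(
                f"non-finite objective during fit; best so far NRMSE={best_f:.4g}, "
                f"parameters {_unpack(best_theta, init, settings.free).to_dict()}"
            )
        if res.fun < best_f:
            best_theta, best_f = res.x.copy(), float(res.fun)
        # a five-order-of-magnitude collapse of the objective means the
        # simplex has found the basin; further restarts are wasted work
        if best_f <= 1e-5 * max(f0, 1e-12):
            break
        # alternate exploration (fresh start near the initial guess) with
        # exploitation (jitter around the best point): the weighted
        # objective has a deceptive ridge that pure best-point jitter
        # cannot always escape
        if restart % 2 == 0:
            theta_start = theta0 + rng.normal(0.0, 0.2, size=len(theta0))
        else:
            theta_start = best_theta + rng.normal(0.0, 0.1, size=len(best_theta))

    fitted = _unpack(best_theta, init, settings.free)
    fitted.validate()

    # per-variable unweighted residual RMS at the optimum
    q0 = fitted.Q_max if settings.q0_policy == "replete" else min(init.Q_max, fitted.Q_max)
    state0 = CultureState(X=obs.initial_biomass, N=obs.nitrogen_N0, Q=q0, t=0.0)
    pred = predict_states(state0, reactor, schedule, fitted, days, sim_options)
    frame = pd.DataFrame(pred, index=days, columns=["X", "N", "Q"])
    residual_rms = {}
    for var in variables:
        sub = obs.data[obs.data["variable"] == var]
        r = sub["value"].to_numpy() - frame[var].loc[sub["day"]].to_numpy()
        residual_rms[var] = float(np.sqrt(np.mean(r**2)))

    window = min(settings.stall_window, len(path) - 1)
    stalled = (
        window > 0
        and path[-1 - window] > 0
        and (path[-1 - window] - path[-1]) / path[-1 - window] < settings.rel_ftol
    )
    converged = bool(best_f <= f0 and (stalled or best_f < 1e-8 * max(f0, 1.0)))
    return FitReport(
        fitted=fitted,
        initial=init,
        nrmse_path=path,
        converged=converged,
        n_iterations=len(path) - 1,
        final_nrmse=best_f,
        initial_nrmse=f0,
        residual_rms=residual_rms,
    )


def estimate_initial_parameters(
    od_series: pd.Series | None = None,
    quota_pair: tuple[float, float] | None = None,
) -> KineticParameters:
    """Pre-fit starting values.

    ``mu_max`` is the slope of ``ln(OD)`` against time over the supplied
    exponential-phase optical-density series (index = day); the quota
    bounds come from measured quotas on a nitrogen-replete early day and a
    depleted late day (``quota_pair = (Q_early, Q_late)`` giving
    ``Q_max, Q_min``).  Everything not supplied falls back to the
    literature defaults.
    """
    p = literature_initial_parameters()
    changes: dict[str, float] = {}
    if od_series is not None:
        if len(od_series) < 3:
            raise ValueError("need >= 3 exponential-phase OD points")
        if (od_series.to_numpy() <= 0).any():
            raise ValueError("OD values must be positive")
        if not np.all(np.diff(od_series.to_numpy()) > 0):
            warnings.warn("OD series is not monotonically increasing", stacklevel=2)
        slope = stats.linregress(od_series.index.to_numpy(dtype=float), np.log(od_series.to_numpy()))
        changes["mu_max"] = float(slope.slope)
    if quota_pair is not None:
        q_early, q_late = quota_pair
        changes["Q_max"] = float(q_early)
        changes["Q_min"] = float(q_late)
    return p.replace(**changes) if changes else p


@dataclass
class CorrelationFit:
    ka_slope: float | None = None
    ka_intercept: float | None = None
    tfa_coeff: float | None = None
    tfa_exponent: float | None = None
    tfa_offset: float | None = None


def fit_empirical_correlations(
    q_ka: pd.DataFrame | None = None,
    q_tfa: pd.DataFrame | None = None,
) -> CorrelationFit:
    """Refit the quota correlations from paired records.

    ``q_ka``: columns ``Q, Ka`` — ordinary least-squares line.
    ``q_tfa``: columns ``Q, TFA`` — damped (Levenberg-Marquardt)
    least-squares fit of ``a * Q**(-b) + c`` with positivity enforced by
    log-parameterization.
    """
    out = CorrelationFit()
    if q_ka is not None:
        if len(q_ka) < 3:
            raise ValueError("need >= 3 (Q, Ka) pairs")
        res = stats.linregress(q_ka["Q"], q_ka["Ka"])
        out.ka_slope = float(res.slope)
        out.ka_intercept = float(res.intercept)
    if q_tfa is not None:
        if len(q_tfa) <= 3:
            raise ValueError("need > 3 (Q, TFA) pairs for the 3-parameter power law")
        qv = q_tfa["Q"].to_numpy(dtype=float)
        tv = q_tfa["TFA"].to_numpy(dtype=float)
        if np.any(qv <= 0):
            raise ValueError("Q must be > 0")

        def residuals(theta):
            a, b, c = np.exp(theta)
            return a * qv ** (-b) + c - tv

        theta0 = np.log([3.0, 1.0, max(tv.min() * 0.5, 1.0)])
        res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=10000)
        if not res.success:
            raise RuntimeError(f"power-law fit failed: {res.message}")
        a, b, c = np.exp(res.x)
        out.tfa_coeff, out.tfa_exponent, out.tfa_offset = float(a), float(b), float(c)
    return out
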