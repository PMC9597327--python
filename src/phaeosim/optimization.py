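"""Harvest-strategy grid search and one-at-a-time parameter sensitivity.

The repeated-batch design space is two-dimensional — the harvest interval
(days between harvests) and the harvest fraction (volume share replaced by
fresh medium).  Each grid cell is an independent repeated-batch
simulation, so the search is embarrassingly parallel in principle; cells
that fail are recorded per-cell and do not abort the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CultureState, KineticParameters, ReactorConfig
from .simulator import (
    HarvestPolicy,
    LightSchedule,
    SimulationOptions,
    biomass_productivity,
    overall_productivity,
    simulate_batch,
    simulate_repeated_batch,
)

__all__ = [
    "HarvestGridResult",
    "SensitivityReport",
    "harvest_grid_search",
    "productivity_vs_cycles",
    "sensitivity_one_at_a_time",
]

DEFAULT_INTERVALS = tuple(range(1, 8))                 # 1..7 days
DEFAULT_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(1, 10))  # 10..90 %


@dataclass
class HarvestGridResult:
    """Productivity matrix over (interval, fraction) plus context.

    ``productivity`` is indexed by interval (rows) and fraction (columns),
    in mg L⁻¹ day⁻¹.  ``batch_baseline`` gives, per interval, the
    productivity of a plain batch run for the same total duration.
    ``argmax`` is the set of maximizing cells (ties reported together).
    """

    productivity: pd.DataFrame
    batch_baseline: pd.Series
    argmax: list[tuple[float, float]]
    max_productivity: float
    improvement_over_batch_pct: float
    errors: dict[tuple[float, float], str] = field(default_factory=dict)

    def to_long_csv(self, path: str | Path) -> None:
        long = self.productivity.stack().rename("productivity_mg_L_day").reset_index()
        long.columns = ["interval_days", "fraction", "productivity_mg_L_day"]
        long.to_csv(path, index=False)

    def contour_plot(self, path: str | Path) -> None:
        """Optional contour artifact (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        F, I = np.meshgrid(self.productivity.columns, self.productivity.index)
        cs = ax.contourf(I, 100 * F, self.productivity.to_numpy(), levels=14, cmap="viridis")
        fig.colorbar(cs, ax=ax, label="biomass productivity (mg L$^{-1}$ day$^{-1}$)")
        ax.set_xlabel("harvest interval (days)")
        ax.set_ylabel("harvest fraction (%)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def harvest_grid_search(
    reactor: ReactorConfig,
    schedule: LightSchedule,
    p: KineticParameters,
    initial: CultureState,
    refresh_nitrogen_N0: float,
    batch_days: float = 8.0,
    intervals=DEFAULT_INTERVALS,
    fractions=DEFAULT_FRACTIONS,
    n_cycles: int = 4,
    options: SimulationOptions | None = None,
) -> HarvestGridResult:
    """Evaluate the repeated-batch productivity over a harvest grid.

    Each cell runs ``batch_days`` of batch growth followed by ``n_cycles``
    harvest cycles and reports the overall productivity (harvested plus
    standing biomass gain per litre per elapsed day).  The batch baseline
    for an interval is a plain batch of the same total duration, judged by
    the batch productivity DCW(t)/t at that duration.
    """
    options = options or SimulationOptions()
    matrix = pd.DataFrame(
        np.nan, index=pd.Index(list(intervals), name="interval_days"),
        columns=pd.Index(list(fractions), name="fraction"),
    )
    errors: dict[tuple[float, float], str] = {}
    baseline = {}
    for interval in intervals:
        total_days = batch_days + n_cycles * interval
        batch = simulate_batch(initial, reactor, schedule, p, total_days, options)
        baseline[interval] = float(
            biomass_productivity(batch, mode="instantaneous_batch").iloc[-1]
        )
        for fraction in fractions:
            policy = HarvestPolicy(
                batch_days=batch_days,
                interval=float(interval),
                fraction=float(fraction),
                refresh_nitrogen_N0=refresh_nitrogen_N0,
                n_cycles=n_cycles,
            )
            try:
                result = simulate_repeated_batch(initial, reactor, schedule, p, policy, options)
                matrix.loc[interval, fraction] = overall_productivity(result)
            except Exception as exc:  # per-cell failure is data, not fatal
                errors[(float(interval), float(fraction))] = str(exc)
    best = float(np.nanmax(matrix.to_numpy()))
    argmax = [
        (float(i), float(f))
        for i in matrix.index
        for f in matrix.columns
        if np.isclose(matrix.loc[i, f], best, rtol=1e-12, atol=1e-9)
    ]
    base_at_best = baseline[argmax[0][0]]
    return HarvestGridResult(
        productivity=matrix,
        batch_baseline=pd.Series(baseline, name="batch_productivity_mg_L_day"),
        argmax=argmax,
        max_productivity=best,
        improvement_over_batch_pct=100.0 * (best / base_at_best - 1.0),
        errors=errors,
    )


def productivity_vs_cycles(
    reactor: ReactorConfig,
    schedule: LightSchedule,
    p: KineticParameters,
    initial: CultureState,
    policy: HarvestPolicy,
    max_cycles: int = 8,
    options: SimulationOptions | None = None,
) -> pd.Series:
    """Overall productivity as a function of the number of harvest cycles
    (same batch period, interval and fraction)."""
    values = {}
    for n in range(1, max_cycles + 1):
        pol = HarvestPolicy(
            batch_days=policy.batch_days,
            interval=policy.interval,
            fraction=policy.fraction,
            refresh_nitrogen_N0=policy.refresh_nitrogen_N0,
            n_cycles=n,
        )
        result = simulate_repeated_batch(initial, reactor, schedule, p, pol, options)
        values[n] = overall_productivity(result)
    return pd.Series(values, name="productivity_mg_L_day").rename_axis("n_cycles")


@dataclass
class SensitivityReport:
    """Per-parameter relative response of the final state to ±perturbation.

    ``table`` rows: scenario, parameter, direction (+/-), pct_change_X,
    pct_change_Q — the percentage changes of the final biomass and final
    quota relative to the unperturbed run.
    """

    table: pd.DataFrame
    perturbation: float

    def ranking(self, scenario: str, variable: str = "pct_change_X") -> pd.Series:
        sub = self.table[self.table["scenario"] == scenario]
        return (
            sub.groupby("parameter")[variable]
            .apply(lambda s: np.max(np.abs(s)))
            .sort_values(ascending=False)
        )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sensitivity_one_at_a_time(
    reactor: ReactorConfig,
    schedule: LightSchedule,
    p: KineticParameters,
    scenarios: dict[str, tuple[CultureState, float]],
    perturbation: float = 0.2,
    parameters: tuple[str, ...] = KineticParameters.ODE_FIELDS,
    options: SimulationOptions | None = None,
) -> SensitivityReport:
    """One-at-a-time sensitivity of final biomass and final quota.

    Each of the kinetic constants is varied by ±``perturbation`` (default
    ±20%) with the others held fixed, under each scenario
    ``name -> (initial state, duration)``.  A zero perturbation returns
    zero change by construction.
    """
    options = options or SimulationOptions()
    rows = []
    for name, (initial, duration) in scenarios.items():
        base = simulate_batch(initial, reactor, schedule, p, duration, options)
        X_ref = float(base.frame["X_mg_L"].iloc[-1])
        Q_ref = float(base.frame["Q_mgN_mgDCW"].iloc[-1])
        for param in parameters:
            for sign, label in ((+1.0, "+"), (-1.0, "-")):
                if perturbation == 0.0 and sign < 0:
                    continue
                factor = 1.0 + sign * perturbation
                pp = p.replace(**{param: getattr(p, param) * factor})
                init_p = initial
                if param in ("Q_min", "Q_max"):
                    # keep the inoculum quota admissible for the perturbed bounds
                    q0 = min(max(initial.Q, pp.Q_min), pp.Q_max)
                    init_p = CultureState(X=initial.X, N=initial.N, Q=q0, t=initial.t)
                run = simulate_batch(init_p, reactor, schedule, pp, duration, options)
                rows.append(
                    {
                        "scenario": name,
                        "parameter": param,
                        "direction": label,
                        "pct_change_X": 100.0 * (float(run.frame["X_mg_L"].iloc[-1]) / X_ref - 1.0),
                        "pct_change_Q": 100.0 * (float(run.frame["Q_mgN_mgDCW"].iloc[-1]) / Q_ref - 1.0),
                    }
                )
    return SensitivityReport(table=pd.DataFrame(rows), perturbation=perturbation)
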