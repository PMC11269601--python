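"""Nonlinear least-squares fitting, BIC model comparison, and the
offline-learning proportion.

Each model is fitted to one group's participant-averaged sequence RTs by
bounded least squares.  Starting values come from a grid search: the
residual sum of squares is evaluated at every point of a parameter grid,
and bounded trust-region descent (``scipy.optimize.least_squares``) is
started from the best ``n_starts`` grid points; the best converged
solution wins.  All parameters are bounded below by 1e-12 (the models
constrain them to be positive); the hybridJ allocation parameter j is
additionally bounded above by Stot/Btot, the all-offline limit.

Model comparison uses BIC = n*ln(RSS/n) + h*ln(n) with n the number of
averaged observations (Stot per group) and h the free-parameter count;
lower is better.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import ModelParams, ModelSpec, get_model, predict_rt
from .trial_design import DesignConstants

__all__ = [
    "POSITIVE_LB", "FitResult", "bic", "default_grid", "fit_model",
    "fit_all", "offline_proportion", "comparison_frame",
]

#: Lower bound standing in for the strict positivity constraint.
POSITIVE_LB = 1e-12


def bic(n: int, rss: float, h: int) -> float:
    """Bayesian information criterion for a least-squares fit."""
    if n <= 0 or h < 1:
        raise ValueError("need n > 0 and h >= 1")
    if rss <= 0:
        raise ValueError("RSS must be > 0 (degenerate perfect fit)")
    return n * np.log(rss / n) + h * np.log(n)


@dataclass
class FitResult:
    """Converged parameters and fit diagnostics for one (group, model)."""

    model: str
    params: ModelParams
    rss: float
    n: int
    h: int
    bic: float
    n_starts: int
    converged: bool
    nfev: int = 0

    def asdict(self) -> dict:
        return {
            "model": self.model, "params": self.params.asdict(),
            "rss": self.rss, "n": self.n, "h": self.h, "bic": self.bic,
            "n_starts": self.n_starts, "converged": self.converged,
            "nfev": self.nfev,
        }


#: Default grid of starting values; spans the parameter magnitudes seen
#: in practice (y around 8-32 ms/sequence, z around 1-19 ms/trial) with
#: margin.  j is gridded as fractions of its design bound Stot/Btot.
_BASE_GRID = {
    "a": (500.0, 1000.0, 2000.0, 3000.0),
    "b": (500.0, 1000.0, 2000.0),
    "c": (1e-4, 1e-3, 1e-2, 1e-1),
    "k": (1e-3, 1e-2, 1e-1, 0.5),
    "y": (1.0, 10.0, 30.0),
    "z": (0.5, 5.0, 20.0),
    "g": (10.0, 100.0),
}
_J_FRACTIONS = (0.0, 0.25, 0.5, 0.75)


def default_grid(model: ModelSpec | str,
                 consts: DesignConstants) -> dict[str, tuple[float, ...]]:
    spec = get_model(model) if isinstance(model, str) else model
    grid = {}
    for name in spec.param_names:
        if name == "j":
            grid[name] = tuple(f * consts.j_max for f in _J_FRACTIONS)
        else:
            grid[name] = _BASE_GRID[name]
    return grid


def _bounds(spec: ModelSpec, consts: DesignConstants):
    lo, hi = [], []
    for name in spec.param_names:
        if name == "j":
            lo.append(0.0)
            hi.append(consts.j_max)
        else:
            lo.append(POSITIVE_LB)
            hi.append(np.inf)
    return np.array(lo), np.array(hi)


def fit_model(model: ModelSpec | str, series: pd.DataFrame,
              schedule: pd.DataFrame, consts: DesignConstants,
              grid: dict[str, tuple[float, ...]] | None = None,
              extra_starts: list[ModelParams] | None = None,
              n_starts: int = 8, seed: int | None = None,
              ftol: float = 1e-12, max_nfev: int = 10_000) -> FitResult:
    """Fit one model to one group's averaged RTs.

    ``series`` carries an ``rt_mean`` column aligned row-for-row with
    ``schedule``.  The grid is screened by RSS; local descent runs from
    the ``n_starts`` best points (plus any ``extra_starts``, always
    descended, e.g. a nested model's solution).  The procedure is fully
    deterministic for a given data/grid/starts configuration; ``seed`` is
    recorded for provenance only.
    """
    spec = get_model(model) if isinstance(model, str) else model
    obs = series["rt_mean"].to_numpy(dtype=float)
    if len(obs) != consts.n_obs:
        raise ValueError(
            f"series has {len(obs)} rows, schedule expects {consts.n_obs}")
    if grid is None:
        grid = default_grid(spec, consts)
    names = spec.param_names
    lo, hi = _bounds(spec, consts)
    # plain-array view of the schedule: avoids per-call pandas overhead in
    # the grid screen and descent
    sched = {c: schedule[c].to_numpy(dtype=float)
             for c in ("trial", "trial_cum", "trial_test", "st", "s", "x")}

    def residuals(x: np.ndarray) -> np.ndarray:
        p = ModelParams.from_array(names, np.maximum(x, POSITIVE_LB))
        return predict_rt(spec, p, sched, consts) - obs

    # grid screen: RSS at every grid point, keep the best n_starts
    combos = np.array(list(itertools.product(*(grid[n] for n in names))))
    rss_grid = np.array([float(np.sum(residuals(x) ** 2)) for x in combos])
    order = np.argsort(rss_grid, kind="stable")[:n_starts]
    starts = [combos[i] for i in order]
    for p in extra_starts or []:
        starts.append(np.clip(p.to_array(names), lo, hi))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, np.where(np.isinf(hi), x0, hi))
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                method="trf", x_scale="jac",
                                ftol=ftol, xtol=1e-12, gtol=1e-12,
                                max_nfev=max_nfev)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        key = (rss, sol.nfev)
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        # no start converged: report the best raw grid point
        i = int(np.argmin(rss_grid))
        params = ModelParams.from_array(names, combos[i])
        rss = rss_grid[i]
        return FitResult(spec.name, params, rss, consts.n_obs, spec.h,
                         bic(consts.n_obs, rss, spec.h), len(starts),
                         converged=False)
    (rss, nfev), sol = best
    params = ModelParams.from_array(names, sol.x)
    return FitResult(spec.name, params, rss, consts.n_obs, spec.h,
                     bic(consts.n_obs, rss, spec.h), len(starts),
                     converged=bool(sol.success), nfev=int(sol.nfev))


def fit_all(datasets: dict[str, tuple[pd.DataFrame, pd.DataFrame, DesignConstants]],
            models: tuple[str, ...] | list[str],
            **fit_kwargs) -> tuple[pd.DataFrame, dict[str, dict[str, FitResult]]]:
    """Fit every model to every group; return the BIC table and fits.

    ``datasets`` maps group label -> (series, schedule, consts).  The
    returned table has one row per group plus a ``Mean`` row, one column
    per model, lowest BIC per group flagged in ``fits``.
    """
    fits: dict[str, dict[str, FitResult]] = {}
    for label, (series, schedule, consts) in datasets.items():
        fits[label] = {}
        for m in models:
            fits[label][m] = fit_model(m, series, schedule, consts,
                                       **fit_kwargs)
    table = comparison_frame(
        {g: {m: r.bic for m, r in row.items()} for g, row in fits.items()})
    return table, fits


def comparison_frame(bics: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Group x model BIC matrix with an appended per-model mean row."""
    table = pd.DataFrame(bics).T
    table.loc["Mean"] = table.mean(axis=0)
    table.index.name = "group"
    return table


def best_model(table: pd.DataFrame, group: str = "Mean") -> str:
    return str(table.loc[group].idxmin())


def offline_proportion(j: float, consts: DesignConstants) -> float:
    """Percent of learning units allocated offline: 100 * Btot * j / Stot.

    j = 0 is all-online (0%); j = Stot/Btot is all-offline (100%).
    """
    if not 0 <= j <= consts.j_max + 1e-9:
        raise ValueError(
            f"j={j} outside [0, Stot/Btot = {consts.j_max:.6g}]")
    return 100.0 * consts.btot * j / consts.stot
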