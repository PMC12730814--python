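"""Pixel-by-pixel three-parameter relaxometry fitting.

The core computation: bounded nonlinear least squares of the saturation-
recovery model (variable-TR series, estimating amplitude, recovery fraction
and T1) or the monoexponential-plus-baseline model (variable-TE series,
estimating amplitude, T2 and baseline) at every foreground pixel, producing
a relaxation-time map and a per-pixel R² (coefficient of determination) map
used for fit quality control.

Everything is deterministic — fixed initialisation, no random restarts — so
maps are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import (
    AcquisitionGrid,
    SeriesMode,
    T1ModelParams,
    T2ModelParams,
)
from .phantom import AcquisitionSeries

__all__ = [
    "PixelFitResult",
    "RelaxationMap",
    "fit_t1_pixel",
    "fit_t2_pixel",
    "foreground_mask",
    "fit_map",
    "T1_BOUNDS_MS",
    "T2_BOUNDS_MS",
]

T1_BOUNDS_MS = (1.0, 20000.0)
T2_BOUNDS_MS = (1.0, 2000.0)
B_MAX = 2.0
XTOL = 1e-8
MAX_NFEV = 200
#: relative margin within which a parameter counts as sitting on a bound
_BOUND_TOL = 1e-6


@dataclass
class PixelFitResult:
    """Outcome of one pixel fit."""

    params: T1ModelParams | T2ModelParams | None
    r_squared: float
    converged: bool
    n_iterations: int
    residual_norm: float
    status: str = "ok"

    @property
    def relaxation_time_ms(self) -> float:
        if self.params is None:
            return float("nan")
        if isinstance(self.params, T1ModelParams):
            return self.params.t1_ms
        return self.params.t2_ms


@dataclass
class RelaxationMap:
    """Per-pixel relaxation-time and R² maps over a foreground mask."""

    kind: str  # "T1" | "T2"
    value_map: np.ndarray
    r2_map: np.ndarray
    mask: np.ndarray
    fit_meta: dict = field(default_factory=dict)
    amplitude_map: np.ndarray | None = None
    qc: dict = field(default_factory=dict)


def _degenerate(signals: np.ndarray, n: int, code: str) -> PixelFitResult:
    return PixelFitResult(
        params=None,
        r_squared=float("-inf"),
        converged=False,
        n_iterations=0,
        residual_norm=float(np.linalg.norm(signals)),
        status=code,
    )


def _r_squared(residuals: np.ndarray, signals: np.ndarray) -> float:
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((signals - signals.mean()) ** 2))
    if ss_tot == 0:
        return float("-inf")
    return 1.0 - ss_res / ss_tot


def _on_bound(x: float, lo: float, hi: float) -> bool:
    span = hi - lo
    return (x - lo) <= _BOUND_TOL * span or (hi - x) <= _BOUND_TOL * span


def _validate(signals, grid: AcquisitionGrid, mode: SeriesMode) -> np.ndarray:
    if grid.mode is not mode:
        raise ValueError(f"grid mode {grid.mode} does not match fitter {mode}")
    s = np.asarray(signals, dtype=float)
    if s.ndim != 1 or len(s) != len(grid):
        raise ValueError(
            f"signals length {s.shape} does not match grid length {len(grid)}"
        )
    if len(s) < 4:
        raise ValueError("need >= 4 samples for a three-parameter fit")
    if np.any(s < 0):
        raise ValueError("magnitude signals must be non-negative")
    return s


def fit_t1_pixel(signals, grid: AcquisitionGrid) -> PixelFitResult:
    """Fit ``S(TR) = a * (1 - b * exp(-TR/T1))`` to one pixel's TR series.

    Bounds: ``a`` in (0, 10·max(signal)], ``b`` in (0, 2], ``T1`` in
    [1, 20000] ms. A solver failure, a constant/zero signal, or a parameter
    landing on a bound yields ``converged=False`` with a diagnostic status
    (never an exception).
    """
    s = _validate(signals, grid, SeriesMode.T1_SERIES)
    tr = grid.variable_ms
    smax = float(s.max())
    if smax == 0:
        return _degenerate(s, len(s), "all-zero signal")
    if np.ptp(s) == 0:
        return _degenerate(s, len(s), "constant signal")

    # deterministic start: full recovery at the largest TR, ideal b, and T1
    # from the first TR reaching the 1 - 1/e recovery level
    a0 = smax
    b0 = 1.0
    level = (1.0 - np.exp(-1.0)) * a0
    above = np.nonzero(s >= level)[0]
    t1_0 = float(tr[above[0]]) if above.size else float(np.median(tr))
    t1_0 = float(np.clip(t1_0, *T1_BOUNDS_MS))

    a_lo, a_hi = 1e-6 * smax, 10.0 * smax
    lb = np.array([a_lo, 1e-6, T1_BOUNDS_MS[0]])
    ub = np.array([a_hi, B_MAX, T1_BOUNDS_MS[1]])
    x0 = np.clip(np.array([a0, b0, t1_0]), lb, ub)

    def resid(x):
        a, b, t1 = x
        return a * (1.0 - b * np.exp(-tr / t1)) - s

    def jac(x):
        a, b, t1 = x
        e = np.exp(-tr / t1)
        return np.column_stack([1.0 - b * e, -a * e, -a * b * e * tr / t1**2])

    sol = least_squares(
        resid, x0, jac=jac, bounds=(lb, ub), xtol=XTOL, ftol=XTOL,
        gtol=XTOL, max_nfev=MAX_NFEV,
    )
    a, b, t1 = sol.x
    params = T1ModelParams(float(a), float(b), float(t1))
    r2 = _r_squared(sol.fun, s)
    on_bound = (
        _on_bound(a, a_lo, a_hi)
        or _on_bound(b, lb[1], ub[1])
        or _on_bound(t1, *T1_BOUNDS_MS)
    )
    status = "ok" if sol.success and not on_bound else (
        "parameter at bound" if on_bound else f"solver: {sol.status}"
    )
    return PixelFitResult(
        params=params,
        r_squared=r2,
        converged=bool(sol.success and not on_bound),
        n_iterations=int(sol.nfev),
        residual_norm=float(np.linalg.norm(sol.fun)),
        status=status,
    )


def fit_t2_pixel(signals, grid: AcquisitionGrid) -> PixelFitResult:
    """Fit ``S(TE) = a * exp(-TE/T2) + c`` to one pixel's TE series.

    Bounds: ``a`` in (0, 10·max(signal)], ``T2`` in [1, 2000] ms, ``c`` in
    [0, max(signal)]. A baseline estimated exactly at 0 is physically
    meaningful (no noise floor) and is not counted as a bound hit; hits on
    the other parameters flag ``converged=False``.
    """
    s = _validate(signals, grid, SeriesMode.T2_SERIES)
    te = grid.variable_ms
    smax = float(s.max())
    if smax == 0:
        return _degenerate(s, len(s), "all-zero signal")
    if np.ptp(s) == 0:
        return _degenerate(s, len(s), "constant signal")

    # deterministic start: log-linear regression of the baseline-subtracted
    # decay gives (a0, t2_0); c0 = min(signal)
    c0 = float(s.min())
    y = s - c0
    pos = y > 1e-9 * smax
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[pos], np.log(y[pos]), 1)
        t2_0 = -1.0 / slope if slope < 0 else float(np.median(te))
        a0 = float(np.exp(intercept))
    else:
        t2_0 = float(np.median(te))
        a0 = smax
    t2_0 = float(np.clip(t2_0, *T2_BOUNDS_MS))

    a_lo, a_hi = 1e-6 * smax, 10.0 * smax
    lb = np.array([a_lo, T2_BOUNDS_MS[0], 0.0])
    ub = np.array([a_hi, T2_BOUNDS_MS[1], smax])
    x0 = np.clip(np.array([a0, t2_0, c0]), lb, ub)

    def resid(x):
        a, t2, c = x
        return a * np.exp(-te / t2) + c - s

    def jac(x):
        a, t2, c = x
        e = np.exp(-te / t2)
        return np.column_stack([e, a * e * te / t2**2, np.ones_like(te)])

    sol = least_squares(
        resid, x0, jac=jac, bounds=(lb, ub), xtol=XTOL, ftol=XTOL,
        gtol=XTOL, max_nfev=MAX_NFEV,
    )
    a, t2, c = sol.x
    params = T2ModelParams(float(a), float(t2), float(max(c, 0.0)))
    r2 = _r_squared(sol.fun, s)
    # c = 0 (lower bound) is allowed; c at the upper bound is not
    on_bound = (
        _on_bound(a, a_lo, a_hi)
        or _on_bound(t2, *T2_BOUNDS_MS)
        or (smax - c) <= _BOUND_TOL * smax
    )
    status = "ok" if sol.success and not on_bound else (
        "parameter at bound" if on_bound else f"solver: {sol.status}"
    )
    return PixelFitResult(
        params=params,
        r_squared=r2,
        converged=bool(sol.success and not on_bound),
        n_iterations=int(sol.nfev),
        residual_norm=float(np.linalg.norm(sol.fun)),
        status=status,
    )


def foreground_mask(series: AcquisitionSeries, fraction: float = 0.05) -> np.ndarray:
    """Threshold-based background exclusion before pixel-wise fitting.

    A pixel is foreground iff its value in the highest-signal image of the
    series (longest TR for a T1 series, shortest TE for a T2 series) exceeds
    ``fraction`` times that image's maximum.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if series.grid.mode is SeriesMode.T1_SERIES:
        idx = int(np.argmax(series.grid.variable_ms))
    else:
        idx = int(np.argmin(series.grid.variable_ms))
    ref = series.images[idx]
    return ref > fraction * ref.max()


def fit_map(series: AcquisitionSeries, mask: np.ndarray) -> RelaxationMap:
    """Apply the per-pixel fitter over every masked pixel of a series.

    Non-converged pixels are removed from the output map's mask and counted
    in the ``qc`` summary. Output is independent of pixel iteration order.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match series shape {series.shape}"
        )
    if not mask.any():
        raise ValueError("mask selects no pixels")

    mode = series.grid.mode
    fit_pixel = fit_t1_pixel if mode is SeriesMode.T1_SERIES else fit_t2_pixel
    kind = "T1" if mode is SeriesMode.T1_SERIES else "T2"

    value_map = np.full(series.shape, np.nan)
    r2_map = np.full(series.shape, np.nan)
    amp_map = np.full(series.shape, np.nan)
    out_mask = np.zeros(series.shape, dtype=bool)
    n_failed = 0
    failure_codes: dict[str, int] = {}

    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        res = fit_pixel(series.images[:, r, c], series.grid)
        if res.converged:
            out_mask[r, c] = True
            value_map[r, c] = res.relaxation_time_ms
            r2_map[r, c] = res.r_squared
            amp_map[r, c] = res.params.amplitude
        else:
            n_failed += 1
            failure_codes[res.status] = failure_codes.get(res.status, 0) + 1

    return RelaxationMap(
        kind=kind,
        value_map=value_map,
        r2_map=r2_map,
        mask=out_mask,
        fit_meta={
            "grid": series.grid.to_dict(),
            "solver": "trust-region reflective least squares",
            "xtol": XTOL,
            "max_nfev": MAX_NFEV,
        },
        amplitude_map=amp_map,
        qc={
            "n_fit": int(mask.sum()),
            "n_converged": int(out_mask.sum()),
            "n_failed": n_failed,
            "failure_codes": failure_codes,
        },
    )
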