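"""Closed-form spin-echo relaxation signal models.

Two three-parameter forward models shared by the phantom simulator and the
pixel-wise fitter:

* variable-TR saturation recovery, ``S(TR) = a * (1 - b * exp(-TR / T1))``,
  where the recovery fraction ``b`` absorbs the (constant, short) TE decay
  and imperfect recovery;
* variable-TE monoexponential decay with offset,
  ``S(TE) = a * exp(-TE / T2) + c``, where the baseline ``c`` absorbs the
  magnitude-image noise floor.

All times are in milliseconds; signal is in arbitrary scanner units.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SeriesMode",
    "T1ModelParams",
    "T2ModelParams",
    "AcquisitionGrid",
    "t1_signal",
    "t2_signal",
    "default_acquisition_grids",
    "DEFAULT_TR_VALUES_MS",
    "DEFAULT_TE_VALUES_MS",
    "DEFAULT_FIXED_TE_MS",
    "DEFAULT_FIXED_TR_MS",
]

# Default acquisition protocol: 1.5 T FSE ex vivo relaxometry with 12
# variable-TR images (fixed TE = 3 ms) for T1 and 11 variable-TE images
# (fixed TR = 10,000 ms) for T2.
DEFAULT_TR_VALUES_MS: tuple[float, ...] = (
    50.0, 100.0, 200.0, 500.0, 700.0, 1000.0,
    1500.0, 2000.0, 3000.0, 5000.0, 10000.0, 15000.0,
)
DEFAULT_TE_VALUES_MS: tuple[float, ...] = (
    10.0, 20.0, 42.0, 68.0, 85.0, 102.0, 130.0, 160.0, 200.0, 230.0, 260.0,
)
DEFAULT_FIXED_TE_MS: float = 3.0
DEFAULT_FIXED_TR_MS: float = 10000.0


class SeriesMode(str, Enum):
    """Which pulse-sequence timing parameter varies across the series."""

    T1_SERIES = "T1_SERIES"
    T2_SERIES = "T2_SERIES"


@dataclass(frozen=True)
class T1ModelParams:
    """Parameters of the saturation-recovery model.

    Attributes
    ----------
    amplitude : float
        Fully recovered signal ``a`` (> 0, arbitrary units).
    recovery_fraction : float
        Dimensionless ``b`` (> 0, typically in (0, 1.5]); ``b = 1`` is ideal
        saturation recovery.
    t1_ms : float
        Longitudinal relaxation time in milliseconds (> 0).
    """

    amplitude: float
    recovery_fraction: float
    t1_ms: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.recovery_fraction > 0:
            raise ValueError(
                f"recovery_fraction must be > 0, got {self.recovery_fraction}"
            )
        if not self.t1_ms > 0:
            raise ValueError(f"t1_ms must be > 0, got {self.t1_ms}")


@dataclass(frozen=True)
class T2ModelParams:
    """Parameters of the monoexponential decay model.

    Attributes
    ----------
    amplitude : float
        Decaying signal component ``a`` (> 0, arbitrary units).
    t2_ms : float
        Transverse relaxation time in milliseconds (> 0).
    baseline : float
        Constant offset ``c`` (>= 0), the magnitude noise floor.
    """

    amplitude: float
    t2_ms: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.t2_ms > 0:
            raise ValueError(f"t2_ms must be > 0, got {self.t2_ms}")
        if self.baseline < 0:
            raise ValueError(f"baseline must be >= 0, got {self.baseline}")


def t1_signal(tr_ms, params: T1ModelParams):
    """Saturation-recovery signal ``a * (1 - b * exp(-TR / T1))``.

    ``tr_ms`` may be a scalar or array of non-negative repetition times;
    the return value has the same shape.
    """
    tr = np.asarray(tr_ms, dtype=float)
    if np.any(tr < 0):
        raise ValueError("tr_ms must be non-negative")
    out = params.amplitude * (
        1.0 - params.recovery_fraction * np.exp(-tr / params.t1_ms)
    )
    return out if out.ndim else float(out)


def t2_signal(te_ms, params: T2ModelParams):
    """Monoexponential decay ``a * exp(-TE / T2) + c`` (scalar or array TE)."""
    te = np.asarray(te_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("te_ms must be non-negative")
    out = params.amplitude * np.exp(-te / params.t2_ms) + params.baseline
    return out if out.ndim else float(out)


def _check_variable(values: Sequence[float], name: str) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if len(vals) < 3:
        raise ValueError(f"{name} needs >= 3 values, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValueError(f"{name} must be strictly positive")
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError(f"{name} must be strictly increasing")
    return vals


@dataclass(frozen=True)
class AcquisitionGrid:
    """Ordered (TR, TE) timing tags of a multi-contrast image series.

    For a T1 series the repetition times vary and one echo time is fixed;
    for a T2 series the echo times vary and one repetition time is fixed.
    """

    mode: SeriesMode
    tr_values_ms: tuple[float, ...]
    te_values_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        mode = SeriesMode(self.mode)
        object.__setattr__(self, "mode", mode)
        object.__setattr__(
            self, "tr_values_ms", tuple(float(v) for v in self.tr_values_ms)
        )
        object.__setattr__(
            self, "te_values_ms", tuple(float(v) for v in self.te_values_ms)
        )
        if mode is SeriesMode.T1_SERIES:
            _check_variable(self.tr_values_ms, "tr_values_ms")
            if len(self.te_values_ms) != 1 or self.te_values_ms[0] <= 0:
                raise ValueError("T1 series needs exactly one positive fixed TE")
        else:
            _check_variable(self.te_values_ms, "te_values_ms")
            if len(self.tr_values_ms) != 1 or self.tr_values_ms[0] <= 0:
                raise ValueError("T2 series needs exactly one positive fixed TR")

    def __len__(self) -> int:
        return len(self.variable_ms)

    @property
    def variable_ms(self) -> np.ndarray:
        """The varying timing axis (TR for T1 series, TE for T2 series)."""
        if self.mode is SeriesMode.T1_SERIES:
            return np.asarray(self.tr_values_ms)
        return np.asarray(self.te_values_ms)

    @property
    def tags(self) -> list[tuple[float, float]]:
        """Per-image (tr_ms, te_ms) tags in series order."""
        if self.mode is SeriesMode.T1_SERIES:
            te = self.te_values_ms[0]
            return [(tr, te) for tr in self.tr_values_ms]
        tr = self.tr_values_ms[0]
        return [(tr, te) for te in self.te_values_ms]

    def to_dict(self) -> dict:
        if self.mode is SeriesMode.T1_SERIES:
            return {
                "mode": self.mode.value,
                "tr_values_ms": list(self.tr_values_ms),
                "fixed_te_ms": self.te_values_ms[0],
            }
        return {
            "mode": self.mode.value,
            "te_values_ms": list(self.te_values_ms),
            "fixed_tr_ms": self.tr_values_ms[0],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionGrid":
        mode = SeriesMode(d["mode"])
        if mode is SeriesMode.T1_SERIES:
            return cls(mode, tuple(d["tr_values_ms"]), (float(d["fixed_te_ms"]),))
        return cls(mode, (float(d["fixed_tr_ms"]),), tuple(d["te_values_ms"]))


def default_acquisition_grids() -> tuple[AcquisitionGrid, AcquisitionGrid]:
    """The default acquisition protocol as a (T1 grid, T2 grid) pair.

    Twelve TR values from 50 to 15,000 ms at fixed TE = 3 ms for T1, and
    eleven TE values from 10 to 260 ms at fixed TR = 10,000 ms for T2.
    """
    t1 = AcquisitionGrid(
        SeriesMode.T1_SERIES, DEFAULT_TR_VALUES_MS, (DEFAULT_FIXED_TE_MS,)
    )
    t2 = AcquisitionGrid(
        SeriesMode.T2_SERIES, (DEFAULT_FIXED_TR_MS,), DEFAULT_TE_VALUES_MS
    )
    return t1, t2
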