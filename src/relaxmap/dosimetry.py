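"""Photodynamic-therapy light-dose arithmetic.

Irradiance (power density, mW/cm²) and fluence (energy density, J/cm²) from
laser power, illuminated area and exposure time, assuming a uniform top-hat
beam over the stated area.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IrradiationProtocol", "irradiance", "fluence", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class IrradiationProtocol:
    """One continuous-wave surface irradiation.

    Attributes
    ----------
    power_mw : float
        Optical output power, mW.
    area_cm2 : float
        Illuminated area, cm².
    duration_s : float
        Exposure time, s (zero means no energy delivered).
    wavelength_nm : float
        Laser wavelength, nm (metadata only; no spectral modelling).
    """

    power_mw: float
    area_cm2: float
    duration_s: float
    wavelength_nm: float = 665.0

    def __post_init__(self) -> None:
        for name in ("power_mw", "area_cm2", "wavelength_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")


#: 665 nm, 350 mW over a 2.5 x 2.5 cm² field for 10 min —
#: 56 mW/cm² irradiance, 33.6 J/cm² fluence.
DEFAULT_PROTOCOL = IrradiationProtocol(
    power_mw=350.0, area_cm2=2.5 * 2.5, duration_s=600.0, wavelength_nm=665.0
)


def irradiance(protocol: IrradiationProtocol) -> float:
    """Delivered power density, mW/cm² = power_mw / area_cm2."""
    return protocol.power_mw / protocol.area_cm2


def fluence(protocol: IrradiationProtocol) -> float:
    """Delivered energy density, J/cm² = (power_mw / 1000) / area_cm2 · duration_s."""
    return (protocol.power_mw / 1000.0) / protocol.area_cm2 * protocol.duration_s
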