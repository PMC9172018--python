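"""Physical properties of the two fluids and the patient postures.

Defaults describe a 1000 mPa.s polydimethylsiloxane silicone oil (SiO)
against aqueous humour.  The static contact angle of 16.2 deg at the
oil–water–retina line is, by default, read as measured through the *aqueous*
phase: the retina is hydrophilic and keeps an aqueous wetting film, so the
oil behaves as the non-wetting phase (oil-side angle 180 - 16.2 deg).  Set
``wetting_phase="sio"`` for the opposite reading.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

G_STANDARD = 9.81  # m/s^2


@dataclass(frozen=True)
class FluidProperties:
    density_sio: float = 980.0            # kg/m^3
    density_aqueous: float = 997.0        # kg/m^3
    viscosity_sio: float = 1.0            # Pa.s (1000 mPa.s)
    viscosity_aqueous: float = 1.0e-3     # Pa.s
    interfacial_tension: float = 0.044    # N/m
    contact_angle_static: float = 16.2    # deg, through the wetting phase
    contact_angle_advancing: float = 21.2  # deg (hysteresis bound, statics unused)
    contact_angle_receding: float = 11.2   # deg
    gravity: float = G_STANDARD           # m/s^2
    wetting_phase: str = "aqueous"        # which phase the 16.2 deg is through

    def __post_init__(self) -> None:
        if self.density_sio >= self.density_aqueous:
            raise ValueError("SiO must be buoyant (density_sio < density_aqueous)")
        if not (self.contact_angle_receding <= self.contact_angle_static
                <= self.contact_angle_advancing):
            raise ValueError("contact angles must satisfy receding <= static <= advancing")
        if self.wetting_phase not in ("aqueous", "sio"):
            raise ValueError("wetting_phase must be 'aqueous' or 'sio'")

    @property
    def delta_rho(self) -> float:
        """Density contrast aqueous - SiO (kg/m^3), positive: oil floats."""
        return self.density_aqueous - self.density_sio

    @property
    def contact_angle_sio_deg(self) -> float:
        """Static contact angle measured through the oil (deg)."""
        if self.wetting_phase == "sio":
            return self.contact_angle_static
        return 180.0 - self.contact_angle_static

    @property
    def kinematic_viscosity_sio(self) -> float:
        return self.viscosity_sio / self.density_sio

    @property
    def kinematic_viscosity_aqueous(self) -> float:
        return self.viscosity_aqueous / self.density_aqueous

    @property
    def capillary_length_mm(self) -> float:
        return 1e3 * float(np.sqrt(
            self.interfacial_tension / (self.delta_rho * self.gravity)))


_SQ2 = np.sqrt(2.0) / 2.0

_POSTURE_GRAVITY = {
    "standing": (0.0, -1.0, 0.0),
    "tilt45": (0.0, -_SQ2, -_SQ2),
    "supine": (0.0, 0.0, -1.0),   # face-up: gravity toward the posterior pole
}


@dataclass(frozen=True)
class Posture:
    """Patient posture as a gravity unit vector in the eye frame."""

    name: str
    gravity_dir: tuple[float, float, float]

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_dir, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0):
            raise ValueError("gravity_dir must be a unit vector")

    @classmethod
    def from_name(cls, name: str) -> "Posture":
        try:
            return cls(name, _POSTURE_GRAVITY[name])
        except KeyError:
            raise ValueError(f"unknown posture {name!r}; "
                             f"choose from {sorted(_POSTURE_GRAVITY)}") from None

    @property
    def up(self) -> np.ndarray:
        """Unit vector opposite gravity (the direction oil floats)."""
        return -np.asarray(self.gravity_dir, dtype=float)


STANDARD_POSTURES = tuple(Posture.from_name(n) for n in ("standing", "tilt45", "supine"))
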