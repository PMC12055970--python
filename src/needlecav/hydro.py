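"""Hydrodynamic characterisation: cavitation number, Reynolds number, regime.

For a needle moving laterally through a fluid at rest, the likelihood of
hydrodynamic cavitation in its wake is estimated by the cavitation number

    Ca = (p - p_v) / (0.5 * rho * u**2)

(low Ca favours inception; a wedge bluff body shows inception near Ca = 4.8),
and the flow regime around the shaft by the Reynolds number

    Re = u * L * rho / mu = u * L / nu.

Flow past a bluff obstacle transitions from laminar to a Karman-vortex
regime for 49 <= Re <= 190 and is fully turbulent above Re = 190; both
boundaries are implemented as closed at 49 and 190.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

#: Cited cavitation-inception value for a wedge-shaped bluff body (comparison
#: constant, not computed by this package).
CA_INCEPTION_WEDGE = 4.8

#: 14 G needle outer diameter, metres (characteristic dimension L).
NEEDLE_OD_M = 2.109e-3


class FlowRegime(str, enum.Enum):
    laminar = "laminar"
    vortex_transition = "vortex_transition"
    turbulent = "turbulent"


@dataclass
class FlowParameters:
    """Fluid and obstacle parameters.

    Defaults are water at 20 °C: rho = 998 kg/m³, mu = 1.0 mPa·s,
    p_v = 2339 Pa, at atmospheric pressure.  ``u`` is the flow (needle)
    speed in m/s and ``L`` the characteristic obstacle dimension in metres.
    """

    u: float
    L: float = NEEDLE_OD_M
    p: float = 101_325.0
    p_v: float = 2_339.0
    rho: float = 998.0
    mu: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.u < 0:
            raise ValueError("u must be non-negative")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m²/s (= mu/rho)."""
        return self.mu / self.rho

    @classmethod
    def from_kinematic(
        cls, u: float, nu: float, L: float = NEEDLE_OD_M, rho: float = 998.0, **kw
    ) -> "FlowParameters":
        """Build from kinematic viscosity (mu = nu * rho)."""
        return cls(u=u, L=L, rho=rho, mu=nu * rho, **kw)


def cavitation_number(fp: FlowParameters) -> float:
    """Ca = (p - p_v) / (0.5 rho u²); negative if p < p_v.  Undefined at u=0."""
    if fp.u == 0:
        raise ValueError("cavitation number is undefined at zero flow speed")
    return (fp.p - fp.p_v) / (0.5 * fp.rho * fp.u**2)


def reynolds_number(fp: FlowParameters) -> float:
    """Re = u L rho / mu."""
    return fp.u * fp.L * fp.rho / fp.mu


def flow_regime(re: float) -> FlowRegime:
    """Classify the wake regime from the Reynolds number."""
    if re < 0:
        raise ValueError("Reynolds number must be non-negative")
    if re < 49:
        return FlowRegime.laminar
    if re <= 190:
        return FlowRegime.vortex_transition
    return FlowRegime.turbulent
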