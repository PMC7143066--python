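"""One-call mixing simulation: geometry -> flow -> transport -> profile.

The coupling is sequential, as in the original device model: the flow is
solved first with fluid properties evaluated at a reference composition (the
flow-averaged outlet ethanol fraction 1/(1+FRR)), then the species field is
solved in the frozen velocity field.  Optionally the transport solve
Picard-iterates a composition-dependent diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flow import FlowField, solve_flow
from .geometry import ChannelGeometry, discretize
from .metrics import MixingProfile, mixing_profile
from .properties import PropertyModel
from .transport import TransportField, solve_transport

__all__ = ["MixingResult", "simulate_mixing"]


@dataclass
class MixingResult:
    flow: FlowField
    transport: TransportField
    profile: MixingProfile
    c_ref: float


def simulate_mixing(
    geom: ChannelGeometry,
    tfr_ml_h: float,
    frr: float,
    properties: PropertyModel | None = None,
    cells_across: int = 30,
    advection: bool = False,
    variable_diffusivity: bool = False,
    n_stations: int = 10,
    n_samples: int = 50,
) -> MixingResult:
    """Simulate mixing at one (TFR, FRR) operating point.

    ``properties=None`` loads the packaged 25 C water-ethanol polynomials.
    """
    props = properties or PropertyModel.from_packaged()
    c_ref = 1.0 / (1.0 + frr)
    grid = discretize(geom, cells_across=cells_across)
    flow = solve_flow(
        grid, tfr_ml_h, frr,
        mu=float(props.mu(c_ref)), rho=float(props.rho(c_ref)),
        advection=advection,
    )
    D = props.D if variable_diffusivity else float(props.D(c_ref))
    transport = solve_transport(flow, D=D)
    profile = mixing_profile(transport, n_stations=n_stations,
                             n_samples=n_samples)
    return MixingResult(flow=flow, transport=transport, profile=profile,
                        c_ref=c_ref)
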