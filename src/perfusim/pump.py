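"""Centrifugal pump, cannulae and the six-switch cannulation logic.

Four extracorporeal connections are supported, named by where the pump
draws and returns blood (RA right atrium, FV femoral vein, SVC superior
vena cava; AA ascending aorta, FA femoral artery, CC bilateral common
carotid arteries):

* ``RA_AA_CC``   - SW3, SW5, SW6 on
* ``RA_FA_CC``   - SW3, SW4, SW5 on
* ``FV_FA_CC``   - SW1, SW3, SW4 on
* ``FVSVC_FA_CC``- SW1, SW2, SW3, SW4 on

Switch roles: SW1 opens the femoral-vein inflow cannula, SW2 the superior
vena cava inflow, SW3 the carotid return, SW4 the femoral-artery return,
SW5 the right-atrial inflow and SW6 the ascending-aorta return.

The pump head follows the quadratic characteristic
``dP = k1 w^2 - k2 w Q - k3 Q |Q|``; cannulae are resistive lines and the
pump stores no blood, so the junction is solved algebraically: inlet and
outlet cannula flows always sum exactly to the pump flow.  With the pump
off every cannula is closed by its check valve; while it spins, flow may
reverse through the circuit if the head cannot support the arteriovenous
gradient (a spinning centrifugal pump has no valve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .parameters import Cannula, CentrifugalPump, ConfigurationError
from .network import CirculationTopology

__all__ = [
    "STRATEGIES",
    "SWITCH_CANNULA",
    "CannulationConfig",
    "CannulationCircuit",
    "configure_switches",
    "pump_head",
    "apply_cannulation",
    "solve_pump_junction",
]

SWITCH_CANNULA: Dict[str, str] = {
    "SW1": "in_FV",
    "SW2": "in_SVC",
    "SW3": "out_CC",
    "SW4": "out_FA",
    "SW5": "in_RA",
    "SW6": "out_AA",
}

STRATEGIES: Dict[str, Tuple[str, ...]] = {
    "RA_AA_CC": ("SW3", "SW5", "SW6"),
    "RA_FA_CC": ("SW3", "SW4", "SW5"),
    "FV_FA_CC": ("SW1", "SW3", "SW4"),
    "FVSVC_FA_CC": ("SW1", "SW2", "SW3", "SW4"),
}


@dataclass(frozen=True)
class CannulationConfig:
    strategy: str
    switches: Dict[str, bool]

    @property
    def active_cannulae(self) -> List[str]:
        return [SWITCH_CANNULA[sw] for sw, on in sorted(self.switches.items()) if on]


def configure_switches(strategy: str) -> CannulationConfig:
    """Switch pattern for one of the four cannulation strategies."""
    if strategy not in STRATEGIES:
        raise ConfigurationError(
            f"unknown cannulation strategy {strategy!r}; expected one of {sorted(STRATEGIES)}")
    on = STRATEGIES[strategy]
    switches = {sw: (sw in on) for sw in SWITCH_CANNULA}
    return CannulationConfig(strategy=strategy, switches=switches)


def pump_head(pump: CentrifugalPump, Q: float, speed: float | None = None) -> float:
    """Pressure rise (mmHg) across the pump at flow ``Q`` (mL/s)."""
    w = pump.speed if speed is None else speed
    return pump.k1 * w * w - pump.k2 * w * Q - pump.k3 * Q * abs(Q)


@dataclass(frozen=True)
class CannulationCircuit:
    """Topology augmented with an active extracorporeal circuit.

    Inlet cannulae connect their tap vertex to the pump inlet junction,
    outlet cannulae the pump outlet junction to their tap vertex.  Only
    cannulae whose switch is on appear; all others carry zero flow.
    """

    topology: CirculationTopology
    config: CannulationConfig
    pump: CentrifugalPump
    inlet_taps: Tuple[str, ...]
    inlet_conductances: Tuple[float, ...]
    outlet_taps: Tuple[str, ...]
    outlet_conductances: Tuple[float, ...]

    @property
    def active(self) -> bool:
        return bool(self.inlet_taps) and bool(self.outlet_taps)


def apply_cannulation(
    topology: CirculationTopology,
    config: CannulationConfig,
    pump: CentrifugalPump,
    cannulae: Dict[str, Cannula],
) -> CannulationCircuit:
    """Attach the pump circuit selected by ``config`` to the topology."""
    inl: List[Tuple[str, float]] = []
    outl: List[Tuple[str, float]] = []
    for role in config.active_cannulae:
        if role not in cannulae:
            raise ConfigurationError(f"strategy {config.strategy} requires cannula {role!r}")
        can = cannulae[role]
        if role not in topology.taps:
            raise ConfigurationError(f"no tap point for cannula {role!r}")
        entry = (topology.taps[role], 1.0 / can.R)
        (inl if role.startswith("in_") else outl).append(entry)
    if bool(inl) != bool(outl):
        raise ConfigurationError(
            f"strategy {config.strategy} opens only one side of the pump circuit")
    return CannulationCircuit(
        topology=topology, config=config, pump=pump,
        inlet_taps=tuple(n for n, _ in inl),
        inlet_conductances=tuple(g for _, g in inl),
        outlet_taps=tuple(n for n, _ in outl),
        outlet_conductances=tuple(g for _, g in outl),
    )


def solve_pump_junction(
    pump: CentrifugalPump,
    speed: float,
    inlet_pressures: Sequence[float],
    inlet_conductances: Sequence[float],
    outlet_pressures: Sequence[float],
    outlet_conductances: Sequence[float],
) -> Tuple[float, float, float]:
    """Solve the storage-free pump junction.

    Returns ``(Q, P_in, P_out)`` where ``Q`` is the pump flow (mL/s) and
    ``P_in``/``P_out`` the junction pressures.  Individual cannula flows
    follow as ``g_i (P_tap_i - P_in)`` and ``g_o (P_out - P_tap_o)`` and
    sum exactly to ``Q`` on each side.  At ``speed = 0`` the check valves
    close the circuit and ``Q = 0``.
    """
    if speed <= 0.0 or not inlet_conductances or not outlet_conductances:
        return 0.0, 0.0, 0.0
    G_in = float(sum(inlet_conductances))
    G_out = float(sum(outlet_conductances))
    Pbar_in = sum(g * p for g, p in zip(inlet_conductances, inlet_pressures)) / G_in
    Pbar_out = sum(g * p for g, p in zip(outlet_conductances, outlet_pressures)) / G_out
    R_tot = 1.0 / G_in + 1.0 / G_out
    # k3 Q|Q| + (k2 w + R_tot) Q + (Pbar_out - Pbar_in - k1 w^2) = 0
    b = pump.k2 * speed + R_tot
    c = (Pbar_out - Pbar_in) - pump.k1 * speed * speed
    a = pump.k3
    if c <= 0.0:  # forward flow
        if a == 0.0:
            Q = -c / b
        else:
            Q = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    else:  # head below gradient: retrograde flow through the spinning pump
        if a == 0.0:
            Q = -c / b
        else:
            mag = (-b + math.sqrt(b * b + 4.0 * a * c)) / (2.0 * a)
            Q = -mag
    P_in = Pbar_in - Q / G_in
    P_out = Pbar_out + Q / G_out
    return Q, P_in, P_out
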