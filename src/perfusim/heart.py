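"""Time-varying-elastance heart: activation, chamber pressure, valves, septum.

The four chambers follow the classic elastance model
``P = [E_min + e(t) * (E_max - E_min)] * (V - V0) + Pt`` with a half-cosine
activation bump ``e(t)`` over the systolic interval.  Valves are ideal
diodes (flow only down a positive pressure gradient); for numerical work
the solver uses a smoothed variant of the same law, while the functions
here implement the ideal limit.

The interventricular septum couples the ventricles through a displacement
volume ``V_spt = (P_LV - P_RV) / E_spt`` that is subtracted from the left
and added to the right free-wall volume; a rigid septum (``E_spt -> inf``)
recovers independent ventricles.
"""

from __future__ import annotations

import math

from .parameters import CardiacTiming, ElastanceChamber, SeptumModel, ValveModel

__all__ = [
    "activation",
    "chamber_pressure",
    "valve_flow",
    "septal_coupling",
    "septal_displacement",
]


def activation(t: float, timing: CardiacTiming, chamber: str = "LV") -> float:
    """Normalised activation e(t) in [0, 1] for one beat.

    The beat clock has the ventricular activation onset at ``t = 0``; the
    atrial bump leads it by ``AV_delay`` (it starts late in the previous
    diastole).  ``t`` outside the beat is wrapped modulo the period.
    """
    tm = timing.resolved()
    period = tm.period
    tau = t % period
    if chamber in ("LA", "RA"):
        tau = (tau + tm.AV_delay) % period
        t_sys = tm.T_sys_atrial
    else:
        t_sys = tm.T_sys_ventricular
    if tau >= t_sys:
        return 0.0
    return 0.5 * (1.0 - math.cos(2.0 * math.pi * tau / t_sys))


def chamber_pressure(chamber: ElastanceChamber, V: float, e: float, Pt: float = 0.0) -> float:
    """Chamber pressure (mmHg) at volume ``V`` and activation ``e``."""
    E = chamber.E_min + e * (chamber.E_max - chamber.E_min)
    return E * (V - chamber.V0) + Pt


def valve_flow(P_upstream: float, P_downstream: float, valve: ValveModel) -> float:
    """Ideal-diode valve flow (mL/s): Ohmic when forward-biased, else zero."""
    dp = P_upstream - P_downstream
    if dp <= 0.0:
        return 0.0
    return dp / valve.R_open


def septal_displacement(P_LV: float, P_RV: float, septum: SeptumModel, e: float) -> float:
    """Septal displacement volume (mL) for given chamber pressures.

    Positive when the septum bulges into the right ventricle.
    """
    E_spt = septum.E_spt_min + e * (septum.E_spt_max - septum.E_spt_min)
    return (P_LV - P_RV) / E_spt


# alias under the name the operation is usually called by
septal_coupling = septal_displacement


def coupled_ventricular_pressures(
    lv: ElastanceChamber,
    rv: ElastanceChamber,
    septum: SeptumModel,
    V_LV: float,
    V_RV: float,
    e: float,
    Pt: float = 0.0,
) -> tuple[float, float, float]:
    """Self-consistent (P_LV, P_RV, V_spt) with septal coupling.

    Solves the linear fixed point of ``V_spt = (P_LV - P_RV)/E_spt`` with
    ``P_LV = E_L (V_LV - V_spt - V0_L)`` and ``P_RV = E_R (V_RV + V_spt - V0_R)``.
    """
    E_L = lv.E_min + e * (lv.E_max - lv.E_min)
    E_R = rv.E_min + e * (rv.E_max - rv.E_min)
    E_S = septum.E_spt_min + e * (septum.E_spt_max - septum.E_spt_min)
    num = E_L * (V_LV - lv.V0) - E_R * (V_RV - rv.V0)
    V_spt = num / (E_S + E_L + E_R)
    P_LV = E_L * (V_LV - V_spt - lv.V0) + Pt
    P_RV = E_R * (V_RV + V_spt - rv.V0) + Pt
    return P_LV, P_RV, V_spt
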