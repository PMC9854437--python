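"""Parameter containers for the closed-loop 0-D circulation model.

Units are fixed throughout the package: pressures in mmHg, volumes in mL,
time in s.  Resistances are therefore mmHg*s/mL, inertances mmHg*s^2/mL and
compliances mL/mmHg.

A :class:`ParameterSet` holds every numeric parameter of the model: one
:class:`CompartmentParams` per named vascular element (keyed by the symbol
of its section, e.g. ``"AA1"`` for the ascending aorta / aortic arch),
the four elastance chambers, the septum, the four valves, cardiac timing,
the centrifugal pump, the six cannulae and the environment pressures.
It serialises losslessly to JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigurationError(ValueError):
    """A parameter set is incomplete or inconsistent with the topology."""


ExternalRef = Literal["intrathoracic", "abdominal", "atmospheric"]


class CompartmentParams(BaseModel):
    """RLC description of one vascular element.

    ``R``/``L`` belong to the branch feeding the element in the adopted
    ladder wiring (venous collectors carry their ``R`` on the outflow
    branch instead; the topology module owns that convention).  ``C`` is
    the shunt compliance of the element's node; ``C = 0`` marks a purely
    resistive element with no pressure node of its own.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    R: float = Field(ge=0.0)
    L: float = Field(default=0.0, ge=0.0)
    C: float = Field(default=0.0, ge=0.0)
    V_unstressed: float = Field(default=0.0, ge=0.0)
    external_pressure_ref: ExternalRef = "atmospheric"


class VariableResistance(BaseModel):
    """A resistance whose effective value is ``base_value * scale``.

    The scale hook exists for sensitivity studies and calibration; it is
    held constant during a run (no reflex control is modelled).
    """

    model_config = ConfigDict(extra="forbid")

    base_value: float = Field(gt=0.0)
    scale: float = Field(default=1.0, gt=0.0)

    @property
    def effective(self) -> float:
        return self.base_value * self.scale


class EnvironmentParams(BaseModel):
    """Pressures surrounding the compartments.

    ``Pt`` is the (constant) intrathoracic pressure applied to thoracic
    vessels and heart chambers; ``P_B`` a breathing pressure offset, kept
    at zero because respiration is not analysed.
    """

    model_config = ConfigDict(extra="forbid")

    Pt: float = -4.0
    P_B: float = 0.0
    P_abdominal: float = 0.0


class ElastanceChamber(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: Literal["LV", "RV", "LA", "RA"]
    E_max: float = Field(gt=0.0)
    E_min: float = Field(gt=0.0)
    V0: float = Field(ge=0.0)
    activation_offset: float = 0.0

    @model_validator(mode="after")
    def _check_elastances(self) -> "ElastanceChamber":
        if self.E_max < self.E_min:
            raise ValueError(f"{self.name}: E_max must be >= E_min")
        return self


class CardiacTiming(BaseModel):
    """Parametric cardiac timing.

    Systolic durations follow the common rate-scaling T_sys = c*sqrt(60/HR);
    the atrial bump leads the ventricular one by ``AV_delay``.  Unset
    durations are filled in from the heart rate.
    """

    model_config = ConfigDict(extra="forbid")

    HR: float = Field(default=90.0, gt=0.0)
    T_sys_ventricular: Optional[float] = Field(default=None, gt=0.0)
    T_sys_atrial: Optional[float] = Field(default=None, gt=0.0)
    AV_delay: Optional[float] = Field(default=None, ge=0.0)

    @property
    def period(self) -> float:
        return 60.0 / self.HR

    def resolved(self) -> "CardiacTiming":
        """Return a copy with all durations made explicit."""
        s = math.sqrt(self.period)
        t_sys_v = self.T_sys_ventricular if self.T_sys_ventricular is not None else 0.3 * s
        t_sys_a = self.T_sys_atrial if self.T_sys_atrial is not None else 0.15 * s
        av = self.AV_delay if self.AV_delay is not None else 0.12 * s
        if not t_sys_v < self.period:
            raise ConfigurationError("T_sys_ventricular must be shorter than the beat period")
        return CardiacTiming(HR=self.HR, T_sys_ventricular=t_sys_v, T_sys_atrial=t_sys_a, AV_delay=av)


class SeptumModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    E_spt_max: float = Field(gt=0.0)
    E_spt_min: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "SeptumModel":
        if self.E_spt_max < self.E_spt_min:
            raise ValueError("E_spt_max must be >= E_spt_min")
        return self


class ValveModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: Literal["AV", "MV", "TV", "PV"]
    R_open: float = Field(gt=0.0)


class CentrifugalPump(BaseModel):
    """Quadratic head-flow characteristic of the extracorporeal pump.

    Head rise dP = k1*w^2 - k2*w*Q - k3*Q*|Q| (mmHg) at rotational speed
    ``w`` (rpm) and flow ``Q`` (mL/s).  The coefficients describe the pump
    together with its tubing/oxygenator losses, which is why ``k2`` is
    larger than a bare impeller characteristic would suggest.
    """

    model_config = ConfigDict(extra="forbid")

    speed: float = Field(default=0.0, ge=0.0)
    k1: float = Field(default=1.6e-5, ge=0.0)
    k2: float = Field(default=9.0e-4, ge=0.0)
    k3: float = Field(default=1.4e-3, ge=0.0)


CannulaRole = Literal["in_RA", "in_SVC", "in_FV", "out_AA", "out_CC", "out_FA"]


class Cannula(BaseModel):
    """One extracorporeal cannula, modelled as a resistive line.

    ``L`` and ``C`` are retained for interface completeness but the pump
    junction is solved algebraically, so only ``R`` enters the dynamics.
    """

    model_config = ConfigDict(extra="forbid")

    role: CannulaRole
    R: float = Field(gt=0.0)
    L: float = Field(default=0.0, ge=0.0)
    C: float = Field(default=0.0, ge=0.0)


class ParameterSet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    compartments: Dict[str, CompartmentParams]
    chambers: Dict[str, ElastanceChamber]
    septum: SeptumModel
    valves: Dict[str, ValveModel]
    timing: CardiacTiming
    pump: CentrifugalPump
    cannulae: Dict[str, Cannula]
    environment: EnvironmentParams = EnvironmentParams()
    #: per-symbol multipliers for the variable resistances (and for the
    #: ascending-aorta resistance used by the sensitivity study)
    resistance_scales: Dict[str, float] = Field(default_factory=dict)
    #: volume added at initialisation to the venous reservoirs (mL),
    #: distributed proportionally to compliance; the calibration handle
    #: for total stressed blood volume
    volume_adjust: float = 0.0

    def copy_with(self, **updates) -> "ParameterSet":
        return self.model_copy(update=updates, deep=True)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: Optional[Path] = None, indent: int = 1) -> str:
        text = json.dumps(self.model_dump(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ParameterSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))

    def scaled_resistance(self, symbol: str, base: float) -> float:
        return base * self.resistance_scales.get(symbol, 1.0)


# ---------------------------------------------------------------------------
# Default adult parameter set
# ---------------------------------------------------------------------------

def _cmp(name: str, R: float, L: float = 0.0, C: float = 0.0,
         Vu: float = 0.0, ext: ExternalRef = "atmospheric") -> CompartmentParams:
    return CompartmentParams(name=name, R=R, L=L, C=C, V_unstressed=Vu,
                             external_pressure_ref=ext)


def default_parameters() -> ParameterSet:
    """Adult closed-loop parameter set.

    Values are assembled from standard adult 0-D modelling ranges and then
    refined by :func:`perfusim.calibration.calibrate_baseline` against the
    baseline haemodynamic targets (HR 90, AoP_sys 90 mmHg, LAP 21 mmHg,
    RAP 10 mmHg, PAP 18 mmHg, CO 4.3 L/min).  Peripheral bed resistances
    encode an approximate flow split of brain 13%, arms 8%, coronary 4%,
    splanchnic 28%, renal 22%, hepatic-arterial 8% and legs 17% of cardiac
    output.
    """
    comps = {
        # aortic ladder -----------------------------------------------------
        "AA1": _cmp("AA1", R=0.04, L=0.0, C=0.507, Vu=60.0, ext="intrathoracic"),
        "AA2": _cmp("AA2", R=0.08, L=3e-4, C=0.455, Vu=60.0, ext="intrathoracic"),
        "THOR": _cmp("THOR", R=0.05),
        "AT1": _cmp("AT1", R=0.05, L=3e-4, C=0.546, Vu=80.0, ext="intrathoracic"),
        "AB1": _cmp("AB1", R=0.06, L=2e-4, C=0.455, Vu=70.0, ext="abdominal"),
        "ABII": _cmp("ABII", R=0.07, L=2e-4, C=0.364, Vu=60.0, ext="abdominal"),
        # head / upper limbs ------------------------------------------------
        "HD": _cmp("HD", R=3.0866, C=1.2, Vu=50.0),
        "HD2": _cmp("HD2", R=1.2),
        "ARM": _cmp("ARM", R=5.058, C=0.8, Vu=40.0),
        "ARM2": _cmp("ARM2", R=1.9),
        # abdominal organ beds ---------------------------------------------
        "SP": _cmp("SP", R=1.4435, C=6.0, Vu=250.0, ext="abdominal"),
        "SP2": _cmp("SP2", R=0.55),
        "KID": _cmp("KID", R=1.8435, C=2.0, Vu=60.0, ext="abdominal"),
        "KID2": _cmp("KID2", R=0.7),
        "HEP": _cmp("HEP", R=5.058, C=3.0, Vu=150.0, ext="abdominal"),
        "HEP2": _cmp("HEP2", R=1.9),
        # legs ---------------------------------------------------------------
        "LLE": _cmp("LLE", R=4.7296, C=2.0, Vu=100.0),
        "LFV": _cmp("LFV", R=1.8),
        "RLE": _cmp("RLE", R=4.7296, C=2.0, Vu=100.0),
        "RFV": _cmp("RFV", R=1.8),
        # venous collectors --------------------------------------------------
        "SVC": _cmp("SVC", R=0.03, C=22.971, Vu=250.0, ext="intrathoracic"),
        "AbdVC": _cmp("AbdVC", R=0.01, C=18.377, Vu=300.0, ext="abdominal"),
        "IVC": _cmp("IVC", R=0.01, C=38.290, Vu=500.0, ext="abdominal"),
        "IVC2": _cmp("IVC2", R=0.01),
        # coronary stub ------------------------------------------------------
        "COR": _cmp("COR", R=12.991),
        # pulmonary circulation ----------------------------------------------
        "PA": _cmp("PA", R=0.005963, L=5e-5, C=4.0, Vu=80.0, ext="intrathoracic"),
        "PC": _cmp("PC", R=0.004764, C=6.0, Vu=100.0, ext="intrathoracic"),
        "PVEN": _cmp("PVEN", R=0.004764, C=8.0, Vu=150.0, ext="intrathoracic"),
    }
    chambers = {
        "LV": ElastanceChamber(name="LV", E_max=2.371, E_min=0.30, V0=15.0),
        "RV": ElastanceChamber(name="RV", E_max=0.70, E_min=0.18, V0=10.0),
        "LA": ElastanceChamber(name="LA", E_max=0.50, E_min=0.35, V0=10.0),
        "RA": ElastanceChamber(name="RA", E_max=0.35, E_min=0.22, V0=8.0),
    }
    valves = {
        "AV": ValveModel(name="AV", R_open=0.005),
        "PV": ValveModel(name="PV", R_open=0.005),
        "MV": ValveModel(name="MV", R_open=0.003),
        "TV": ValveModel(name="TV", R_open=0.003),
    }
    cannulae = {
        "in_RA": Cannula(role="in_RA", R=0.2715),
        "in_SVC": Cannula(role="in_SVC", R=0.50),
        "in_FV": Cannula(role="in_FV", R=0.0902),
        "out_AA": Cannula(role="out_AA", R=0.25),
        "out_CC": Cannula(role="out_CC", R=180.0),
        "out_FA": Cannula(role="out_FA", R=1.45),
    }
    return ParameterSet(
        compartments=comps,
        chambers=chambers,
        septum=SeptumModel(E_spt_max=4.8, E_spt_min=0.58),
        valves=valves,
        timing=CardiacTiming(HR=90.0),
        pump=CentrifugalPump(),
        cannulae=cannulae,
        environment=EnvironmentParams(),
        volume_adjust=-90.0,
    )
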