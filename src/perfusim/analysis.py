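"""Pressure-volume loops, ventricular energetics and scenario summaries.

External work EW is the area enclosed by one steady-state PV loop
(shoelace formula, mmHg*mL).  The pressure-volume area adds the
triangular potential energy between the end-systolic point and the
chamber's unstressed volume: ``PE = ESP * (ESV - V0) / 2``, ``PVA = EW + PE``.
Arterial elastance is the classic ratio ``Ea = ESP / SV``; ventricular-
arterial coupling is reported as ``Ea_S/Ees_Left`` for the left and
``Ees_Right/Ea_P`` for the right ventricle (the inverse right-sided ratio
is exposed as a derived field).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .parameters import ParameterSet
from .solver import SolverSettings, WaveformRecord, simulate

__all__ = [
    "PVLoop", "EnergeticsResult", "ScenarioResult",
    "extract_pv_loop", "external_work", "pressure_volume_area",
    "coupling_ratios", "summarize", "resistance_sensitivity", "percent_change",
]

#: organ perfusion is measured on the venous drainage branch of each bed
FLOW_BRANCHES = {
    "cerebral_flow": "Q_head_ven",
    "renal_flow": "Q_ren_ven",
    "hepatic_flow": "Q_hep_ven",
    "splanchnic_flow": "Q_spl_ven",
    "svc_flow": "Q_svc_ra",
    "arm_flow": "Q_arm_ven",
    "coronary_flow": "Q_coronary",
}


class UnconvergedRecordError(RuntimeError):
    pass


@dataclass
class PVLoop:
    """One steady-state beat of a chamber in the (volume, pressure) plane."""

    chamber: str
    volume: np.ndarray
    pressure: np.ndarray
    EDV: float = field(init=False)
    ESV: float = field(init=False)
    ESP: float = field(init=False)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.volume.shape != self.pressure.shape:
            raise ValueError("volume and pressure must have the same length")
        self.EDV = float(self.volume.max())
        self.ESV = float(self.volume.min())
        self.ESP = float(self.pressure[int(np.argmin(self.volume))])

    @property
    def stroke_volume(self) -> float:
        return self.EDV - self.ESV

    def signed_area(self) -> float:
        """Shoelace area in the (V, P) plane; positive = counter-clockwise."""
        v, p = self.volume, self.pressure
        return 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"V": self.volume, "P": self.pressure}).to_csv(path, index=False)


def extract_pv_loop(record: WaveformRecord, chamber: str) -> PVLoop:
    """Final converged beat of ``chamber`` as a closed PV loop."""
    if not record.converged:
        raise UnconvergedRecordError(
            f"record did not reach periodic steady state after {record.beats_run} beats; "
            "refusing to extract a PV loop")
    v = record.last_beat(f"V_{chamber}")
    p = record.last_beat({"LV": "LVP", "RV": "RVP", "LA": "LAP", "RA": "RAP"}[chamber])
    return PVLoop(chamber=chamber, volume=v, pressure=p)


def external_work(loop: PVLoop) -> float:
    """Stroke work (mmHg*mL): absolute enclosed PV-loop area."""
    if len(loop.volume) < 3:
        warnings.warn("degenerate loop (<3 points); external work set to 0")
        return 0.0
    return abs(loop.signed_area())


def pressure_volume_area(loop: PVLoop, V0: float) -> Dict[str, float]:
    """EW, triangular potential energy and their sum PVA for one loop."""
    ew = external_work(loop)
    pe = 0.5 * loop.ESP * (loop.ESV - V0)
    if pe < 0.0:
        warnings.warn(f"ESV {loop.ESV:.1f} mL below V0 {V0:.1f} mL; PE clamped to 0")
        pe = 0.0
    return {"EW": ew, "PE": pe, "PVA": ew + pe}


@dataclass
class EnergeticsResult:
    EW: float
    PE: float
    PVA: float
    Ea: float
    coupling: float           # Ea_S/Ees_Left (left) or Ees_Right/Ea_P (right)
    coupling_inverse: float


def coupling_ratios(loop_LV: PVLoop, loop_RV: PVLoop,
                    chambers: Dict[str, "object"]) -> Tuple[float, float]:
    """(Ea_S/Ees_Left, Ees_Right/Ea_P) from the two ventricular loops."""
    for loop in (loop_LV, loop_RV):
        if loop.stroke_volume <= 0:
            raise ValueError(f"{loop.chamber}: stroke volume <= 0, coupling undefined")
    Ea_S = loop_LV.ESP / loop_LV.stroke_volume
    Ea_P = loop_RV.ESP / loop_RV.stroke_volume
    return Ea_S / chambers["LV"].E_max, chambers["RV"].E_max / Ea_P


def percent_change(value: float, baseline: float) -> Optional[float]:
    if baseline == 0.0:
        return None
    return 100.0 * (value - baseline) / baseline


def _ventricle_energetics(record: WaveformRecord, params: ParameterSet,
                          chamber: str) -> Tuple[PVLoop, EnergeticsResult]:
    loop = extract_pv_loop(record, chamber)
    pva = pressure_volume_area(loop, params.chambers[chamber].V0)
    Ea = loop.ESP / loop.stroke_volume if loop.stroke_volume > 0 else float("nan")
    Ees = params.chambers[chamber].E_max
    if chamber == "LV":
        coupling, inv = Ea / Ees, Ees / Ea
    else:
        coupling, inv = Ees / Ea, Ea / Ees
    return loop, EnergeticsResult(EW=pva["EW"], PE=pva["PE"], PVA=pva["PVA"],
                                  Ea=Ea, coupling=coupling, coupling_inverse=inv)


@dataclass
class ScenarioResult:
    """Cycle-mean haemodynamics + energetics for one (strategy, rpm) run."""

    strategy: Optional[str]
    rpm: float
    values: Dict[str, float]
    percent_changes: Dict[str, Optional[float]]
    loops: Dict[str, PVLoop]

    def value(self, key: str) -> float:
        return self.values[key]

    def change(self, key: str) -> Optional[float]:
        return self.percent_changes.get(key)


def summarize(record: WaveformRecord, baseline_record: Optional[WaveformRecord],
              params: ParameterSet) -> ScenarioResult:
    """Cycle means over the final converged beat, plus changes vs baseline.

    Cardiac output is the net systemic perfusion: native aortic-valve flow
    plus every pump return entering the systemic arterial tree.
    """
    values: Dict[str, float] = {
        "AoP_mean": record.cycle_mean("AoP"),
        "AoP_sys": record.cycle_max("AoP"),
        "PAP_mean": record.cycle_mean("PAP"),
        "LAP_mean": record.cycle_mean("LAP"),
        "RAP_mean": record.cycle_mean("RAP"),
        "CO": record.cardiac_output(),
        "pump_flow": record.cycle_mean("Q_pump") * 60.0 / 1000.0,
    }
    for key, col in FLOW_BRANCHES.items():
        values[key] = record.cycle_mean(col) * 60.0 / 1000.0
    loops: Dict[str, PVLoop] = {}
    for ch in ("LV", "RV"):
        loop, en = _ventricle_energetics(record, params, ch)
        loops[ch] = loop
        values[f"EW_{ch}"] = en.EW
        values[f"PVA_{ch}"] = en.PVA
        values[f"EDV_{ch}"] = loop.EDV
        values[f"ESV_{ch}"] = loop.ESV
        values[f"Ea_{'S' if ch == 'LV' else 'P'}"] = en.Ea
        values[f"coupling_{'left' if ch == 'LV' else 'right'}"] = en.coupling
        values[f"coupling_{'left' if ch == 'LV' else 'right'}_inverse"] = en.coupling_inverse
    loops["LA"] = extract_pv_loop(record, "LA")

    changes: Dict[str, Optional[float]] = {}
    if baseline_record is not None:
        base = summarize(baseline_record, None, params) if not isinstance(
            baseline_record, ScenarioResult) else baseline_record
        for key, v in values.items():
            bv = base.values.get(key)
            changes[key] = None if bv is None else percent_change(v, bv)
    return ScenarioResult(strategy=record.strategy, rpm=record.rpm,
                          values=values, percent_changes=changes, loops=loops)


def resistance_sensitivity(
    params: ParameterSet,
    strategy: str,
    rpm: float,
    scale: float = 1.2,
    baseline_record: Optional[WaveformRecord] = None,
    settings: Optional[SolverSettings] = None,
) -> Tuple[ScenarioResult, ScenarioResult]:
    """Rerun a scenario with the ascending-aorta resistance scaled.

    Returns ``(nominal, scaled)`` scenario results; the scaled run is the
    'starred' condition in which R_AA1 is multiplied by ``scale``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if baseline_record is None:
        baseline_record = simulate(params, settings=settings)
    nominal = simulate(params, strategy=strategy, rpm=rpm, settings=settings)
    scales = dict(params.resistance_scales)
    scales["R_AA1"] = scales.get("R_AA1", 1.0) * scale
    scaled_params = params.copy_with(resistance_scales=scales)
    scaled = simulate(scaled_params, strategy=strategy, rpm=rpm, settings=settings)
    return (summarize(nominal, baseline_record, params),
            summarize(scaled, baseline_record, scaled_params))
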