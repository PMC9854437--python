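"""Configuration I/O and the scenario-suite driver.

A study configuration is a JSON document with two top-level objects:
``parameters`` (a full :class:`~perfusim.parameters.ParameterSet`) and an
optional ``suite`` (:class:`SuiteSpec`).  ``run_suite`` reproduces the
experiment grid: one pump-off baseline plus one run per (strategy, rpm)
pair, writing a tidy summary CSV, per-scenario waveform CSVs and PV-loop
CSVs, and a JSON run log.  Reruns with the same inputs are reproducible
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .parameters import ConfigurationError, ParameterSet
from .pump import STRATEGIES
from .solver import SolverSettings, WaveformRecord, simulate
from .analysis import ScenarioResult, summarize

__all__ = ["SuiteSpec", "load_config", "run_suite", "DEFAULT_RPM_GRID"]

DEFAULT_RPM_GRID = (2000, 2500, 3000, 3500, 4000, 4500)


class SuiteSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    strategies: List[str] = Field(default_factory=lambda: list(STRATEGIES))
    rpm_list: List[float] = Field(default_factory=lambda: list(DEFAULT_RPM_GRID))
    include_baseline: bool = True
    sensitivity_scales: List[float] = Field(default_factory=list)

    def model_post_init(self, __context) -> None:
        if not self.strategies:
            raise ValueError("strategy list must not be empty")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(f"unknown strategies: {unknown}")
        if any(r < 0 for r in self.rpm_list):
            raise ValueError("rpm values must be >= 0")


def _symbolise(loc: Tuple) -> str:
    """Translate a pydantic error location into a Table-symbol-style name."""
    loc = tuple(str(x) for x in loc)
    if len(loc) >= 3 and loc[0] == "compartments":
        return f"{loc[2]}_{loc[1]}"          # ('compartments','HD','C') -> 'C_HD'
    return ".".join(loc)


def load_config(path: str | Path) -> Tuple[ParameterSet, SuiteSpec]:
    """Load and validate a JSON study configuration.

    Unknown keys are rejected; negative resistances/compliances raise a
    :class:`ConfigurationError` naming the offending symbol.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    doc = json.loads(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration root must be a JSON object")
    extra = set(doc) - {"parameters", "suite"}
    if extra:
        raise ConfigurationError(f"unknown top-level keys: {sorted(extra)}")
    if "parameters" not in doc:
        raise ConfigurationError("configuration must contain a 'parameters' object")
    try:
        params = ParameterSet.model_validate(doc["parameters"])
    except ValidationError as err:
        bad = sorted({_symbolise(e["loc"]) for e in err.errors()})
        raise ConfigurationError(f"invalid parameters: {bad}") from err
    try:
        spec = SuiteSpec.model_validate(doc.get("suite", {}))
    except ValidationError as err:
        raise ConfigurationError(f"invalid suite spec: {err}") from err
    return params, spec


@dataclass
class SuiteOutcome:
    summary: pd.DataFrame
    results: Dict[Tuple[Optional[str], float], ScenarioResult]
    records: Dict[Tuple[Optional[str], float], WaveformRecord]
    failed: List[Tuple[str, float, str]] = field(default_factory=list)


_SUMMARY_KEYS = [
    "AoP_mean", "AoP_sys", "PAP_mean", "LAP_mean", "RAP_mean", "CO", "pump_flow",
    "cerebral_flow", "renal_flow", "hepatic_flow", "splanchnic_flow", "svc_flow",
    "EW_LV", "EW_RV", "PVA_LV", "PVA_RV", "EDV_LV", "ESV_LV", "EDV_RV", "ESV_RV",
    "Ea_S", "Ea_P", "coupling_left", "coupling_right",
]


def run_suite(
    params: ParameterSet,
    spec: Optional[SuiteSpec] = None,
    out_dir: Optional[str | Path] = None,
    settings: Optional[SolverSettings] = None,
    write_waveforms: bool = True,
) -> SuiteOutcome:
    """Run the baseline + (strategy, rpm) grid and collect summaries.

    A non-convergent scenario is recorded as failed and the suite
    continues.  If ``out_dir`` is given, writes ``summary.csv``,
    ``waveforms/<strategy>_<rpm>.csv``, ``loops/<chamber>_<strategy>_<rpm>.csv``
    and ``run_log.json`` beneath it.
    """
    spec = spec or SuiteSpec()
    settings = settings or SolverSettings()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "waveforms").mkdir(parents=True, exist_ok=True)
        (out / "loops").mkdir(parents=True, exist_ok=True)

    results: Dict[Tuple[Optional[str], float], ScenarioResult] = {}
    records: Dict[Tuple[Optional[str], float], WaveformRecord] = {}
    failed: List[Tuple[str, float, str]] = []

    baseline = simulate(params, settings=settings)
    records[(None, 0.0)] = baseline
    results[(None, 0.0)] = summarize(baseline, baseline, params)

    for strat in spec.strategies:
        for rpm in spec.rpm_list:
            try:
                rec = simulate(params, strategy=strat, rpm=rpm, settings=settings)
                if not rec.converged:
                    raise RuntimeError(f"no periodic steady state in {rec.beats_run} beats")
                records[(strat, rpm)] = rec
                results[(strat, rpm)] = summarize(rec, baseline, params)
            except Exception as exc:  # noqa: BLE001 - suite continues past failures
                failed.append((strat, rpm, str(exc)))

    rows = []
    for (strat, rpm), res in results.items():
        row = {"strategy": strat or "baseline", "rpm": rpm}
        for k in _SUMMARY_KEYS:
            row[k] = res.values.get(k)
            pc = res.percent_changes.get(k)
            row[f"pct_{k}"] = pc
        rows.append(row)
    for strat, rpm, msg in failed:
        rows.append({"strategy": strat, "rpm": rpm, "error": msg})
    summary = pd.DataFrame(rows)

    if out is not None:
        summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        if write_waveforms:
            for (strat, rpm), rec in records.items():
                name = f"{strat or 'baseline'}_{int(rpm)}"
                rec.to_csv(out / "waveforms" / f"{name}.csv")
                res = results[(strat, rpm)]
                for ch, loop in res.loops.items():
                    loop.to_csv(out / "loops" / f"{ch}_{name}.csv")
        log = {
            "settings": {
                "dt_max": settings.dt_max, "rec_dt": settings.rec_dt,
                "convergence_tol": settings.convergence_tol,
                "min_beats": settings.min_beats, "max_beats": settings.max_beats,
            },
            "scenarios": [
                {"strategy": strat or "baseline", "rpm": rpm,
                 "beats_run": rec.beats_run, "converged": rec.converged}
                for (strat, rpm), rec in records.items()
            ],
            "failed": [{"strategy": s, "rpm": r, "error": m} for s, r, m in failed],
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return SuiteOutcome(summary=summary, results=results, records=records, failed=failed)
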