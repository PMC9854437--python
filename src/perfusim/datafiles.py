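"""Access to the parameter sets shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .parameters import ParameterSet


def data_path(name: str) -> Path:
    return Path(str(resources.files("perfusim").joinpath("data", name)))


def load_tuned_parameters() -> ParameterSet:
    """Calibrated + pump-tuned parameter set used for the scenario suite."""
    return ParameterSet.from_json(data_path("tuned_params.json"))


def load_default_json_parameters() -> ParameterSet:
    """The uncalibrated default set, as shipped in JSON form."""
    return ParameterSet.from_json(data_path("default_params.json"))
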