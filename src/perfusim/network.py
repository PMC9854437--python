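"""Vascular topology: nodes, branches and the closed-loop wiring.

The circulation is a directed graph.  *Nodes* are compliant compartments
with a volume state and pressure ``P = (V - V_unstressed)/C + P_ext``.
*Boundary* vertices (the four heart chambers, or fixed-pressure terminals
in test networks) have their pressure imposed from outside.  Branches are
resistive (algebraic Ohmic flow), diodes (one-way Ohmic flow) or inertial
(their flow is a state obeying ``L dQ/dt = dP - R Q``).

:func:`build_topology` wires the full systemic + pulmonary loop: aortic
root -> ascending aorta / arch -> {head, arms, descending aorta} ->
thoracic -> abdominal I -> {splanchnic, renal, hepatic, abdominal II} ->
legs -> abdominal/inferior vena cava -> right atrium, with head and arms
returning through the superior vena cava, a resistive coronary branch
from the aortic root to the right atrium, and a three-element pulmonary
circulation between the right ventricle and the left atrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .parameters import ConfigurationError, ParameterSet

__all__ = [
    "NodeSpec",
    "Branch",
    "CirculationTopology",
    "build_topology",
    "compartment_derivatives",
    "REQUIRED_COMPARTMENTS",
]


@dataclass(frozen=True)
class NodeSpec:
    name: str
    C: float
    V_unstressed: float
    P_external: float


@dataclass(frozen=True)
class Branch:
    name: str
    src: str
    dst: str
    R: float
    L: float = 0.0
    kind: str = "resistive"  # resistive | diode | inertial


@dataclass
class CirculationTopology:
    """Numeric, self-contained wiring of a lumped-parameter network."""

    nodes: List[NodeSpec]
    branches: List[Branch]
    #: vertices whose pressure is imposed externally (chambers, sources)
    boundaries: List[str]
    #: cannula tap points: role -> vertex name
    taps: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping -------------------------------------------------------
    @property
    def node_names(self) -> List[str]:
        return [n.name for n in self.nodes]

    @property
    def inertial_branches(self) -> List[Branch]:
        return [b for b in self.branches if b.kind == "inertial"]

    @property
    def state_size(self) -> int:
        return len(self.nodes) + len(self.inertial_branches)

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate compartment in topology")
        seen = set(names) | set(self.boundaries)
        touched = set()
        for b in self.branches:
            for end in (b.src, b.dst):
                if end not in seen:
                    raise ConfigurationError(
                        f"branch {b.name!r} references unknown vertex {end!r}")
            touched.add(b.src)
            touched.add(b.dst)
        dangling = set(names) - touched
        if dangling:
            raise ConfigurationError(f"dangling compartments: {sorted(dangling)}")
        for node in self.nodes:
            if node.C <= 0:
                raise ConfigurationError(f"compartment {node.name} needs C > 0")
        for role, vertex in self.taps.items():
            if vertex not in seen:
                raise ConfigurationError(f"cannula tap {role} references unknown vertex {vertex!r}")


# ---------------------------------------------------------------------------
# Full circulation wiring
# ---------------------------------------------------------------------------

#: compartment symbols that must be present, with the fields each must carry
REQUIRED_COMPARTMENTS: Dict[str, Tuple[str, ...]] = {
    "AA1": ("R", "C"), "AA2": ("R", "C"), "THOR": ("R",), "AT1": ("R", "C"),
    "AB1": ("R", "C"), "ABII": ("R", "C"),
    "HD": ("R", "C"), "HD2": ("R",), "ARM": ("R", "C"), "ARM2": ("R",),
    "SP": ("R", "C"), "SP2": ("R",), "KID": ("R", "C"), "KID2": ("R",),
    "HEP": ("R", "C"), "HEP2": ("R",),
    "LLE": ("R", "C"), "LFV": ("R",), "RLE": ("R", "C"), "RFV": ("R",),
    "SVC": ("R", "C"), "AbdVC": ("R", "C"), "IVC": ("R", "C"), "IVC2": ("R",),
    "COR": ("R",),
    "PA": ("R", "C"), "PC": ("R", "C"), "PVEN": ("R", "C"),
}

#: symbols whose R is a variable resistance (scaled by resistance_scales)
VARIABLE_RESISTANCES = ("HD", "ARM", "SP", "KID", "HEP", "LLE", "RLE", "AA1")

CHAMBER_BOUNDARIES = ["LV", "RV", "LA", "RA"]


def _ext_pressure(params: ParameterSet, ref: str) -> float:
    env = params.environment
    if ref == "intrathoracic":
        return env.Pt + env.P_B
    if ref == "abdominal":
        return env.P_abdominal
    return 0.0


def build_topology(params: ParameterSet) -> CirculationTopology:
    """Wire the closed systemic + pulmonary loop from a parameter set.

    Raises :class:`ConfigurationError` naming the offending symbol if a
    compartment (or one of its required element values) is missing.
    """
    comps = params.compartments
    missing = [sym for sym in REQUIRED_COMPARTMENTS if sym not in comps]
    if missing:
        raise ConfigurationError(f"missing compartments: {missing}")
    for sym, fields in REQUIRED_COMPARTMENTS.items():
        c = comps[sym]
        if "C" in fields and c.C <= 0:
            raise ConfigurationError(f"C_{sym}")
        if "R" in fields and c.R < 0:
            raise ConfigurationError(f"R_{sym}")
    if comps["AA1"].L > 0:
        raise ConfigurationError(
            "L_AA1 > 0 is not supported: the ascending-aorta impedance sits on "
            "the aortic-valve branch, which cannot carry an inertance")

    def node(sym: str) -> NodeSpec:
        c = comps[sym]
        return NodeSpec(sym, c.C, c.V_unstressed, _ext_pressure(params, c.external_pressure_ref))

    def eff_R(sym: str) -> float:
        base = comps[sym].R
        if sym in VARIABLE_RESISTANCES:
            return params.scaled_resistance(f"R_{sym}", base)
        return base

    node_order = ["AA1", "AA2", "AT1", "AB1", "ABII", "HD", "ARM", "LLE", "RLE",
                  "SP", "KID", "HEP", "SVC", "IVC", "AbdVC", "PA", "PC", "PVEN"]
    nodes = [node(s) for s in node_order]

    v = params.valves
    branches = [
        # heart valves (the aortic valve carries the ascending-aorta R in series)
        Branch("MV", "LA", "LV", v["MV"].R_open, kind="diode"),
        Branch("AV", "LV", "AA1", v["AV"].R_open + eff_R("AA1"), kind="diode"),
        Branch("TV", "RA", "RV", v["TV"].R_open, kind="diode"),
        Branch("PV", "RV", "PA", v["PV"].R_open, kind="diode"),
        # aortic ladder (inertial)
        Branch("arch", "AA1", "AA2", comps["AA2"].R, comps["AA2"].L, "inertial"),
        Branch("desc", "AA2", "AT1", comps["THOR"].R + comps["AT1"].R, comps["AT1"].L, "inertial"),
        Branch("thor", "AT1", "AB1", comps["AB1"].R, comps["AB1"].L, "inertial"),
        Branch("abd", "AB1", "ABII", comps["ABII"].R, comps["ABII"].L, "inertial"),
        # head and upper limbs
        Branch("head_art", "AA1", "HD", eff_R("HD")),
        Branch("head_ven", "HD", "SVC", comps["HD2"].R),
        Branch("arm_art", "AA1", "ARM", eff_R("ARM")),
        Branch("arm_ven", "ARM", "SVC", comps["ARM2"].R),
        # abdominal organ beds
        Branch("spl_art", "AB1", "SP", eff_R("SP")),
        Branch("spl_ven", "SP", "AbdVC", comps["SP2"].R),
        Branch("ren_art", "AB1", "KID", eff_R("KID")),
        Branch("ren_ven", "KID", "AbdVC", comps["KID2"].R),
        Branch("hep_art", "AB1", "HEP", eff_R("HEP")),
        Branch("hep_ven", "HEP", "AbdVC", comps["HEP2"].R),
        # legs
        Branch("lleg_art", "ABII", "LLE", eff_R("LLE")),
        Branch("lleg_ven", "LLE", "AbdVC", comps["LFV"].R),
        Branch("rleg_art", "ABII", "RLE", eff_R("RLE")),
        Branch("rleg_ven", "RLE", "AbdVC", comps["RFV"].R),
        # venous collectors
        Branch("abdvc_ivc", "AbdVC", "IVC", comps["AbdVC"].R + comps["IVC"].R),
        Branch("ivc_ra", "IVC", "RA", comps["IVC2"].R),
        Branch("svc_ra", "SVC", "RA", comps["SVC"].R),
        # coronary stub
        Branch("coronary", "AA1", "RA", comps["COR"].R),
        # pulmonary circulation
        Branch("pulm_art", "PA", "PC", comps["PA"].R, comps["PA"].L, "inertial"),
        Branch("pulm_cap", "PC", "PVEN", comps["PC"].R),
        Branch("pulm_ven", "PVEN", "LA", comps["PVEN"].R),
    ]
    taps = {
        "in_RA": "RA", "in_SVC": "SVC", "in_FV": "AbdVC",
        "out_AA": "AA1", "out_CC": "HD", "out_FA": "ABII",
    }
    return CirculationTopology(nodes=nodes, branches=branches,
                               boundaries=list(CHAMBER_BOUNDARIES), taps=taps)


# ---------------------------------------------------------------------------
# Reference derivative evaluation (pure python/numpy)
# ---------------------------------------------------------------------------

def compartment_derivatives(
    state: np.ndarray,
    topology: CirculationTopology,
    boundary_pressures: Optional[Dict[str, float]] = None,
    t: float = 0.0,
    external_flows: Optional[Dict[str, float]] = None,
) -> np.ndarray:
    """Time derivative of the vascular state ``[node volumes, inertial flows]``.

    ``boundary_pressures`` supplies the pressure of every boundary vertex
    (heart chambers or fixed terminals); ``external_flows`` adds signed
    source flows (mL/s, positive into the vertex) at named vertices, which
    is how cannulae enter.  This is the straightforward reference
    implementation; the production solver evaluates the same equations in
    a compiled kernel.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        labels = topology.node_names + [b.name for b in topology.inertial_branches]
        raise FloatingPointError(f"non-finite state for {labels[bad]!r}")
    nn = len(topology.nodes)
    if state.shape[0] != topology.state_size:
        raise ValueError("state dimension does not match topology")
    boundary_pressures = boundary_pressures or {}
    pressures: Dict[str, float] = dict(boundary_pressures)
    for i, node in enumerate(topology.nodes):
        pressures[node.name] = (state[i] - node.V_unstressed) / node.C + node.P_external

    dV = np.zeros(nn)
    dQ = []
    inert = topology.inertial_branches

    def add_flow(name: str, q: float) -> None:
        if name in boundary_pressures or name in topology.boundaries:
            return
        dV[topology.node_index(name)] += q

    qi = 0
    for b in topology.branches:
        if b.kind == "inertial":
            q = state[nn + qi]
            dQ.append((pressures[b.src] - pressures[b.dst] - b.R * q) / b.L)
            qi += 1
        else:
            dp = pressures[b.src] - pressures[b.dst]
            if b.kind == "diode" and dp <= 0.0:
                q = 0.0
            else:
                q = dp / b.R
        add_flow(b.src, -q)
        add_flow(b.dst, +q)

    if external_flows:
        for name, q in external_flows.items():
            add_flow(name, q)

    return np.concatenate([dV, np.asarray(dQ, dtype=float)]) if dQ else dV
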