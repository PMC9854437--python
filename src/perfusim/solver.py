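"""Global ODE assembly, fixed-step integration and cycle convergence.

The full model state is ``x = [V_LV, V_RV, V_LA, V_RA, V_node(18), Q_inertial(5)]``
(27 states).  The right-hand side is evaluated in a numba-compiled kernel:
chamber pressures from the time-varying elastances with septal coupling,
node pressures from their compliances, diode valves smoothed by a sharp
but continuous conductance ramp (width ``eps`` mmHg), the extracorporeal
pump junction solved algebraically so that inlet and outlet cannula flows
balance exactly.

Integration is classic RK4 with a fixed step chosen to divide the beat
period exactly.  A fixed step keeps runs bitwise reproducible and, with
the valve smoothing, the system is not stiff at the default step of
0.2 ms.  Beats are integrated one at a time until the cycle means of
aortic pressure, systemic output, left and right atrial pressure all
change by less than ``convergence_tol`` between consecutive beats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

from .parameters import ConfigurationError, ParameterSet
from .network import CirculationTopology, build_topology
from .pump import CannulationCircuit, apply_cannulation, configure_switches

__all__ = ["SolverSettings", "WaveformRecord", "simulate", "check_conservation", "ModelAssembly"]

CHAMBERS = ("LV", "RV", "LA", "RA")
N_CHAMBERS = 4

#: pressure column names: chambers then nodes, in assembly order
PRESSURE_NAMES = {
    "LV": "LVP", "RV": "RVP", "LA": "LAP", "RA": "RAP",
    "AA1": "AoP", "AA2": "DAP", "AT1": "THP", "AB1": "ABP_I", "ABII": "ABP_II",
    "HD": "HDP", "ARM": "ARP", "LLE": "LLEP", "RLE": "RLEP",
    "SP": "SPP", "KID": "KP", "HEP": "HP",
    "SVC": "SVCP", "IVC": "IVCP", "AbdVC": "AbdVCP",
    "PA": "PAP", "PC": "PCP", "PVEN": "PVP",
}


@dataclass
class SolverSettings:
    dt_max: float = 2e-4            # integration step (s); rounded to divide the beat
    rec_dt: float = 1e-3            # sampling interval of the waveform record (s)
    convergence_tol: float = 1e-3   # max relative change of cycle means between beats
    min_beats: int = 10
    max_beats: int = 200
    start_phase: float = 0.0        # fraction of the beat at which integration starts
    eps_valve: float = 1e-3         # smoothing width of the diode conductance ramp (mmHg)

    def __post_init__(self) -> None:
        if self.dt_max <= 0 or self.convergence_tol <= 0:
            raise ConfigurationError("solver tolerances must be positive")
        if self.max_beats < 2:
            raise ConfigurationError("max_beats must be >= 2")


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _eval_rhs(t, x, C, Vu, Pext, rb_src, rb_dst, rb_R,
              d_src, d_dst, d_R, ib_src, ib_dst, ib_R, ib_L,
              ch_Emax, ch_Emin, ch_V0, scal,
              in_codes, in_g, out_codes, out_g, dx, aux):
    (period, t_sys_v, t_sys_a, av_delay, Pt, Es_max, Es_min,
     k1, k2, k3, omega, eps) = (scal[0], scal[1], scal[2], scal[3], scal[4],
                                scal[5], scal[6], scal[7], scal[8], scal[9],
                                scal[10], scal[11])
    nn = C.shape[0]
    nstate = N_CHAMBERS + nn + ib_R.shape[0]
    for i in range(nstate):
        dx[i] = 0.0

    # activations (ventricular onset at t = 0 mod period; atria lead by av_delay)
    tau_v = t % period
    e_v = 0.0
    if tau_v < t_sys_v:
        e_v = 0.5 * (1.0 - math.cos(2.0 * math.pi * tau_v / t_sys_v))
    tau_a = (t + av_delay) % period
    e_a = 0.0
    if tau_a < t_sys_a:
        e_a = 0.5 * (1.0 - math.cos(2.0 * math.pi * tau_a / t_sys_a))

    # chamber pressures with septal coupling of the ventricles
    E_L = ch_Emin[0] + e_v * (ch_Emax[0] - ch_Emin[0])
    E_R = ch_Emin[1] + e_v * (ch_Emax[1] - ch_Emin[1])
    E_S = Es_min + e_v * (Es_max - Es_min)
    v_spt = (E_L * (x[0] - ch_V0[0]) - E_R * (x[1] - ch_V0[1])) / (E_S + E_L + E_R)
    aux[0] = E_L * (x[0] - v_spt - ch_V0[0]) + Pt
    aux[1] = E_R * (x[1] + v_spt - ch_V0[1]) + Pt
    E_LA = ch_Emin[2] + e_a * (ch_Emax[2] - ch_Emin[2])
    E_RA = ch_Emin[3] + e_a * (ch_Emax[3] - ch_Emin[3])
    aux[2] = E_LA * (x[2] - ch_V0[2]) + Pt
    aux[3] = E_RA * (x[3] - ch_V0[3]) + Pt
    for i in range(nn):
        aux[N_CHAMBERS + i] = (x[N_CHAMBERS + i] - Vu[i]) / C[i] + Pext[i]

    # diode valves, smoothed: q = (dp + sqrt(dp^2 + eps^2)) / (2 R) >= 0
    for k in range(d_R.shape[0]):
        dp = aux[d_src[k]] - aux[d_dst[k]]
        q = (dp + math.sqrt(dp * dp + eps * eps)) / (2.0 * d_R[k])
        aux[22 + k] = q
        dx[d_src[k]] -= q
        dx[d_dst[k]] += q

    # algebraic resistive branches
    for k in range(rb_R.shape[0]):
        dp = aux[rb_src[k]] - aux[rb_dst[k]]
        q = dp / rb_R[k]
        aux[26 + k] = q
        dx[rb_src[k]] -= q
        dx[rb_dst[k]] += q

    # inertial branches: flow is a state
    for k in range(ib_R.shape[0]):
        q = x[N_CHAMBERS + nn + k]
        aux[46 + k] = q
        dx[ib_src[k]] -= q
        dx[ib_dst[k]] += q
        dp = aux[ib_src[k]] - aux[ib_dst[k]]
        dx[N_CHAMBERS + nn + k] = (dp - ib_R[k] * q) / ib_L[k]

    # extracorporeal pump junction (no storage: flows balance exactly)
    Q = 0.0
    P_in = 0.0
    P_out = 0.0
    for k in range(3):
        aux[54 + k] = 0.0
        aux[57 + k] = 0.0
    if omega > 0.0 and in_g.shape[0] > 0 and out_g.shape[0] > 0:
        G_in = 0.0
        Pbar_in = 0.0
        for k in range(in_g.shape[0]):
            G_in += in_g[k]
            Pbar_in += in_g[k] * aux[in_codes[k]]
        Pbar_in /= G_in
        G_out = 0.0
        Pbar_out = 0.0
        for k in range(out_g.shape[0]):
            G_out += out_g[k]
            Pbar_out += out_g[k] * aux[out_codes[k]]
        Pbar_out /= G_out
        R_tot = 1.0 / G_in + 1.0 / G_out
        b = k2 * omega + R_tot
        c = (Pbar_out - Pbar_in) - k1 * omega * omega
        if k3 == 0.0:
            Q = -c / b
        elif c <= 0.0:
            Q = (-b + math.sqrt(b * b - 4.0 * k3 * c)) / (2.0 * k3)
        else:
            Q = -(-b + math.sqrt(b * b + 4.0 * k3 * c)) / (2.0 * k3)
        P_in = Pbar_in - Q / G_in
        P_out = Pbar_out + Q / G_out
        for k in range(in_g.shape[0]):
            qi = in_g[k] * (aux[in_codes[k]] - P_in)
            aux[54 + k] = qi
            dx[in_codes[k]] -= qi
        for k in range(out_g.shape[0]):
            qo = out_g[k] * (P_out - aux[out_codes[k]])
            aux[57 + k] = qo
            dx[out_codes[k]] += qo
    aux[51] = Q
    aux[52] = P_in
    aux[53] = P_out
    aux[60] = v_spt
    aux[61] = e_v
    aux[62] = e_a


@njit(cache=True)
def _integrate_beat(x, t0, nsteps, dt, rec_every,
                    C, Vu, Pext, rb_src, rb_dst, rb_R,
                    d_src, d_dst, d_R, ib_src, ib_dst, ib_R, ib_L,
                    ch_Emax, ch_Emin, ch_V0, scal,
                    in_codes, in_g, out_codes, out_g,
                    rec_t, rec_x, rec_aux):
    n = x.shape[0]
    naux = rec_aux.shape[1]
    k1v = np.empty(n)
    k2v = np.empty(n)
    k3v = np.empty(n)
    k4v = np.empty(n)
    xtmp = np.empty(n)
    aux = np.empty(naux)
    irec = 0
    t = t0
    for step in range(nsteps):
        _eval_rhs(t, x, C, Vu, Pext, rb_src, rb_dst, rb_R, d_src, d_dst, d_R,
                  ib_src, ib_dst, ib_R, ib_L, ch_Emax, ch_Emin, ch_V0, scal,
                  in_codes, in_g, out_codes, out_g, k1v, aux)
        if step % rec_every == 0:
            rec_t[irec] = t
            for i in range(n):
                rec_x[irec, i] = x[i]
            for i in range(naux):
                rec_aux[irec, i] = aux[i]
            irec += 1
        for i in range(n):
            xtmp[i] = x[i] + 0.5 * dt * k1v[i]
        _eval_rhs(t + 0.5 * dt, xtmp, C, Vu, Pext, rb_src, rb_dst, rb_R, d_src, d_dst, d_R,
                  ib_src, ib_dst, ib_R, ib_L, ch_Emax, ch_Emin, ch_V0, scal,
                  in_codes, in_g, out_codes, out_g, k2v, aux)
        for i in range(n):
            xtmp[i] = x[i] + 0.5 * dt * k2v[i]
        _eval_rhs(t + 0.5 * dt, xtmp, C, Vu, Pext, rb_src, rb_dst, rb_R, d_src, d_dst, d_R,
                  ib_src, ib_dst, ib_R, ib_L, ch_Emax, ch_Emin, ch_V0, scal,
                  in_codes, in_g, out_codes, out_g, k3v, aux)
        for i in range(n):
            xtmp[i] = x[i] + dt * k3v[i]
        _eval_rhs(t + dt, xtmp, C, Vu, Pext, rb_src, rb_dst, rb_R, d_src, d_dst, d_R,
                  ib_src, ib_dst, ib_R, ib_L, ch_Emax, ch_Emin, ch_V0, scal,
                  in_codes, in_g, out_codes, out_g, k4v, aux)
        for i in range(n):
            x[i] = x[i] + (dt / 6.0) * (k1v[i] + 2.0 * k2v[i] + 2.0 * k3v[i] + k4v[i])
        t = t0 + (step + 1) * dt
    return irec


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

NAUX = 63


class ModelAssembly:
    """Packed-array form of a parameter set + cannulation for the kernel."""

    def __init__(self, params: ParameterSet, strategy: Optional[str] = None,
                 rpm: float = 0.0, settings: Optional[SolverSettings] = None):
        self.params = params
        self.settings = settings or SolverSettings()
        self.topology: CirculationTopology = build_topology(params)
        self.strategy = strategy
        self.rpm = float(rpm)

        topo = self.topology
        self.node_names = topo.node_names
        nn = len(self.node_names)
        code = {name: i for i, name in enumerate(CHAMBERS)}
        for i, name in enumerate(self.node_names):
            code[name] = N_CHAMBERS + i
        self.code = code

        self.C = np.array([n.C for n in topo.nodes])
        self.Vu = np.array([n.V_unstressed for n in topo.nodes])
        self.Pext = np.array([n.P_external for n in topo.nodes])

        diodes = [b for b in topo.branches if b.kind == "diode"]
        resist = [b for b in topo.branches if b.kind == "resistive"]
        inert = [b for b in topo.branches if b.kind == "inertial"]
        if len(diodes) > 4 or len(resist) > 20 or len(inert) > 5:
            raise ConfigurationError("assembly exceeds the kernel's branch capacity")
        self.diode_names = [b.name for b in diodes]
        self.resist_names = [b.name for b in resist]
        self.inert_names = [b.name for b in inert]

        def codes(bs, attr):
            return np.array([code[getattr(b, attr)] for b in bs], dtype=np.int64)

        self.d_src, self.d_dst = codes(diodes, "src"), codes(diodes, "dst")
        self.d_R = np.array([b.R for b in diodes])
        self.rb_src, self.rb_dst = codes(resist, "src"), codes(resist, "dst")
        self.rb_R = np.array([b.R for b in resist])
        self.ib_src, self.ib_dst = codes(inert, "src"), codes(inert, "dst")
        self.ib_R = np.array([b.R for b in inert])
        self.ib_L = np.array([b.L for b in inert])

        ch = params.chambers
        self.ch_Emax = np.array([ch[c].E_max for c in CHAMBERS])
        self.ch_Emin = np.array([ch[c].E_min for c in CHAMBERS])
        self.ch_V0 = np.array([ch[c].V0 for c in CHAMBERS])

        tm = params.timing.resolved()
        env = params.environment
        self.scal = np.array([
            tm.period, tm.T_sys_ventricular, tm.T_sys_atrial, tm.AV_delay,
            env.Pt + env.P_B, params.septum.E_spt_max, params.septum.E_spt_min,
            params.pump.k1, params.pump.k2, params.pump.k3, self.rpm,
            self.settings.eps_valve,
        ])

        if strategy is not None:
            self.circuit: Optional[CannulationCircuit] = apply_cannulation(
                topo, configure_switches(strategy), params.pump, params.cannulae)
            self.in_roles = [r for r in self.circuit.config.active_cannulae if r.startswith("in_")]
            self.out_roles = [r for r in self.circuit.config.active_cannulae if r.startswith("out_")]
            self.in_codes = np.array([code[topo.taps[r]] for r in self.in_roles], dtype=np.int64)
            self.in_g = np.array([1.0 / params.cannulae[r].R for r in self.in_roles])
            self.out_codes = np.array([code[topo.taps[r]] for r in self.out_roles], dtype=np.int64)
            self.out_g = np.array([1.0 / params.cannulae[r].R for r in self.out_roles])
        else:
            self.circuit = None
            self.in_roles, self.out_roles = [], []
            self.in_codes = np.zeros(0, dtype=np.int64)
            self.in_g = np.zeros(0)
            self.out_codes = np.zeros(0, dtype=np.int64)
            self.out_g = np.zeros(0)

        self.n_state = N_CHAMBERS + nn + len(inert)

        # per-beat step counts
        self.dt = tm.period / max(1, round(tm.period / self.settings.dt_max))
        self.rec_every = max(1, round(self.settings.rec_dt / self.dt))
        self.steps_per_beat = round(tm.period / self.dt)
        self.samples_per_beat = (self.steps_per_beat + self.rec_every - 1) // self.rec_every

        # aux column names
        names: List[str] = []
        for c in CHAMBERS:
            names.append(PRESSURE_NAMES[c])
        for nname in self.node_names:
            names.append(PRESSURE_NAMES[nname])
        names += [f"Q_{n}" for n in self.diode_names]
        names += [f"Q_{n}" for n in self.resist_names]
        names += [f"Q_{n}" for n in self.inert_names]
        names += ["Q_pump", "P_pump_in", "P_pump_out"]
        for k in range(3):
            names.append(f"Q_{self.in_roles[k]}" if k < len(self.in_roles) else f"Q_in_unused{k}")
        for k in range(3):
            names.append(f"Q_{self.out_roles[k]}" if k < len(self.out_roles) else f"Q_out_unused{k}")
        names += ["V_spt", "e_v", "e_a"]
        # pad Q_resist block up to 20 and Q_inert up to 5 with placeholders
        self.aux_names = self._padded_aux_names(names)

    def _padded_aux_names(self, names: List[str]) -> List[str]:
        out = names[:22]
        out += names[22:22 + len(self.diode_names)]
        out += ["_pad_d%d" % k for k in range(4 - len(self.diode_names))]
        base = 22 + len(self.diode_names)
        out += names[base:base + len(self.resist_names)]
        out += ["_pad_r%d" % k for k in range(20 - len(self.resist_names))]
        base += len(self.resist_names)
        out += names[base:base + len(self.inert_names)]
        out += ["_pad_i%d" % k for k in range(5 - len(self.inert_names))]
        base += len(self.inert_names)
        out += names[base:]
        assert len(out) == NAUX, len(out)
        return out

    # -- initial state ------------------------------------------------------
    _P_INIT = {
        "AA1": 70.0, "AA2": 69.0, "AT1": 68.5, "AB1": 68.0, "ABII": 67.0,
        "HD": 12.0, "ARM": 12.0, "LLE": 12.0, "RLE": 12.0,
        "SP": 13.0, "KID": 13.0, "HEP": 13.0,
        "SVC": 10.5, "IVC": 10.5, "AbdVC": 11.0,
        "PA": 22.0, "PC": 21.5, "PVEN": 21.0,
    }
    _V_CHAMBER_INIT = {"LV": 170.0, "RV": 180.0, "LA": 100.0, "RA": 90.0}
    _VENOUS_RESERVOIRS = ("SVC", "IVC", "AbdVC")

    def initial_state(self) -> np.ndarray:
        x = np.zeros(self.n_state)
        for i, c in enumerate(CHAMBERS):
            x[i] = self._V_CHAMBER_INIT[c]
        for i, (name, node) in enumerate(zip(self.node_names, self.topology.nodes)):
            x[N_CHAMBERS + i] = node.V_unstressed + node.C * (self._P_INIT[name] - node.P_external)
        extra = self.params.volume_adjust
        if extra:
            cs = np.array([self.C[self.node_names.index(n)] for n in self._VENOUS_RESERVOIRS])
            for n, c in zip(self._VENOUS_RESERVOIRS, cs):
                x[N_CHAMBERS + self.node_names.index(n)] += extra * c / cs.sum()
        return x

    # -- python-side RHS (for tests and cross-checks) -----------------------
    def rhs(self, t: float, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        dx = np.zeros(self.n_state)
        aux = np.zeros(NAUX)
        _eval_rhs(t, np.asarray(x, dtype=float), self.C, self.Vu, self.Pext,
                  self.rb_src, self.rb_dst, self.rb_R,
                  self.d_src, self.d_dst, self.d_R,
                  self.ib_src, self.ib_dst, self.ib_R, self.ib_L,
                  self.ch_Emax, self.ch_Emin, self.ch_V0, self.scal,
                  self.in_codes, self.in_g, self.out_codes, self.out_g, dx, aux)
        return dx, aux

    def run_beat(self, x: np.ndarray, t0: float):
        ns = self.samples_per_beat
        rec_t = np.empty(ns)
        rec_x = np.empty((ns, self.n_state))
        rec_aux = np.empty((ns, NAUX))
        nrec = _integrate_beat(x, t0, self.steps_per_beat, self.dt, self.rec_every,
                               self.C, self.Vu, self.Pext,
                               self.rb_src, self.rb_dst, self.rb_R,
                               self.d_src, self.d_dst, self.d_R,
                               self.ib_src, self.ib_dst, self.ib_R, self.ib_L,
                               self.ch_Emax, self.ch_Emin, self.ch_V0, self.scal,
                               self.in_codes, self.in_g, self.out_codes, self.out_g,
                               rec_t, rec_x, rec_aux)
        return rec_t[:nrec], rec_x[:nrec], rec_aux[:nrec]


# ---------------------------------------------------------------------------
# Waveform record
# ---------------------------------------------------------------------------

@dataclass
class WaveformRecord:
    """Time-sampled pressures, flows and volumes over the recorded beats."""

    time: np.ndarray
    states: np.ndarray            # (n_samples, n_state)
    aux: np.ndarray               # (n_samples, NAUX)
    aux_names: List[str]
    state_names: List[str]
    samples_per_beat: int
    n_beats_recorded: int
    beats_run: int
    converged: bool
    period: float
    strategy: Optional[str]
    rpm: float
    convergence_history: List[Dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        if name in self.aux_names:
            return self.aux[:, self.aux_names.index(name)]
        if name in self.state_names:
            return self.states[:, self.state_names.index(name)]
        raise KeyError(name)

    def last_beat(self, name: str) -> np.ndarray:
        return self.column(name)[-self.samples_per_beat:]

    def cycle_mean(self, name: str) -> float:
        return float(np.mean(self.last_beat(name)))

    def cycle_max(self, name: str) -> float:
        return float(np.max(self.last_beat(name)))

    def cycle_min(self, name: str) -> float:
        return float(np.min(self.last_beat(name)))

    def systemic_inflow(self) -> np.ndarray:
        """Instantaneous net systemic arterial inflow (mL/s): native aortic
        valve flow plus every pump return entering the systemic tree."""
        q = self.column("Q_AV").copy()
        for n in self.aux_names:
            if n.startswith("Q_out_") and not n.startswith("Q_out_unused"):
                q = q + self.column(n)
        return q

    def cardiac_output(self) -> float:
        """Cycle-mean systemic perfusion in L/min."""
        return float(np.mean(self.systemic_inflow()[-self.samples_per_beat:])) * 60.0 / 1000.0

    def to_dataframe(self):
        import pandas as pd

        data = {"time": self.time}
        for i, n in enumerate(self.state_names):
            data[n] = self.states[:, i]
        for i, n in enumerate(self.aux_names):
            if not n.startswith("_pad"):
                data[n] = self.aux[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def total_volume(self) -> np.ndarray:
        n_vol = sum(n.startswith("V_") for n in self.state_names)
        return self.states[:, :n_vol].sum(axis=1)


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def simulate(
    params: ParameterSet,
    strategy: Optional[str] = None,
    rpm: float = 0.0,
    settings: Optional[SolverSettings] = None,
    record: str = "last2",
    initial_state: Optional[np.ndarray] = None,
) -> WaveformRecord:
    """Integrate the closed loop to periodic steady state.

    ``strategy=None`` (or ``rpm=0`` with all switches off) is the native
    circulation.  Returns the final recorded beats (``record='last2'``) or
    every beat (``record='all'``).  Deterministic for fixed inputs.
    """
    settings = settings or SolverSettings()
    asm = ModelAssembly(params, strategy=strategy, rpm=rpm, settings=settings)
    tm = params.timing.resolved()
    x = asm.initial_state().copy() if initial_state is None else np.array(initial_state, dtype=float)
    if x.shape[0] != asm.n_state:
        raise ConfigurationError("initial state has wrong dimension")

    state_names = ([f"V_{c}" for c in CHAMBERS] + [f"V_{n}" for n in asm.node_names]
                   + [f"Q_{n}" for n in asm.inert_names])

    keep_all = record == "all"
    history: List[Dict[str, float]] = []
    beats: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    prev = None
    converged = False
    beats_run = 0
    t0 = settings.start_phase * tm.period
    co_cols = None
    for beat in range(settings.max_beats):
        rec_t, rec_x, rec_aux = asm.run_beat(x, t0 + beat * tm.period)
        beats_run += 1
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise FloatingPointError(
                f"non-finite value in {state_names[bad]!r} at t={t0 + (beat + 1) * tm.period:.4f} s")
        if keep_all:
            beats.append((rec_t, rec_x, rec_aux))
        else:
            beats = beats[-1:] + [(rec_t, rec_x, rec_aux)]
        if co_cols is None:
            iaux = {n: i for i, n in enumerate(asm.aux_names)}
            co_cols = [iaux["Q_AV"]] + [iaux[f"Q_{r}"] for r in asm.out_roles]
        means = {
            "AoP": float(rec_aux[:, asm.aux_names.index("AoP")].mean()),
            "CO": float(sum(rec_aux[:, c].mean() for c in co_cols)),
            "LAP": float(rec_aux[:, asm.aux_names.index("LAP")].mean()),
            "RAP": float(rec_aux[:, asm.aux_names.index("RAP")].mean()),
        }
        history.append(means)
        if prev is not None and beat + 1 >= settings.min_beats:
            ok = True
            for k, v in means.items():
                ref = max(abs(prev[k]), 1e-6)
                if abs(v - prev[k]) / ref >= settings.convergence_tol:
                    ok = False
                    break
            if ok:
                converged = True
                break
        prev = means

    rec_t = np.concatenate([b[0] for b in beats])
    rec_x = np.concatenate([b[1] for b in beats])
    rec_aux = np.concatenate([b[2] for b in beats])
    return WaveformRecord(
        time=rec_t, states=rec_x, aux=rec_aux, aux_names=asm.aux_names,
        state_names=state_names, samples_per_beat=asm.samples_per_beat,
        n_beats_recorded=len(beats), beats_run=beats_run, converged=converged,
        period=tm.period, strategy=strategy, rpm=rpm, convergence_history=history,
    )


def check_conservation(record: WaveformRecord, params: Optional[ParameterSet] = None) -> Dict[str, float]:
    """Report the drift of total blood volume over a recorded run."""
    total = record.total_volume()
    v0 = float(total[0])
    drift = float(np.max(np.abs(total - v0)) / v0)
    return {
        "initial_volume_mL": v0,
        "final_volume_mL": float(total[-1]),
        "max_relative_drift": drift,
    }
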