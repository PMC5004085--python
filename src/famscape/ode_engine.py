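"""Config-driven two-cell conductance-based simulator.

The engine integrates a pair of identical single-compartment cells coupled
by graded and spike-mediated inhibitory synapses.  Current kinetics are not
hard-coded: they come from a YAML model config (see ``data/surrogate.yaml``
for the packaged surrogate model and the schema-by-example).  Units are
mV / nS / pF / pA with time in ms internally; the public protocol speaks
seconds.

Voltage-gated currents follow ``I = g * prod(x_i^p_i) * (V - E)`` with each
gate obeying ``dx/dt = (x_inf(V) - x) / tau(V)``;
``x_inf(V) = 1 / (1 + exp((V - vhalf) / k))`` (k < 0 activates with
depolarization, k > 0 inactivates), and ``tau`` either constant or a
cosh-bell ``base + amp / cosh((V - vhalf) / width)``.  The graded synapse
drives a first-order conductance toward a sigmoid of presynaptic voltage;
the spike-mediated synapse is a rise/decay conductance gated by the
presynaptic voltage crossing the spike threshold, i.e. each presynaptic
spike injects a stereotyped conductance transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .burst_metrics import SPIKE_THRESHOLD_MV, detect_spikes
from .gridspace import ParameterPoint
from .traces import TracePair

__all__ = [
    "GateSpec",
    "CurrentSpec",
    "SynapseSpec",
    "ModelConfig",
    "SimProtocol",
    "load_model_config",
    "load_surrogate_config",
    "make_initial_state",
    "simulate_pair",
]

_V_CHECK_RANGE = np.linspace(-120.0, 60.0, 181)


@dataclass(frozen=True)
class GateSpec:
    power: int = 1
    vhalf_mV: float = -40.0
    k_mV: float = -5.0
    instantaneous: bool = False
    tau_form: str = "constant"  # constant | bell
    tau_base_ms: float = 1.0
    tau_amp_ms: float = 0.0
    tau_vhalf_mV: float = -40.0
    tau_width_mV: float = 10.0

    def x_inf(self, v: np.ndarray | float):
        return 1.0 / (1.0 + np.exp((v - self.vhalf_mV) / self.k_mV))

    def tau(self, v: np.ndarray | float):
        if self.tau_form == "constant":
            return self.tau_base_ms
        return self.tau_base_ms + self.tau_amp_ms / np.cosh(
            (v - self.tau_vhalf_mV) / self.tau_width_mV
        )

    def validate(self) -> None:
        if self.tau_form not in {"constant", "bell"}:
            raise ValueError(f"unknown tau form {self.tau_form!r}")
        if not self.instantaneous:
            taus = np.asarray(self.tau(_V_CHECK_RANGE))
            if np.any(taus <= 0):
                raise ValueError("gate time constant must stay positive")


@dataclass(frozen=True)
class CurrentSpec:
    name: str
    conductance_nS: float
    reversal_mV: float | None = None
    reversal_param: str | None = None  # e.g. "e_leak"
    scale: str | None = None  # grid fraction scaling this conductance
    gates: tuple[GateSpec, ...] = ()

    def validate(self) -> None:
        if self.conductance_nS < 0:
            raise ValueError(f"{self.name}: conductance must be >= 0")
        if (self.reversal_mV is None) == (self.reversal_param is None):
            raise ValueError(f"{self.name}: exactly one of reversal_mV/reversal_param")
        for g in self.gates:
            g.validate()


@dataclass(frozen=True)
class SynapseSpec:
    name: str
    kind: str  # graded | spike_mediated
    conductance_nS: float
    reversal_mV: float
    scale: str | None = None
    # spike_mediated
    threshold_mV: float = SPIKE_THRESHOLD_MV
    rise_ms: float = 1.0
    decay_ms: float = 100.0
    # graded
    vhalf_mV: float = -45.0
    k_mV: float = -2.0
    tau_ms: float = 100.0

    def validate(self) -> None:
        if self.kind not in {"graded", "spike_mediated"}:
            raise ValueError(f"{self.name}: unknown synapse kind {self.kind!r}")
        if min(self.rise_ms, self.decay_ms, self.tau_ms) <= 0:
            raise ValueError(f"{self.name}: synapse time constants must be positive")
        if self.conductance_nS < 0:
            raise ValueError(f"{self.name}: conductance must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    name: str
    capacitance_pF: float
    currents: tuple[CurrentSpec, ...]
    synapses: tuple[SynapseSpec, ...]
    init_v_mV: tuple[float, float] = (-50.0, -60.0)

    def validate(self) -> None:
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")
        for c in self.currents:
            c.validate()
        for s in self.synapses:
            s.validate()


@dataclass(frozen=True)
class SimProtocol:
    """Timing contract: settle for ``t_settle`` s, record ``t_record`` s.

    ``t_init`` is the canonical-model pre-run that produces the shared
    initial state; ``dt`` is the output (recording) grid, not the solver
    step — the solver is variable-step with dense output.
    """

    t_init: float = 200.0
    t_settle: float = 100.0
    t_record: float = 100.0
    dt: float = 1e-3
    rtol: float = 1e-6
    atol: float = 1e-8
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if min(self.t_init, self.t_settle, self.t_record) < 0:
            raise ValueError("durations must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _gate_dict(d: dict) -> GateSpec:
    tau = d.get("tau", {}) or {}
    return GateSpec(
        power=int(d.get("power", 1)),
        vhalf_mV=float(d["vhalf_mV"]),
        k_mV=float(d["k_mV"]),
        instantaneous=bool(d.get("instantaneous", False)),
        tau_form=str(tau.get("form", "constant")),
        tau_base_ms=float(tau.get("base_ms", 1.0)),
        tau_amp_ms=float(tau.get("amp_ms", 0.0)),
        tau_vhalf_mV=float(tau.get("vhalf_mV", d["vhalf_mV"])),
        tau_width_mV=float(tau.get("width_mV", 10.0)),
    )


def parse_model_config(doc: dict) -> ModelConfig:
    currents = tuple(
        CurrentSpec(
            name=str(c["name"]),
            conductance_nS=float(c["conductance_nS"]),
            reversal_mV=None if "reversal_param" in c else float(c["reversal_mV"]),
            reversal_param=c.get("reversal_param"),
            scale=c.get("scale"),
            gates=tuple(_gate_dict(g) for g in c.get("gates", [])),
        )
        for c in doc.get("currents", [])
    )
    synapses = tuple(
        SynapseSpec(
            name=str(s["name"]),
            kind=str(s["kind"]),
            conductance_nS=float(s["conductance_nS"]),
            reversal_mV=float(s["reversal_mV"]),
            scale=s.get("scale"),
            threshold_mV=float(s.get("threshold_mV", SPIKE_THRESHOLD_MV)),
            rise_ms=float(s.get("rise_ms", 1.0)),
            decay_ms=float(s.get("decay_ms", 100.0)),
            vhalf_mV=float(s.get("vhalf_mV", -45.0)),
            k_mV=float(s.get("k_mV", -2.0)),
            tau_ms=float(s.get("tau_ms", 100.0)),
        )
        for s in doc.get("synapses", [])
    )
    init_v = doc.get("init_v_mV", [-50.0, -60.0])
    cfg = ModelConfig(
        name=str(doc.get("name", "model")),
        capacitance_pF=float(doc["capacitance_pF"]),
        currents=currents,
        synapses=synapses,
        init_v_mV=(float(init_v[0]), float(init_v[1])),
    )
    cfg.validate()
    return cfg


def load_model_config(path) -> ModelConfig:
    with open(path) as fh:
        return parse_model_config(yaml.safe_load(fh))


def load_surrogate_config() -> ModelConfig:
    """The packaged surrogate model (test vehicle)."""
    text = (resources.files("famscape.data") / "surrogate.yaml").read_text()
    return parse_model_config(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

class _Compiled:
    """Flattened per-instance model: one RHS closure over numpy arrays.

    State layout: ``[cell A block, cell B block, synapse block]`` where a
    cell block is ``V`` followed by its dynamic gates, and the synapse
    block holds one activation per synapse per direction
    (A->B then B->A, in config order).
    """

    def __init__(self, config: ModelConfig, point: ParameterPoint | None):
        self.config = config
        fractions = {}
        e_leak_override = None
        if point is not None:
            fractions = {p: point.get(p) for p in
                         ("x_P", "x_K2", "x_Leak", "x_CaS", "x_h", "x_SynS", "x_SynG")}
            e_leak_override = point.e_leak
        self.g = np.array([
            c.conductance_nS * (fractions.get(c.scale, 1.0) if c.scale else 1.0)
            for c in config.currents
        ])
        if np.any(self.g < 0):
            raise ValueError("negative conductance after scaling")
        self.E = np.array([
            (e_leak_override if (c.reversal_param == "e_leak" and e_leak_override
                                 is not None) else
             (c.reversal_mV if c.reversal_mV is not None else -60.0))
            for c in config.currents
        ])
        self.gsyn = np.array([
            s.conductance_nS * (fractions.get(s.scale, 1.0) if s.scale else 1.0)
            for s in config.synapses
        ])
        self.Esyn = np.array([s.reversal_mV for s in config.synapses])
        # dynamic gates, flattened
        self.dyn: list[tuple[int, GateSpec]] = []
        self.inst: list[tuple[int, GateSpec]] = []
        for ci, cur in enumerate(config.currents):
            for gate in cur.gates:
                (self.inst if gate.instantaneous else self.dyn).append((ci, gate))
        self.n_gates = len(self.dyn)
        self.cell_len = 1 + self.n_gates
        self.n_syn = len(config.synapses)
        self.n_state = 2 * self.cell_len + 2 * self.n_syn

    # -- state construction -------------------------------------------------
    def default_state(self) -> np.ndarray:
        y = np.zeros(self.n_state)
        for cell, v0 in enumerate(self.config.init_v_mV):
            base = cell * self.cell_len
            y[base] = v0
            for gi, (_, gate) in enumerate(self.dyn):
                y[base + 1 + gi] = gate.x_inf(v0)
        return y

    # -- dynamics -----------------------------------------------------------
    def _membrane_current(self, v: float, gates: np.ndarray) -> float:
        prod = np.ones(len(self.g))
        for gi, (ci, gate) in enumerate(self.dyn):
            prod[ci] *= gates[gi] ** gate.power
        for ci, gate in self.inst:
            prod[ci] *= gate.x_inf(v) ** gate.power
        return float(np.sum(self.g * prod * (v - self.E)))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        C = self.config.capacitance_pF
        vs = (y[0], y[self.cell_len])
        syn0 = 2 * self.cell_len
        for cell in range(2):
            base = cell * self.cell_len
            v = y[base]
            gates = y[base + 1: base + 1 + self.n_gates]
            i_total = self._membrane_current(v, gates)
            # synaptic input: activation driven by the *other* cell.
            # direction blocks: A->B uses presyn A and targets cell B.
            for si in range(self.n_syn):
                s = y[syn0 + 2 * si + (0 if cell == 1 else 1)]
                i_total += self.gsyn[si] * s * (v - self.Esyn[si])
            dy[base] = -i_total / C
            for gi, (_, gate) in enumerate(self.dyn):
                dy[base + 1 + gi] = (gate.x_inf(v) - gates[gi]) / gate.tau(v)
        for si, spec in enumerate(self.config.synapses):
            for d, pre in enumerate(vs):  # d=0: A->B, d=1: B->A
                idx = syn0 + 2 * si + d
                s = y[idx]
                if spec.kind == "graded":
                    s_inf = 1.0 / (1.0 + math.exp((pre - spec.vhalf_mV) / spec.k_mV))
                    dy[idx] = (s_inf - s) / spec.tau_ms
                else:
                    drive = 1.0 / (1.0 + math.exp(-(pre - spec.threshold_mV) / 2.0))
                    dy[idx] = drive * (1.0 - s) / spec.rise_ms - s / spec.decay_ms
        return dy

    def integrate(self, y0: np.ndarray, duration_ms: float,
                  protocol: SimProtocol,
                  t_eval_ms: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        if duration_ms == 0:
            return np.array([0.0]), y0[:, None].copy()
        sol = solve_ivp(
            self.rhs, (0.0, duration_ms), y0, method=protocol.method,
            rtol=protocol.rtol, atol=protocol.atol, t_eval=t_eval_ms,
            max_step=duration_ms,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"integration failed: {sol.message}")
        return sol.t, sol.y


_initial_state_cache: dict[tuple, np.ndarray] = {}


def make_initial_state(config: ModelConfig, protocol: SimProtocol) -> np.ndarray:
    """Shared initial state: canonical model integrated for ``t_init`` s.

    Deterministic, cached per (config, t_init) and reused across the grid;
    ``t_init = 0`` returns the documented default state (cell A depolarized
    relative to cell B, gates at steady state, synapses off).
    """
    key = (id(config), config.name, protocol.t_init, protocol.rtol, protocol.atol)
    cached = _initial_state_cache.get(key)
    if cached is not None:
        return cached.copy()
    comp = _Compiled(config, point=None)
    y0 = comp.default_state()
    if protocol.t_init > 0:
        _, y = comp.integrate(y0, protocol.t_init * 1000.0, protocol)
        y0 = y[:, -1]
    _initial_state_cache[key] = y0.copy()
    return y0


def simulate_pair(point: ParameterPoint, config: ModelConfig,
                  protocol: SimProtocol,
                  init_state: np.ndarray | None = None) -> TracePair:
    """Integrate the coupled pair at one grid point; return the record window.

    The instance settles for ``t_settle`` s from the shared initial state,
    then the final ``t_record`` s is recorded on the ``dt`` output grid and
    spike times are extracted at the −20 mV threshold.
    """
    comp = _Compiled(config, point)
    y0 = init_state.copy() if init_state is not None else make_initial_state(config, protocol)
    settle_ms = protocol.t_settle * 1000.0
    record_ms = protocol.t_record * 1000.0
    dt_ms = protocol.dt * 1000.0
    if settle_ms > 0:
        _, y = comp.integrate(y0, settle_ms, protocol)
        y0 = y[:, -1]
    n_out = int(round(record_ms / dt_ms)) + 1
    t_eval = np.linspace(0.0, record_ms, n_out)
    _, y = comp.integrate(y0, record_ms, protocol, t_eval_ms=t_eval)
    t_s = t_eval / 1000.0
    v_A = y[0]
    v_B = y[comp.cell_len]
    spk_A, _ = detect_spikes(t_s, v_A)
    spk_B, _ = detect_spikes(t_s, v_B)
    return TracePair(t=t_s, v_A=v_A, v_B=v_B, spikes_A=spk_A, spikes_B=spk_B)
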