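"""Two-cell half-center oscillator (HCO) model of the cat locomotor CPG.

Two identical neurons coupled by mutual inhibition, each carrying five
intrinsic currents — fast sodium (NaF), slowly inactivating sodium (NaS),
delayed-rectifier potassium (K), slowly inactivating low-voltage-activated
calcium (CaS) and leak — plus the inhibitory synaptic current and an
optional square pulse of excitatory conductance used as the perturbation.

The slow calcium inactivation hCaS (tau = 0.485 s) is the slowest variable
of the system and drives the slow (~1 Hz, locomotor-like) rhythm; the slow
sodium inactivation hNaS (tau = 0.1 s) drives the fast (~10 Hz,
paw-shake-like) rhythm.  Both rhythms coexist at the canonical parameters.

Units: seconds, mV, nS, pA, nF (so pA/nF = mV/s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import _kernels as K

__all__ = [
    "ModelParameters",
    "NeuronState",
    "HCOState",
    "PulseSpec",
    "GATE_IDS",
    "gate_kinetics",
    "membrane_currents",
    "derivatives",
]


@dataclass(frozen=True)
class ModelParameters:
    """Maximal conductances (nS), reversal potentials (mV), capacitance (nF).

    Defaults are the canonical parameter set of the symmetric HCO.
    """

    g_NaF: float = 50.0
    g_NaS: float = 3.83
    g_K: float = 40.0
    g_CaS: float = 12.3
    g_leak: float = 2.96
    g_Syn: float = 5.5
    g_E_max: float = 1.0
    E_Na: float = 65.0
    E_K: float = -70.0
    E_Ca: float = 160.0
    E_leak: float = -54.0
    E_Syn: float = -75.0
    E_E: float = 0.0
    C: float = 0.001

    def __post_init__(self):
        for name in ("g_NaF", "g_NaS", "g_K", "g_CaS", "g_leak", "g_Syn",
                     "g_E_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.C <= 0:
            raise ValueError("capacitance C must be > 0")

    def as_array(self) -> np.ndarray:
        """Parameter vector in the kernel layout."""
        return np.array([self.g_NaF, self.g_NaS, self.g_K, self.g_CaS,
                         self.g_leak, self.g_Syn, self.E_Na, self.E_K,
                         self.E_Ca, self.E_leak, self.E_Syn, self.C])

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def to_file(self, path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(data))
        else:
            path.write_text(json.dumps(data, indent=1))

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class NeuronState:
    """Instantaneous state of one neuron.

    The fast sodium activation is not a state variable — it is the
    instantaneous m_NaF_inf(V).  m_Syn is this neuron's synaptic activation
    as a presynaptic source (it gates the current into the *other* cell).
    """

    V: float
    h_NaF: float
    m_NaS: float
    h_NaS: float
    m_K: float
    m_CaS: float
    h_CaS: float
    m_Syn: float

    GATES = ("h_NaF", "m_NaS", "h_NaS", "m_K", "m_CaS", "h_CaS", "m_Syn")

    def __post_init__(self):
        for g in self.GATES:
            v = getattr(self, g)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gating variable {g}={v} outside [0, 1]")

    @classmethod
    def at_rest(cls, V: float) -> "NeuronState":
        """All gates at their steady-state value for the given voltage."""
        vals = {g: gate_kinetics(g, V)[0] for g in cls.GATES}
        return cls(V=V, **vals)

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h_NaF, self.m_NaS, self.h_NaS,
                         self.m_K, self.m_CaS, self.h_CaS, self.m_Syn])

    @classmethod
    def from_array(cls, a) -> "NeuronState":
        return cls(*[float(v) for v in a])


@dataclass
class HCOState:
    """Joint state of the two-neuron HCO at time t (s)."""

    neuron1: NeuronState
    neuron2: NeuronState
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.neuron1.as_array(),
                               self.neuron2.as_array()])

    @classmethod
    def from_array(cls, a, t: float = 0.0) -> "HCOState":
        a = np.asarray(a, dtype=float)
        if a.shape != (16,):
            raise ValueError("full HCO state has 16 variables")
        return cls(NeuronState.from_array(a[:8]),
                   NeuronState.from_array(a[8:]), t=t)

    def swapped(self) -> "HCOState":
        return HCOState(self.neuron2, self.neuron1, t=self.t)


@dataclass(frozen=True)
class PulseSpec:
    """Square pulse of excitatory conductance applied to both neurons.

    Onset may be given as an absolute time ``t_pul`` (s) or as a phase
    ``p_pul`` in percent of the locomotor cycle (resolved by the protocol
    driver against the attractor's phase-zero reference).
    """

    g_E: float = 1.0
    d_pul: float = 0.950
    t_pul: float | None = None
    p_pul: float | None = None
    E_E: float = 0.0
    targets: tuple = (1, 2)

    def __post_init__(self):
        if self.g_E < 0:
            raise ValueError("pulse conductance g_E must be >= 0")
        if self.d_pul <= 0:
            raise ValueError("pulse duration d_pul must be > 0")
        if self.p_pul is not None and not 0 <= self.p_pul < 100:
            raise ValueError("pulse phase p_pul must lie in [0, 100)")

    def conductance_at(self, t: float) -> float:
        if self.t_pul is None:
            raise ValueError("pulse onset time t_pul is not resolved")
        if self.t_pul <= t <= self.t_pul + self.d_pul:
            return self.g_E
        return 0.0


# ---------------------------------------------------------------------------
# Gate kinetics lookup
# ---------------------------------------------------------------------------

_GATE_TABLE = {
    "h_NaF": (K.inf_hnaf, K.tau_hnaf),
    "m_NaS": (K.inf_mnas, K.TAU_MNAS),
    "h_NaS": (K.inf_hnas, K.TAU_HNAS),
    "m_K": (K.inf_mk, K.tau_mk),
    "m_CaS": (K.inf_mcas, K.tau_mcas),
    "h_CaS": (K.inf_hcas, K.TAU_HCAS),
    "m_Syn": (K.inf_msyn, K.TAU_MSYN),
    "m_NaF_inf": (K.minf_naf, 0.0),
}

GATE_IDS = tuple(_GATE_TABLE)


def gate_kinetics(gate_id: str, V: float) -> tuple[float, float]:
    """Steady state and time constant of a gating variable at voltage V.

    Returns ``(x_inf, tau)`` with tau in seconds; for the instantaneous
    ``m_NaF_inf`` gate tau is returned as 0.
    """
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    try:
        inf_fn, tau = _GATE_TABLE[gate_id]
    except KeyError:
        raise KeyError(f"unknown gate identifier {gate_id!r}; "
                       f"expected one of {GATE_IDS}") from None
    x_inf = inf_fn(V)
    if callable(tau):
        tau = tau(V)
    return float(x_inf), float(tau)


def membrane_currents(state: NeuronState, m_syn_pre: float,
                      params: ModelParameters,
                      g_E_now: float = 0.0) -> dict[str, float]:
    """All membrane currents (pA) of one neuron.

    ``m_syn_pre`` is the synaptic activation of the *other* (presynaptic)
    neuron; ``g_E_now`` the instantaneous pulse conductance.
    """
    V = state.V
    m_naf = K.minf_naf(V)
    return {
        "I_NaF": params.g_NaF * m_naf ** 3 * state.h_NaF * (V - params.E_Na),
        "I_NaS": params.g_NaS * state.m_NaS * state.h_NaS * (V - params.E_Na),
        "I_K": params.g_K * state.m_K ** 4 * (V - params.E_K),
        "I_CaS": params.g_CaS * state.m_CaS ** 3 * state.h_CaS
                 * (V - params.E_Ca),
        "I_leak": params.g_leak * (V - params.E_leak),
        "I_Syn": params.g_Syn * m_syn_pre * (V - params.E_Syn),
        "I_E": g_E_now * (V - params.E_E),
    }


def derivatives(state: HCOState, params: ModelParameters,
                pulse: PulseSpec | None = None) -> np.ndarray:
    """Time derivative of the full 16-variable state (kernel evaluation)."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite value in HCO state")
    gE = pulse.conductance_at(state.t) if pulse is not None else 0.0
    EE = pulse.E_E if pulse is not None else 0.0
    dy = np.empty(16)
    K.rhs_full(y, params.as_array(), gE, EE, dy)
    return dy
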