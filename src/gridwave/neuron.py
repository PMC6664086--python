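"""Event-driven leaky integrate-and-fire neuron with spike-frequency adaptation.

Between synaptic events the membrane potential ``V`` and the fatigue
variable ``c`` obey the linear system

    dV/dt = -(V - E)/tau_m - (g_c/C_m) * c
    dc/dt = -c/tau_c

which has a closed-form solution, so the state can be advanced exactly from
one event to the next (no time stepping).  Synaptic events add an
instantaneous jump ``J`` to ``V``; crossing the threshold ``V_theta`` emits a
spike, resets ``V`` to ``V_r`` for an absolute refractory period ``tau_arp``
and increments ``c`` by ``alpha_c``.  Inhibitory neurons carry no fatigue
dynamics.  Because the drift between events is always toward (or below) the
resting potential ``E < V_theta``, threshold crossings can only happen at
events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rng import PURPOSE_EXTERNAL, normal_draw, poisson_draw, stream_key, uniform01

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SynapticEvent",
    "evolve_state",
    "apply_event",
    "draw_external_events",
    "relax_closed_form",
]


class TemporalOrderError(ValueError):
    """An update or event was requested earlier than the state's clock."""


@dataclass(frozen=True)
class NeuronParams:
    """LIF + SFA constants.  Potentials in mV, times in ms.

    ``g_c`` is the fatigue-to-current coupling; only the ratio ``g_c / C_m``
    (mV/ms per unit of fatigue) enters the dynamics.  For inhibitory neurons
    the fatigue equation and its current are absent.
    """

    tau_m: float = 20.0
    C_m: float = 1.0
    E: float = 0.0
    V_theta: float = 20.0
    V_r: float = 15.0
    tau_arp: float = 2.0
    g_c: float = 0.0
    alpha_c: float = 1.0
    tau_c: float = 150.0
    inhibitory: bool = False

    def __post_init__(self):
        if self.tau_m <= 0 or self.tau_c <= 0:
            raise ValueError("tau_m and tau_c must be positive")
        if self.tau_arp < 0:
            raise ValueError("tau_arp must be >= 0")
        if not (self.E < self.V_theta and self.V_r < self.V_theta):
            raise ValueError("need E < V_theta and V_r < V_theta")

    @property
    def adapt_coupling(self) -> float:
        """g_c / C_m, zero for inhibitory neurons."""
        return 0.0 if self.inhibitory else self.g_c / self.C_m

    def to_dict(self) -> dict:
        return {
            "tau_m": self.tau_m, "C_m": self.C_m, "E": self.E,
            "V_theta": self.V_theta, "V_r": self.V_r, "tau_arp": self.tau_arp,
            "g_c": self.g_c, "alpha_c": self.alpha_c, "tau_c": self.tau_c,
            "inhibitory": self.inhibitory,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


@dataclass
class NeuronState:
    V: float
    c: float = 0.0
    t_last: float = 0.0
    refractory_until: float = -math.inf


@dataclass(frozen=True, order=True)
class SynapticEvent:
    arrival_time: float
    amplitude: float = field(compare=False)
    origin: str = field(default="recurrent", compare=False)  # recurrent | external
    source: int = field(default=-1, compare=False)


def relax_closed_form(V0: float, c0: float, dt: float, E: float,
                      tau_m: float, tau_c: float, a: float) -> tuple[float, float]:
    """Exact relaxation of (V, c) over ``dt`` ms with no input.

    ``a = g_c / C_m``.  Handles ``tau_c == tau_m`` as the confluent limit
    ``V = E + (V0-E) e^{-dt/tau} - a c0 dt e^{-dt/tau}``.
    """
    if dt == 0.0:
        return V0, c0
    ev_m = math.exp(-dt / tau_m)
    c1 = c0 * math.exp(-dt / tau_c)
    if a == 0.0 or c0 == 0.0:
        return E + (V0 - E) * ev_m, c1
    if abs(tau_c - tau_m) < 1e-9 * tau_m:
        V1 = E + (V0 - E) * ev_m - a * c0 * dt * ev_m
        return V1, c1
    k = a * tau_m * tau_c / (tau_c - tau_m)
    V1 = E + (V0 - E + k * c0) * ev_m - k * c0 * math.exp(-dt / tau_c)
    return V1, c1


def evolve_state(state: NeuronState, params: NeuronParams, to_time: float) -> NeuronState:
    """Advance the state to ``to_time`` by the exact inter-event solution."""
    if to_time < state.t_last:
        raise TemporalOrderError(
            f"evolve to t={to_time} before state clock t={state.t_last}"
        )
    V, c = relax_closed_form(
        state.V, state.c, to_time - state.t_last,
        params.E, params.tau_m, params.tau_c, params.adapt_coupling,
    )
    return NeuronState(V=V, c=c, t_last=to_time, refractory_until=state.refractory_until)


def apply_event(
    state: NeuronState, params: NeuronParams, event: SynapticEvent
) -> tuple[NeuronState, float | None]:
    """Deliver one synaptic event; returns (new state, spike time or None).

    The state is first relaxed to the arrival time.  Events arriving during
    the refractory period are discarded (the membrane keeps relaxing from the
    reset value but receives no jump).  A threshold crossing fires a spike at
    the event time, resets ``V`` and increments the fatigue of excitatory
    neurons.
    """
    if event.arrival_time < state.t_last:
        raise TemporalOrderError("event arrives before the state clock")
    st = evolve_state(state, params, event.arrival_time)
    if event.arrival_time < st.refractory_until:
        return st, None
    st.V += event.amplitude
    if st.V >= params.V_theta:
        t_sp = event.arrival_time
        st.V = params.V_r
        st.refractory_until = t_sp + params.tau_arp
        if not params.inhibitory:
            st.c += params.alpha_c
        return st, t_sp
    return st, None


def draw_external_events(
    nu_ext_hz: float,
    window: tuple[float, float],
    J_ext: float,
    delta_J_ext: float,
    seed: int,
    neuron_id: int = 0,
    comm_step_ms: float = 1.0,
) -> list[SynapticEvent]:
    """External Poisson drive for one neuron over ``window = [t0, t1)`` ms.

    Event counts are Poisson(nu_ext * (t1 - t0)), arrival times uniform, and
    amplitudes Gaussian(J_ext, delta_J_ext) (not sign-clipped).  Draws come
    from the counter-based stream keyed by (seed, neuron, communication step),
    so the events in any window are independent of how, or in how many pieces,
    the window is traversed — the same events the simulation engine injects.
    """
    if nu_ext_hz < 0:
        raise ValueError("nu_ext_hz must be >= 0")
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    if nu_ext_hz == 0:
        return []
    lam = nu_ext_hz * 1e-3 * comm_step_ms  # expected events per step
    first = int(math.floor(t0 / comm_step_ms))
    last = int(math.ceil(t1 / comm_step_ms))
    events: list[SynapticEvent] = []
    for step in range(first, last):
        key = np.uint64(stream_key(
            np.uint64(seed), np.uint64(neuron_id), np.uint64(step),
            np.uint64(PURPOSE_EXTERNAL),
        ))
        k, ctr = poisson_draw(lam, key, np.uint64(0))
        ctr = np.uint64(ctr)
        base = step * comm_step_ms
        for _ in range(k):
            u = uniform01(key, ctr)
            ctr += np.uint64(1)
            z, ctr = normal_draw(key, ctr)
            ctr = np.uint64(ctr)
            t = base + comm_step_ms * u
            if t0 <= t < t1:
                events.append(
                    SynapticEvent(
                        arrival_time=t,
                        amplitude=J_ext + delta_J_ext * z,
                        origin="external",
                    )
                )
    events.sort(key=lambda e: e.arrival_time)
    return events
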