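"""Time-domain simulation of the axon-bundle circuit.

The bundle is one central axon surrounded by ``N`` neighbours (default six).
Each axon is a chain of nodes of Ranvier joined by passive internodal
resistances ``R_i``; each node is a capacitor in parallel with four
threshold-gated ionic branches.  Nodes of neighbouring axons exchange an
ephaptic current ``alpha * (V_j - V_i) / R_o`` through the extracellular
resistance, evaluated at the nearest-node pairing induced by the alignment
offset.

The state equation at node ``i`` (voltages in mV, currents in uA) is

    C_i dV_i/dt = I_axial,i + I_ephaptic,i - I_ion,i + I_stim,i

with ``I_ion,i = sum over open branches x of g_x (1 + gamma) (V_i - e_x)``.
With the switch flags frozen over a step the system is linear, so the
stepper is backward Euler on the linear circuit with switch flags updated
from threshold crossings detected within the step (crossing times by linear
interpolation, so velocity resolution is finer than ``dt``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateMeasurementError,
    DomainError,
    NumericalInstabilityError,
    PropagationFailureError,
)
from .model_core import (
    AxonState,
    ModelConfig,
    apply_block,
    node_offset,
    scale_capacitance,
)

__all__ = [
    "StimulusProtocol",
    "BundleModel",
    "SimState",
    "PropagationResult",
    "ionic_current",
    "ephaptic_current",
    "build_bundle",
    "step",
    "simulate",
    "conduction_velocity",
]

_PF_TO_UF = 1e-6


# ---------------------------------------------------------------------------
# elementary current laws (also serve as the documented reference forms)
# ---------------------------------------------------------------------------

def ionic_current(v: float, params, gamma: float,
                  switches: Sequence[bool]) -> float:
    """Total ionic current (uA) at a node, summed over the open branches.

    ``switches`` holds the open/closed flag per branch in the order
    (na, kf, ks, leak).  Each open branch contributes the Ohmic term
    ``g_x * (1 + gamma) * (v - e_x)``; closed branches contribute nothing.
    Positive values are outward (repolarizing) currents.
    """
    if not 0.0 <= gamma < 1.0:
        raise DomainError(f"gamma must be in [0, 1), got {gamma}")
    total = 0.0
    for g, e, open_ in zip(params.conductances(), params.nernst(), switches):
        if open_:
            total += g * (1.0 + gamma) * (v - e)
    return total


def ephaptic_current(v_self: float, neighbor_voltages: Sequence[float],
                     alpha: float, r_o: float,
                     n_neighbors: int | None = None) -> float:
    """Ephaptic current (uA) into a node from its neighbour nodes.

    ``alpha * sum_j (v_j - v_self) / r_o``; zero when decoupled
    (``alpha = 0``) or when all voltages agree.  If ``n_neighbors`` is
    given, the voltage list must have exactly that length.
    """
    if alpha < 0:
        raise DomainError(f"alpha must be >= 0, got {alpha}")
    if r_o <= 0:
        raise DomainError(f"r_o must be > 0, got {r_o}")
    voltages = list(neighbor_voltages)
    if n_neighbors is not None and len(voltages) != n_neighbors:
        raise DomainError(
            f"expected {n_neighbors} neighbour voltages, "
            f"got {len(voltages)}")
    return alpha * sum(v - v_self for v in voltages) / r_o


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Current-pulse stimulation.

    amplitude in uA, duration in ms (0.1 ms default), repetition frequency
    in Hz (1 Hz default — one pulse per simulated window at typical
    ``t_end``).  By default every axon in the bundle is stimulated at the
    same node, emulating a whole-nerve shock.
    """

    amplitude: float = 0.05
    duration: float = 0.1
    frequency: float = 1.0
    node: int = 0
    all_axons: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError("stimulus duration must be > 0")
        if self.amplitude == 0:
            raise DomainError("stimulus amplitude must be non-zero")
        if self.frequency <= 0:
            raise DomainError("stimulus frequency must be > 0")

    def active(self, t: float) -> bool:
        period_ms = 1000.0 / self.frequency
        return (t % period_ms) < self.duration


@dataclass(frozen=True)
class BundleModel:
    """Assembled bundle: geometry, per-axon states and cached circuit arrays.

    ``n_axons = 1 + layout.n_neighbors``; axon 0 is the central axon,
    neighbours are staggered by ``node_offset(alignment, L)``.  The cached
    arrays hold the per-axon effective branch conductances (demyelination
    and block applied), effective nodal capacitances in uF, and the constant
    passive coupling matrix (axial + ephaptic).
    """

    config: ModelConfig
    states: tuple[AxonState, ...]
    positions: np.ndarray          # (n_axons, n_nodes) node positions, mm
    g_eff: np.ndarray              # (n_axons, 4) effective conductances, mS
    e_rev: np.ndarray              # (4,) Nernst potentials, mV
    thresholds: np.ndarray         # (4,) branch thresholds, mV
    static_open: np.ndarray        # (4,) bool: threshold <= resting
    durations: np.ndarray          # (4,) open durations, ms
    c_eff: np.ndarray              # (n_axons,) effective capacitance, uF
    passive: np.ndarray            # (n, n) axial + ephaptic coupling, mS

    @property
    def n_axons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[1]

    @property
    def n_total(self) -> int:
        return self.positions.size

    def flat(self, axon: int, node: int) -> int:
        return axon * self.n_nodes + node


def build_bundle(config: ModelConfig,
                 per_axon_states: Sequence[AxonState] | None = None
                 ) -> BundleModel:
    """Assemble a :class:`BundleModel` from a validated configuration.

    All axons share the geometry and channel parameters; ``config.state``
    (gamma, block fraction) applies to every axon unless ``per_axon_states``
    overrides it with one state per axon.
    """
    geo, lay, ch = config.geometry, config.layout, config.channels
    n_axons = 1 + lay.n_neighbors
    k = geo.n_nodes
    if per_axon_states is None:
        states = tuple(config.state for _ in range(n_axons))
    else:
        states = tuple(per_axon_states)
        if len(states) != n_axons:
            raise DomainError(
                f"need {n_axons} axon states, got {len(states)}")

    offset = node_offset(lay.alignment, geo.internodal_length)
    base = np.arange(k) * geo.internodal_length
    positions = np.empty((n_axons, k))
    positions[0] = base
    positions[1:] = base + offset

    g_eff = np.empty((n_axons, 4))
    c_eff = np.empty(n_axons)
    for a, st in enumerate(states):
        blocked = apply_block(ch, st.block_fraction)
        # direct (1+gamma) scaling: a fully blocked branch (g = 0) is legal
        # here even though scale_conductance rejects g <= 0
        g_eff[a] = np.array(blocked.conductances()) * (1.0 + st.gamma)
        c_eff[a] = scale_capacitance(
            geo.nodal_capacitance, st.gamma,
            config.capacitance_gamma_exponent) * _PF_TO_UF

    thresholds = np.array(ch.thresholds())
    e_rev = np.array(ch.nernst())
    static_open = thresholds <= config.resting_potential
    durations = np.array(config.gating.durations())

    passive = _passive_matrix(positions, geo.axial_resistance,
                              lay.ephaptic_coupling,
                              lay.external_resistance, offset,
                              geo.internodal_length)

    return BundleModel(config=config, states=states, positions=positions,
                       g_eff=g_eff, e_rev=e_rev, thresholds=thresholds,
                       static_open=static_open, durations=durations,
                       c_eff=c_eff, passive=passive)


def _passive_matrix(positions: np.ndarray, r_i: float, alpha: float,
                    r_o: float, offset: float, length: float) -> np.ndarray:
    """Constant coupling matrix: I_passive = passive @ V_flat (uA).

    Axial block: graph Laplacian of each axon chain with edge conductance
    ``1/R_i``.  Ephaptic block: star topology — each node of the central
    axon couples to the nearest node of every neighbour axon and vice versa,
    with conductance ``alpha / R_o`` per directed pair.
    """
    n_axons, k = positions.shape
    n = n_axons * k
    mat = np.zeros((n, n))
    g_ax = 1.0 / r_i
    for a in range(n_axons):
        for i in range(k - 1):
            u, v = a * k + i, a * k + i + 1
            mat[u, u] -= g_ax
            mat[u, v] += g_ax
            mat[v, v] -= g_ax
            mat[v, u] += g_ax
    if alpha > 0:
        g_ep = alpha / r_o
        for b in range(1, n_axons):
            # central node i <- nearest neighbour-axon node
            for i in range(k):
                j = int(np.clip(round((positions[0, i] - offset) / length),
                                0, k - 1))
                u, v = i, b * k + j
                mat[u, u] -= g_ep
                mat[u, v] += g_ep
            # neighbour node j <- nearest central node
            for j in range(k):
                i = int(np.clip(round((positions[b, j]) / length), 0, k - 1))
                u, v = b * k + j, i
                mat[u, u] -= g_ep
                mat[u, v] += g_ep
    return mat


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Mutable integration state: voltages, switch timers, crossing record."""

    t: float
    v: np.ndarray                 # (n_axons, n_nodes) mV
    open_until: np.ndarray        # (n_axons, n_nodes, 4) ms
    refract_until: np.ndarray     # (n_axons, n_nodes, 4) ms
    crossing_times: np.ndarray    # (n_axons, n_nodes) first vth_na crossing

    @classmethod
    def initial(cls, model: BundleModel) -> "SimState":
        shape = (model.n_axons, model.n_nodes)
        return cls(
            t=0.0,
            v=np.full(shape, model.config.resting_potential),
            open_until=np.full(shape + (4,), -np.inf),
            refract_until=np.full(shape + (4,), -np.inf),
            crossing_times=np.full(shape, np.nan),
        )

    def open_mask(self, model: BundleModel) -> np.ndarray:
        """(n_axons, n_nodes, 4) bool: branch open at the current time."""
        return model.static_open[None, None, :] | (self.t < self.open_until)


def stimulus_vector(model: BundleModel, protocol: StimulusProtocol,
                    t: float) -> np.ndarray:
    """(n_axons, n_nodes) injected current (uA) at time ``t``."""
    stim = np.zeros((model.n_axons, model.n_nodes))
    if protocol.active(t):
        if not 0 <= protocol.node < model.n_nodes:
            raise DomainError(
                f"stimulated node {protocol.node} outside "
                f"[0, {model.n_nodes - 1}]")
        if protocol.all_axons:
            stim[:, protocol.node] = protocol.amplitude
        else:
            stim[0, protocol.node] = protocol.amplitude
    return stim


def nodal_currents(model: BundleModel, v: np.ndarray, open_mask: np.ndarray,
                   stim: np.ndarray) -> np.ndarray:
    """Net current (uA) into every node at voltages ``v``.

    Axial + ephaptic (via the cached passive matrix) minus ionic plus
    stimulus — the right-hand side of the state equation, exposed so the
    stepper's Kirchhoff balance can be checked independently.
    """
    passive = (model.passive @ v.reshape(-1)).reshape(v.shape)
    g_open = model.g_eff[:, None, :] * open_mask          # (M, K, 4)
    ionic = (g_open * (v[:, :, None] - model.e_rev)).sum(axis=2)
    return passive - ionic + stim


def linear_step(model: BundleModel, v: np.ndarray, open_mask: np.ndarray,
                dt: float, stim: np.ndarray) -> np.ndarray:
    """One backward-Euler solve of the circuit with frozen switch flags.

    Returns the voltages ``v_new`` satisfying the Kirchhoff balance
    ``C (v_new - v)/dt = nodal_currents(model, v_new, open_mask, stim)``
    exactly (to linear-solver precision).
    """
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    g_open = model.g_eff[:, None, :] * open_mask          # (M, K, 4)
    g_diag = g_open.sum(axis=2).reshape(-1)               # mS
    drive = (g_open * model.e_rev).sum(axis=2).reshape(-1)  # uA
    c_over_dt = np.repeat(model.c_eff, model.n_nodes) / dt  # uF/ms = mS

    mat = -model.passive.copy()
    idx = np.arange(model.n_total)
    mat[idx, idx] += c_over_dt + g_diag
    rhs = c_over_dt * v.reshape(-1) + drive + stim.reshape(-1)
    v_new = np.linalg.solve(mat, rhs).reshape(v.shape)
    if not np.all(np.isfinite(v_new)):
        raise NumericalInstabilityError(
            f"non-finite voltage after implicit solve with dt={dt} ms")
    return v_new


def _next_event_cap(model: BundleModel, state: SimState,
                    protocol: StimulusProtocol | None, h: float) -> float:
    """Largest sub-step <= h that ends no later than the next scheduled
    switch closing or stimulus edge, so both stay exact in time."""
    t = state.t
    later = state.open_until[state.open_until > t + 1e-12]
    if later.size:
        h = min(h, float(later.min()) - t)
    if protocol is not None:
        period = 1000.0 / protocol.frequency
        tau = t % period
        edge = (protocol.duration - tau) if tau < protocol.duration \
            else (period - tau)
        if edge > 1e-12:
            h = min(h, edge)
    return h


def step(model: BundleModel, state: SimState, dt: float,
         protocol: StimulusProtocol | None = None) -> SimState:
    """Advance the state by ``dt`` (ms), resolving switch events exactly.

    The switched-linear circuit is integrated by backward Euler with the
    switch flags frozen over each sub-step (:func:`linear_step`).  The step
    is sub-divided at every event: scheduled branch closings and stimulus
    edges are known in advance and cap the sub-step; upward threshold
    crossings are located by linear interpolation inside a trial sub-step,
    which is then re-solved up to the earliest crossing before the branch
    opens.  Event times are therefore resolved far below ``dt``, and the
    first sodium-threshold crossing per node is recorded for velocity
    measurement.
    """
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    remaining = dt
    guard = 0
    while remaining > 1e-12:
        guard += 1
        if guard > 200:
            raise NumericalInstabilityError(
                f"event cascade did not terminate within one step "
                f"(t={state.t:.6f} ms, dt={dt} ms)")
        h = _next_event_cap(model, state, protocol, remaining)
        open_mask = state.open_mask(model)
        stim = (stimulus_vector(model, protocol, state.t)
                if protocol is not None
                else np.zeros((model.n_axons, model.n_nodes)))
        v_old = state.v
        v_new = linear_step(model, v_old, open_mask, h, stim)

        # locate upward crossings of any gated branch within the trial step
        events: list[tuple[float, int]] = []   # (fraction, branch)
        masks: dict[int, np.ndarray] = {}
        for x in range(4):
            if model.static_open[x]:
                continue
            vth = model.thresholds[x]
            crossed = ((v_old < vth) & (v_new >= vth)
                       & ~open_mask[:, :, x]
                       & (state.refract_until[:, :, x] <= state.t))
            if np.any(crossed):
                frac = np.full(v_old.shape, np.inf)
                frac[crossed] = ((vth - v_old[crossed])
                                 / (v_new[crossed] - v_old[crossed]))
                events.append((float(frac.min()), x))
                masks[x] = frac
        if events:
            frac_min = min(f for f, _ in events)
            if frac_min < 1.0 - 1e-9:
                h_sub = max(frac_min, 1e-9) * h
                v_new = linear_step(model, v_old, open_mask, h_sub, stim)
                h = h_sub
                frac_cut = frac_min + 1e-9
            else:
                frac_cut = 1.0 + 1e-9
            t0 = state.t
            for _, x in events:
                frac = masks[x]
                fire = frac <= frac_cut
                if np.any(fire):
                    t_cross = t0 + h  # sub-step ends at the crossing
                    state.open_until[:, :, x][fire] = (
                        t_cross + model.durations[x])
                    state.refract_until[:, :, x][fire] = (
                        t_cross + model.durations[x]
                        + model.config.gating.refractory)

        # record the first sodium-threshold crossing per node
        vth_na = model.thresholds[0]
        first = (np.isnan(state.crossing_times)
                 & (v_old < vth_na) & (v_new >= vth_na))
        if np.any(first):
            frac = (vth_na - v_old[first]) / (v_new[first] - v_old[first])
            state.crossing_times[first] = state.t + frac * h

        state.v = v_new
        state.t += h
        remaining -= h
    return state


# ---------------------------------------------------------------------------
# simulation driver and velocity measurement
# ---------------------------------------------------------------------------

@dataclass
class PropagationResult:
    """Output of :func:`simulate`.

    ``traces`` is (n_samples, n_axons, n_nodes) in mV at times ``times``
    (ms); ``crossing_times`` the first sodium-threshold crossing per node
    (NaN if never crossed); ``velocities`` the per-axon two-point conduction
    velocity over the default measurement window (NaN where degenerate).
    """

    times: np.ndarray
    traces: np.ndarray
    crossing_times: np.ndarray
    velocities: np.ndarray
    positions: np.ndarray
    stimulated_node: int
    dt: float

    @property
    def n_axons(self) -> int:
        return self.crossing_times.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.crossing_times.shape[1]

    def default_window(self) -> tuple[int, int]:
        """Measurement window excluding the stimulated and terminal nodes."""
        first = min(self.stimulated_node + 2, self.n_nodes - 2)
        last = self.n_nodes - 2
        return first, last


def simulate(model: BundleModel, protocol: StimulusProtocol | None = None,
             t_end: float = 6.0, dt: float = 0.005,
             record_every: int = 1, seed: int | None = None,
             raise_on_failure: bool = True) -> PropagationResult:
    """Run the bundle simulation and measure conduction velocities.

    Deterministic given (model, protocol, dt); ``seed`` is accepted for
    interface uniformity with the stochastic generators but unused — the
    circuit has no noise sources.  Raises
    :class:`~demyelin.exceptions.PropagationFailureError` if the wave on the
    central axon never reaches the distal end of the measurement window
    (expected at extreme gamma or block), unless ``raise_on_failure`` is
    false, in which case the failed axon's velocity is NaN.
    """
    del seed  # deterministic dynamics
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    protocol = protocol or StimulusProtocol()
    state = SimState.initial(model)
    n_steps = int(round(t_end / dt))
    times = [0.0]
    traces = [state.v.copy()]
    for i in range(n_steps):
        step(model, state, dt, protocol)
        if (i + 1) % record_every == 0:
            times.append(state.t)
            traces.append(state.v.copy())

    result = PropagationResult(
        times=np.asarray(times), traces=np.asarray(traces),
        crossing_times=state.crossing_times.copy(),
        velocities=np.full(model.n_axons, np.nan),
        positions=model.positions.copy(),
        stimulated_node=protocol.node, dt=dt)

    first, last = result.default_window()
    for a in range(model.n_axons):
        try:
            result.velocities[a] = conduction_velocity(result, first, last,
                                                       axon=a)
        except (PropagationFailureError, DegenerateMeasurementError):
            if a == 0 and raise_on_failure:
                raise
    return result


def conduction_velocity(result: PropagationResult,
                        first_node: int | None = None,
                        last_node: int | None = None, axon: int = 0,
                        method: str = "two-point") -> float:
    """Conduction velocity (m/s) from nodal threshold-crossing times.

    The default window excludes the stimulated node and the terminal node
    (edge effects).  ``method='two-point'`` divides the node-position
    difference by the crossing-time difference — the circuit analogue of
    electrode distance over peak latency; ``method='regression'`` returns
    the least-squares slope of position versus crossing time over all
    window nodes.  Positions in mm and times in ms make the result m/s.
    """
    d_first, d_last = result.default_window()
    first = d_first if first_node is None else first_node
    last = d_last if last_node is None else last_node
    if not 0 <= first < last <= result.n_nodes - 1:
        raise DomainError(
            f"invalid window [{first}, {last}] for {result.n_nodes} nodes")
    ct = result.crossing_times[axon]
    pos = result.positions[axon]
    if np.isnan(ct[first]) or np.isnan(ct[last]):
        missing = first if np.isnan(ct[first]) else last
        raise PropagationFailureError(
            f"axon {axon}: wave never crossed threshold at node {missing}")
    if method == "two-point":
        dt_cross = ct[last] - ct[first]
        if dt_cross <= 0:
            raise DegenerateMeasurementError(
                f"axon {axon}: non-positive crossing-time difference "
                f"({dt_cross:.6f} ms) between nodes {first} and {last}")
        return float((pos[last] - pos[first]) / dt_cross)
    if method == "regression":
        window = slice(first, last + 1)
        t_w, p_w = ct[window], pos[window]
        if np.any(np.isnan(t_w)):
            raise PropagationFailureError(
                f"axon {axon}: missing crossings inside window "
                f"[{first}, {last}]")
        if np.ptp(t_w) <= 0:
            raise DegenerateMeasurementError(
                f"axon {axon}: all crossing times equal in window")
        slope = np.polyfit(t_w, p_w, 1)[0]
        return float(slope)
    raise ValueError(f"unknown method {method!r}")


def single_axon_config(config: ModelConfig) -> ModelConfig:
    """A copy of ``config`` with no neighbours (decoupled single axon)."""
    layout = dataclasses.replace(config.layout, n_neighbors=0)
    return config.replace(layout=layout)
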