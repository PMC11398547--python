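"""Eligibility-driven Gillespie simulation over mode excitations.

The simulator tracks only mode excitation flags plus a *state constructor* --
the set of creation operators that rebuilds the current microstate from the
vacuum.  A rule instance is eligible iff every factor is eligible (create and
absence need an unexcited mode, annihilate and presence an excited one).
Two eligibility strategies are provided: a full rescan of every instance per
step (the reference) and an incremental index that re-evaluates only the
instances touching flipped modes; both consume the random stream identically
and produce bitwise-identical trajectories.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .fock import CompiledModel, Microstate, Mode, compile_model
from .model import ModelSpec, render_model

__all__ = [
    "SimulationState",
    "TrajectoryEvent",
    "Trajectory",
    "initialize",
    "eligible_rules",
    "gillespie_step",
    "apply_and_record",
    "run",
]

SNAPSHOT_INTERVAL = 1000  # full constructor snapshot every this many events


@dataclass(frozen=True)
class TrajectoryEvent:
    t: float
    instance: int  # index into CompiledModel.instances
    added: Tuple[int, ...]  # bit positions newly excited
    removed: Tuple[int, ...]  # bit positions newly cleared


@dataclass
class Trajectory:
    compiled: CompiledModel
    init_mask: int
    events: List[TrajectoryEvent] = dc_field(default_factory=list)
    snapshots: List[Tuple[int, int]] = dc_field(default_factory=list)  # (event idx, mask)
    metadata: Dict = dc_field(default_factory=dict)
    absorbed: bool = False
    t_end: float = 0.0

    def mask_at(self, t: float) -> int:
        """State bitmask immediately after the last event with time <= t."""
        mask = self.init_mask
        for ev in self.events:
            if ev.t > t:
                break
            for b in ev.added:
                mask |= 1 << b
            for b in ev.removed:
                mask &= ~(1 << b)
        return mask

    def masks_at(self, times: Sequence[float]) -> List[int]:
        """Piecewise-constant sampling at an ascending list of times."""
        out = []
        mask = self.init_mask
        i = 0
        events = self.events
        prev = -math.inf
        for t in times:
            if t < prev:
                raise ValueError("times must be ascending")
            prev = t
            while i < len(events) and events[i].t <= t:
                for b in events[i].added:
                    mask |= 1 << b
                for b in events[i].removed:
                    mask &= ~(1 << b)
                i += 1
            out.append(mask)
        return out

    def replay_masks(self) -> List[int]:
        """Full sequence of post-event bitmasks (for snapshot verification)."""
        mask = self.init_mask
        out = []
        for ev in self.events:
            for b in ev.added:
                mask |= 1 << b
            for b in ev.removed:
                mask &= ~(1 << b)
            out.append(mask)
        return out


class SimulationState:
    """Mutable simulation state: excitation mask, constructor, clock, RNG."""

    def __init__(self, compiled: CompiledModel, seed: int = 0, mode: str = "indexed"):
        if mode not in ("naive", "indexed"):
            raise ValueError("mode must be 'naive' or 'indexed'")
        self.compiled = compiled
        self.mode = mode
        self.mask = compiled.init_mask()
        self.constructor: set[Mode] = set(compiled.state_of(self.mask))
        self.t = 0.0
        self.seed = seed
        self.rng = np.random.Generator(np.random.Philox(seed))
        n = len(compiled.instances)
        self._eligible = np.zeros(n, dtype=bool)
        # mode-bit -> instance ids touching that bit (the O.rules index);
        # cached on the compiled model since it is static
        touching = getattr(compiled, "_touching_index", None)
        if touching is None:
            touching = {}
            for k in range(n):
                bits = compiled._need_set_py[k] | compiled._need_clear_py[k]
                while bits:
                    low = bits & -bits
                    touching.setdefault(low.bit_length() - 1, []).append(k)
                    bits ^= low
            compiled._touching_index = touching  # type: ignore[attr-defined]
        self._touching: Dict[int, List[int]] = touching
        self._rescan_all()

    def _rescan_all(self) -> None:
        cm = self.compiled
        for k in range(len(cm.instances)):
            self._eligible[k] = cm.eligible_mask(self.mask, k)

    def _rescan_dirty(self, flipped_bits: Sequence[int]) -> None:
        cm = self.compiled
        seen = set()
        for b in flipped_bits:
            for k in self._touching.get(b, ()):
                if k not in seen:
                    seen.add(k)
                    self._eligible[k] = cm.eligible_mask(self.mask, k)

    @property
    def microstate(self) -> Microstate:
        return self.compiled.state_of(self.mask)

    def check_coherence(self) -> None:
        """Assert the constructor rebuilds exactly the excited-mode set."""
        rebuilt = self.compiled.mask_of(frozenset(self.constructor))
        if rebuilt != self.mask:
            raise RuntimeError("constructor/excitation-flag mismatch")


def initialize(
    model: Union[ModelSpec, CompiledModel], seed: int = 0, mode: str = "indexed"
) -> SimulationState:
    """Build the static indices and the initial simulation state.

    Accepts a precompiled model to amortize instance construction across runs.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    return SimulationState(cm, seed=seed, mode=mode)


def eligible_rules(state: SimulationState) -> List[int]:
    """Indices of all eligible rule instances (the set R*)."""
    if state.mode == "naive":
        state._rescan_all()
    return [int(k) for k in np.nonzero(state._eligible)[0]]


def gillespie_step(
    eligible: Sequence[Tuple[int, float]], rng: np.random.Generator
) -> Tuple[float, int]:
    """Sample (dt, chosen instance) from a list of (instance id, rate) pairs.

    dt is exponential with the total rate; the instance is chosen with
    probability proportional to its rate by cumulative search in list order.
    """
    rates = np.array([r for _, r in eligible], dtype=float)
    total = rates.sum()
    if total <= 0.0 or not len(rates):
        raise ValueError("no eligible rules")
    u = rng.random()
    dt = -math.log1p(-u) / total
    v = rng.random() * total
    idx = int(np.searchsorted(np.cumsum(rates), v, side="right"))
    idx = min(idx, len(rates) - 1)
    return dt, eligible[idx][0]


def apply_and_record(
    state: SimulationState, chosen: int, traj: Trajectory
) -> SimulationState:
    """Apply one rule instance: update constructor, flip modes, append record."""
    cm = state.compiled
    if not cm.eligible_mask(state.mask, chosen):
        raise RuntimeError(f"instance {chosen} applied while ineligible")
    inst = cm.instances[chosen]
    added: List[int] = []
    removed: List[int] = []
    for op, mode in inst.modes_touched:
        if op == "create":
            state.constructor.add(mode)
            added.append(cm.bit[mode])
        elif op == "annihilate":
            state.constructor.discard(mode)
            removed.append(cm.bit[mode])
    state.mask = cm.apply_mask(state.mask, chosen)
    flipped = added + removed
    if state.mode == "indexed":
        state._rescan_dirty(flipped)
    traj.events.append(
        TrajectoryEvent(state.t, chosen, tuple(added), tuple(removed))
    )
    if len(traj.events) % SNAPSHOT_INTERVAL == 0:
        traj.snapshots.append((len(traj.events) - 1, state.mask))
    return state


def _model_hash(model: ModelSpec) -> str:
    return hashlib.sha256(render_model(model).encode()).hexdigest()[:16]


def run(
    model: Union[ModelSpec, CompiledModel],
    tmax: float,
    seed: int = 0,
    mode: str = "indexed",
    debug_coherence: bool = False,
) -> Trajectory:
    """Simulate until tmax (or an absorbing state); bitwise-reproducible."""
    if tmax <= 0:
        raise ValueError("tmax must be positive")
    state = initialize(model, seed=seed, mode=mode)
    spec = state.compiled.model
    traj = Trajectory(
        compiled=state.compiled,
        init_mask=state.mask,
        metadata={
            "model_hash": _model_hash(spec),
            "seed": seed,
            "N": spec.N,
            "mode": mode,
        },
    )
    rates = state.compiled.rates
    rng = state.rng
    while True:
        if state.mode == "naive":
            state._rescan_all()
        w = rates * state._eligible
        total = float(w.sum())
        if total <= 0.0:
            traj.absorbed = True
            break
        u = rng.random()
        dt = -math.log1p(-u) / total
        if state.t + dt > tmax:
            break
        v = rng.random() * total
        chosen = int(np.searchsorted(np.cumsum(w), v, side="right"))
        chosen = min(chosen, len(w) - 1)
        while w[chosen] == 0.0:  # float boundary landing on a zero-rate slot
            chosen -= 1
        state.t += dt
        apply_and_record(state, chosen, traj)
        if debug_coherence:
            state.check_coherence()
    traj.t_end = tmax
    return traj
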