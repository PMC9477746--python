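"""Deterministic state machine of the motor nucleotide cycle.

The processive cycle runs through five structural states (s1..s5) per motor:

* s1 -> s2  ADP release in subunit D (bottom of the staircase); the second
  RuvA domain-III tether binds subunit E;
* s2 -> s3  catalytic cleavage in subunit A (top): ATP -> ADP + Mg;
* s3 -> s4  magnesium release in subunit A: ADP + Mg -> ADP;
* s4 -> s5  ATP uptake in subunit D;
* s5 -> s1' the cluster switch: every subunit adopts the conformation of its
  successor position (A -> F, B -> A, ...) with no change in per-pocket
  chemistry, the register advances by one, and the motor has walked two
  nucleotides along the DNA while rotating 60 degrees.

One full cycle therefore hydrolyses one ATP per motor and advances the DNA
by two nucleotides; six cycles complete a 360-degree rotation and return
every subunit to its starting position.  The model is purely structural and
sequential — no rates, no thermodynamics, no stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import CycleError

__all__ = [
    "CycleState",
    "CycleEvent",
    "CycleTrace",
    "S1_PATTERN",
    "S0_PATTERN",
    "S0_T1_PATTERN",
    "step",
    "run_cycles",
    "initiation_to_cycle",
]

SUBUNITS = ("A", "B", "C", "D", "E", "F")
OCCUPANCY_VALUES = ("ATP", "ADP_Mg", "ADP", "apo")

#: Sequential-cycle entry pattern (state s1).
S1_PATTERN = {"A": "ATP", "B": "ATP", "C": "ATP", "D": "ADP", "E": "ADP", "F": "ADP"}
#: Initiation pattern with four ATP (A-D) after stochastic loading.
S0_PATTERN = {"A": "ATP", "B": "ATP", "C": "ATP", "D": "ATP", "E": "ADP", "F": "ADP"}
#: Early initiation pattern carrying a fifth ATP in subunit F.
S0_T1_PATTERN = {"A": "ATP", "B": "ATP", "C": "ATP", "D": "ATP", "E": "ADP", "F": "ATP"}

#: Single-pocket chemistry steps allowed during out-of-register initiation.
_FORWARD_EVENT = {
    "ATP": ("hydrolysis_cleavage", "ADP_Mg"),
    "ADP_Mg": ("Mg_release", "ADP"),
    "ADP": ("ADP_release", "apo"),
    "apo": ("ATP_uptake", "ATP"),
}

STATE_SEQUENCE = ("s1", "s2", "s3", "s4", "s5")


@dataclass(frozen=True)
class CycleEvent:
    transition: str   # e.g. "s1->s2"
    subunit: str
    event_type: str   # ADP_release | hydrolysis_cleavage | Mg_release | ATP_uptake | cluster_switch
    note: str = ""


@dataclass(frozen=True)
class CycleState:
    """One structural state of a motor with its pocket chemistry and register."""

    state_label: str
    occupancy: Mapping[str, str]
    ruvA_d3_bound: frozenset = frozenset({"D"})
    register: int = 0  # completed cluster switches

    def __post_init__(self):
        if self.state_label not in STATE_SEQUENCE:
            raise CycleError(f"unknown cycle state {self.state_label!r}")
        occ = dict(self.occupancy)
        if sorted(occ) != list(SUBUNITS):
            raise CycleError(f"occupancy must cover subunits A-F, got {sorted(occ)}")
        bad = {s: v for s, v in occ.items() if v not in OCCUPANCY_VALUES}
        if bad:
            raise CycleError(f"invalid occupancy values: {bad}")
        object.__setattr__(self, "occupancy", occ)
        expected = _expected_occupancy(self.state_label)
        if occ != expected:
            raise CycleError(
                f"state {self.state_label} occupancy {occ} violates the cycle "
                f"invariant {expected}"
            )
        d3 = frozenset(self.ruvA_d3_bound)
        if not d3 <= {"D", "E"}:
            raise CycleError(f"RuvA D3 may bind only D and E, got {sorted(d3)}")
        if "D" not in d3:
            raise CycleError("RuvA D3 must stay bound to subunit D throughout s1-s5")
        if ("E" in d3) != (self.state_label in ("s2", "s3", "s4", "s5")):
            raise CycleError(
                f"state {self.state_label}: second RuvA D3 on E is bound in s2-s5 only"
            )
        object.__setattr__(self, "ruvA_d3_bound", d3)

    @classmethod
    def initial(cls) -> "CycleState":
        return cls("s1", dict(S1_PATTERN), frozenset({"D"}), 0)


def _expected_occupancy(label: str) -> dict[str, str]:
    occ = dict(S1_PATTERN)
    if label in ("s2", "s3", "s4"):
        occ["D"] = "apo"
    if label == "s3":
        occ["A"] = "ADP_Mg"
    if label in ("s4", "s5"):
        occ["A"] = "ADP"
    if label == "s5":
        occ["D"] = "ATP"
    return occ


def step(state: CycleState) -> tuple[CycleState, CycleEvent]:
    """Deterministic successor of a cycle state, with the driving event."""
    occ = dict(state.occupancy)
    label = state.state_label
    if label == "s1":
        occ["D"] = "apo"
        nxt = CycleState("s2", occ, frozenset({"D", "E"}), state.register)
        ev = CycleEvent("s1->s2", "D", "ADP_release",
                        "second RuvA D3 binds subunit E")
    elif label == "s2":
        occ["A"] = "ADP_Mg"
        nxt = CycleState("s3", occ, state.ruvA_d3_bound, state.register)
        ev = CycleEvent("s2->s3", "A", "hydrolysis_cleavage",
                        "gamma-phosphate released; ATP counted as hydrolysed")
    elif label == "s3":
        occ["A"] = "ADP"
        nxt = CycleState("s4", occ, state.ruvA_d3_bound, state.register)
        ev = CycleEvent("s3->s4", "A", "Mg_release")
    elif label == "s4":
        occ["D"] = "ATP"
        nxt = CycleState("s5", occ, state.ruvA_d3_bound, state.register)
        ev = CycleEvent("s4->s5", "D", "ATP_uptake",
                        "N terminus of E folds away, priming its later ADP release")
    elif label == "s5":
        # cluster switch: each subunit adopts its successor position; the
        # pocket chemistry travels with the subunit (A->F, B->A, ...).
        new_occ = {}
        for i, s in enumerate(SUBUNITS):
            new_occ[SUBUNITS[(i - 1) % 6]] = occ[s]
        nxt = CycleState("s1", new_occ, frozenset({"D"}), state.register + 1)
        ev = CycleEvent("s5->s1'", "*", "cluster_switch",
                        "register shift; RuvA D3 released from E pending re-binding")
    else:  # pragma: no cover - guarded by CycleState validation
        raise CycleError(f"cannot step from {label}")
    return nxt, ev


@dataclass
class CycleTrace:
    """Record of a multi-cycle simulation for one or two motors."""

    events: list[tuple[int, CycleEvent]] = field(default_factory=list)  # (motor, event)
    n_motors: int = 1
    atp_hydrolysed_per_motor: dict[int, int] = field(default_factory=dict)
    atp_taken_up_per_motor: dict[int, int] = field(default_factory=dict)
    cluster_switches_per_motor: dict[int, int] = field(default_factory=dict)

    @property
    def atp_hydrolysed_total(self) -> int:
        return sum(self.atp_hydrolysed_per_motor.values())

    @property
    def atp_taken_up_total(self) -> int:
        return sum(self.atp_taken_up_per_motor.values())

    @property
    def switches_per_motor(self) -> int:
        vals = set(self.cluster_switches_per_motor.values()) or {0}
        if len(vals) != 1:
            raise CycleError("motors are out of step")  # pragma: no cover
        return vals.pop()

    @property
    def dna_advance_nt(self) -> int:
        """Net DNA advance: two nucleotides per cluster switch per motor.

        The two motors flank the junction and pull synchronously on the two
        emerging duplexes, so the advance is counted once, not per motor.
        """
        return 2 * self.switches_per_motor

    @property
    def rotation_deg(self) -> float:
        return 60.0 * self.switches_per_motor


def run_cycles(n_cycles: int, n_motors: int = 1) -> CycleTrace:
    """Run ``n_cycles`` full nucleotide cycles on ``n_motors`` motors."""
    if n_cycles < 0:
        raise CycleError("n_cycles must be >= 0")
    if n_motors not in (1, 2):
        raise CycleError("n_motors must be 1 or 2")
    trace = CycleTrace(n_motors=n_motors)
    for motor in range(n_motors):
        trace.atp_hydrolysed_per_motor[motor] = 0
        trace.atp_taken_up_per_motor[motor] = 0
        trace.cluster_switches_per_motor[motor] = 0
        state = CycleState.initial()
        for _ in range(5 * n_cycles):
            state, ev = step(state)
            trace.events.append((motor, ev))
            if ev.event_type == "hydrolysis_cleavage":
                trace.atp_hydrolysed_per_motor[motor] += 1
            elif ev.event_type == "ATP_uptake":
                trace.atp_taken_up_per_motor[motor] += 1
            elif ev.event_type == "cluster_switch":
                trace.cluster_switches_per_motor[motor] += 1
    return trace


#: Initiation events start in the substrate-disengaged converter (the early
#: five-ATP pattern resolves by hydrolysis in subunit F), so ties between
#: equally short event lists are broken converter-first.
_INITIATION_ORDER = ("F", "E", "D", "C", "B", "A")


def initiation_to_cycle(s0_occupancy: Mapping[str, str]):
    """Out-of-register events taking an initiation pattern to the s1 pattern.

    Pocket chemistry moves only forward along ATP -> ADP+Mg -> ADP -> apo ->
    ATP, one subunit at a time; the returned list is the shortest such event
    sequence (subunits resolved converter-first: F, then E, D, C, B, A).
    Returns ``(entry_state, events)`` where the entry state is s1.
    """
    occ = dict(s0_occupancy)
    if sorted(occ) != list(SUBUNITS):
        raise CycleError(f"occupancy must cover subunits A-F, got {sorted(occ)}")
    bad = {s: v for s, v in occ.items() if v not in OCCUPANCY_VALUES}
    if bad:
        raise CycleError(f"invalid occupancy values: {bad}")
    events: list[CycleEvent] = []
    for s in _INITIATION_ORDER:
        guard = 0
        while occ[s] != S1_PATTERN[s]:
            ev_type, nxt = _FORWARD_EVENT[occ[s]]
            events.append(CycleEvent("initiation", s, ev_type))
            occ[s] = nxt
            guard += 1
            if guard > 4:  # pragma: no cover - cycle of length 4 always closes
                raise CycleError(f"subunit {s}: cannot reach the s1 pattern")
    entry = CycleState("s1", occ, frozenset({"D"}), 0)
    return entry, events
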