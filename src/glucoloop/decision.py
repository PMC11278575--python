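"""Threshold decision engine for the closed diagnostic-therapeutic loop.

The loop reads a sweat-glucose estimate from the sensing side, compares it
against a therapy threshold (default 400 μM, strict greater-than), and on
a positive decision emits exactly one command to the thermal release
circuit. A cooldown guards against re-dosing on a persistently high
signal. Every reading, decision and command is appended to an ordered
event log so a run is fully auditable and reproducible.

Blood-glucose context (for reporting only): hypoglycemia is conventionally
below 70 mg/dL and hyperglycemia above 130 mg/dL. No sweat-to-blood
conversion is applied anywhere — decisions compare sweat concentrations
directly against the sweat threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from .calibration import ConcentrationEstimate, EstimateStatus
from .exceptions import DataError

#: Sweat-glucose therapy threshold, μM.
DEFAULT_THRESHOLD_UM: float = 400.0

#: Default refractory period between triggers, s.
DEFAULT_COOLDOWN_S: float = 1800.0

#: Blood-glucose reference bounds (mg/dL), documentation constants only.
HYPOGLYCEMIA_MGDL: float = 70.0
HYPERGLYCEMIA_MGDL: float = 130.0


class Action(str, Enum):
    NO_ACTION = "NO_ACTION"
    TRIGGER = "TRIGGER"


@dataclass(frozen=True)
class DecisionPolicy:
    """Trigger policy: strict threshold comparison plus cooldown."""

    threshold_um: float = DEFAULT_THRESHOLD_UM
    cooldown_s: float = DEFAULT_COOLDOWN_S
    require_status_ok: bool = True

    def __post_init__(self) -> None:
        if self.threshold_um <= 0:
            raise DataError("threshold must be > 0 μM")
        if self.cooldown_s < 0:
            raise DataError("cooldown must be >= 0 s")


@dataclass
class LoopState:
    """Decision-engine state with an ordered, append-only event log."""

    time_s: float = 0.0
    last_estimate: ConcentrationEstimate | None = None
    action: Action = Action.NO_ACTION
    htrc_armed: bool = True
    last_trigger_time_s: float | None = None
    event_log: list[dict[str, Any]] = field(default_factory=list)

    def log(self, time_s: float, kind: str, **payload: Any) -> None:
        if self.event_log and time_s < self.event_log[-1]["time_s"]:
            raise DataError("event log times must be non-decreasing")
        self.event_log.append({"time_s": time_s, "kind": kind, **payload})


def decide(
    policy: DecisionPolicy, estimate: ConcentrationEstimate, state: LoopState,
    time_s: float | None = None,
) -> LoopState:
    """Apply the policy to one estimate, mutating and returning the state.

    TRIGGER fires iff the estimated concentration strictly exceeds the
    threshold, the estimate's status is acceptable, the circuit is armed
    and the cooldown since the previous trigger has elapsed. Degenerate
    estimates never raise: they produce NO_ACTION with a logged reason.
    """
    t = state.time_s if time_s is None else time_s
    state.time_s = t
    state.last_estimate = estimate
    state.log(t, "reading", value_uM=estimate.value, status=estimate.status.value)

    reason = None
    if policy.require_status_ok and estimate.status is not EstimateStatus.OK:
        reason = f"estimate status {estimate.status.value} not usable"
    elif not estimate.value > policy.threshold_um:
        reason = f"value {estimate.value:.1f} μM not above threshold"
    elif not state.htrc_armed:
        reason = "release circuit not armed"
    elif (
        state.last_trigger_time_s is not None
        and t - state.last_trigger_time_s < policy.cooldown_s
    ):
        reason = "cooldown not elapsed"

    if reason is None:
        state.action = Action.TRIGGER
        state.last_trigger_time_s = t
        state.log(t, "decision", action=Action.TRIGGER.value,
                  threshold_uM=policy.threshold_um)
        state.log(t, "command", message=encode_command(Action.TRIGGER, t))
    else:
        state.action = Action.NO_ACTION
        state.log(t, "decision", action=Action.NO_ACTION.value, reason=reason)
    return state


def encode_command(action: Action, time_s: float) -> dict[str, Any]:
    """Structured release-circuit command record (JSON-lines message body)."""
    if not isinstance(action, Action):
        raise DataError(f"unknown action: {action!r}")
    return {"type": "htrc_command", "action": action.value, "time_s": float(time_s)}


def serialize_command(message: dict[str, Any]) -> str:
    """Byte-stable single-line serialization of a command message."""
    return json.dumps(message, sort_keys=True, separators=(",", ":"))


def decode_command(line: str) -> dict[str, Any]:
    msg = json.loads(line)
    if msg.get("type") != "htrc_command" or msg.get("action") not in Action.__members__:
        raise DataError(f"not a valid command message: {line!r}")
    return msg


def write_event_log(events: list[dict[str, Any]], path) -> None:
    """Write events as JSON lines, one event per line, key-sorted."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev, sort_keys=True) + "\n")
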