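"""Virtual gantry controller: binary instruction set, FIFO execution, routes.

Software twin of an open-loop CNC scanning gantry driven by an Arduino
stepper stack.  Host software compiles movement commands into 12-byte
frames — three little-endian signed 32-bit integers ``(opcode, arg1,
arg2)`` — that are enqueued in strict FIFO order and executed one at a
time:

====== ========================================== ========== =======
opcode meaning                                    arg1       arg2
====== ========================================== ========== =======
1      move X/Y to absolute position              X steps    Y steps
2      set delay between movements                ms         0
3      move X/Y by relative offset                dX steps   dY steps
4      move Z to absolute position                Z steps    0
5      move Z by relative offset                  dZ steps   0
6      set movement speed                         steps/s    0
====== ========================================== ========== =======

The simulated machine enforces the physical travel box (1.35 m x 1.55 m x
85 cm) and the 8 cm/s safe-speed cap; out-of-bounds moves are rejected
atomically (open-loop control has no feedback to recover from a clipped
move).  Moves take ``distance / speed + delay`` simulated seconds at
constant speed.
"""

from __future__ import annotations

import math
import struct
import warnings
from dataclasses import dataclass, field, replace

from .errors import EncodingError, GeometryError

__all__ = [
    "Instruction",
    "MachineState",
    "InstructionQueue",
    "RoutePlan",
    "encode",
    "decode",
    "execute",
    "plan_serpentine",
    "line_length_for_height",
    "workable_area_m2",
    "load_route",
    "save_route",
    "MOVE_XY_ABS",
    "SET_DELAY",
    "MOVE_XY_REL",
    "MOVE_Z_ABS",
    "MOVE_Z_REL",
    "SET_SPEED",
]

MOVE_XY_ABS = 1
SET_DELAY = 2
MOVE_XY_REL = 3
MOVE_Z_ABS = 4
MOVE_Z_REL = 5
SET_SPEED = 6

#: Opcodes whose second argument must be zero on the wire.
_ZERO_ARG2 = frozenset({SET_DELAY, MOVE_Z_ABS, MOVE_Z_REL, SET_SPEED})

_INT32_MIN, _INT32_MAX = -(2**31), 2**31 - 1
_FRAME = struct.Struct("<iii")  # 12 bytes

#: Axis travel capacities in cm and the safe-speed cap in cm/s.
TRAVEL_CM = (135.0, 155.0, 85.0)
MAX_SAFE_SPEED_CM_S = 8.0
OPTIMAL_SCAN_SPEED_CM_S = 1.0


@dataclass(frozen=True)
class Instruction:
    """One 12-byte control command: (opcode, arg1, arg2)."""

    opcode: int
    arg1: int = 0
    arg2: int = 0

    def validate(self) -> "Instruction":
        if self.opcode not in range(1, 7):
            raise EncodingError(f"opcode must be 1..6, got {self.opcode}")
        for name, val in (("arg1", self.arg1), ("arg2", self.arg2)):
            if not (_INT32_MIN <= val <= _INT32_MAX):
                raise EncodingError(f"{name}={val} outside signed 32-bit range")
        if self.opcode in _ZERO_ARG2 and self.arg2 != 0:
            raise EncodingError(f"opcode {self.opcode} requires arg2 = 0, got {self.arg2}")
        return self


def encode(instr: Instruction) -> bytes:
    """Pack an instruction into its 12-byte little-endian frame."""
    instr.validate()
    return _FRAME.pack(instr.opcode, instr.arg1, instr.arg2)


def decode(frame: bytes) -> Instruction:
    """Unpack one 12-byte frame; inverse of :func:`encode`."""
    if len(frame) != _FRAME.size:
        raise EncodingError(f"frame must be {_FRAME.size} bytes, got {len(frame)}")
    opcode, arg1, arg2 = _FRAME.unpack(frame)
    return Instruction(opcode, arg1, arg2).validate()


@dataclass
class MachineState:
    """Gantry position/speed/delay state in motor steps.

    ``steps_per_cm`` is the calibration constant linking steps to physical
    distance (never published for the original rig; 40 steps/cm comfortably
    beats the ±0.10 cm positioning spec and is configurable).
    """

    x: int = 0
    y: int = 0
    z: int = 0
    speed: float = OPTIMAL_SCAN_SPEED_CM_S * 40.0  # steps/s
    delay_ms: float = 0.0
    steps_per_cm: float = 40.0
    travel_cm: tuple[float, float, float] = TRAVEL_CM

    def limit_steps(self, axis: int) -> int:
        return int(round(self.travel_cm[axis] * self.steps_per_cm))

    @property
    def max_speed(self) -> float:
        return MAX_SAFE_SPEED_CM_S * self.steps_per_cm

    def in_bounds(self, x: int, y: int, z: int) -> bool:
        return (0 <= x <= self.limit_steps(0) and 0 <= y <= self.limit_steps(1)
                and 0 <= z <= self.limit_steps(2))

    def copy(self) -> "MachineState":
        return replace(self)


@dataclass
class InstructionQueue:
    """Strict FIFO of pending instructions plus an executed log."""

    pending: list[Instruction] = field(default_factory=list)
    executed: list[dict] = field(default_factory=list)

    def push(self, *instructions: Instruction) -> None:
        for instr in instructions:
            self.pending.append(instr.validate())

    def push_bytes(self, stream: bytes) -> None:
        """Accept a byte stream of concatenated 12-byte frames."""
        if len(stream) % _FRAME.size:
            raise EncodingError("byte stream length is not a multiple of 12")
        for off in range(0, len(stream), _FRAME.size):
            self.pending.append(decode(stream[off:off + _FRAME.size]))


def execute(queue: InstructionQueue, state: MachineState) -> tuple[MachineState, list[dict]]:
    """Drain the queue in FIFO order, mutating a copy of ``state``.

    Every instruction produces one event dict with the instruction, its
    order index, a status (``executed`` / ``rejected`` / ``clamped``), the
    simulated duration in seconds and the post-instruction position.
    Limit-violating moves are rejected whole: the state is untouched.
    Speeds above the safe cap are clamped with a warning event.
    """
    state = state.copy()
    events: list[dict] = []
    for index, instr in enumerate(queue.pending):
        instr.validate()
        status = "executed"
        duration = 0.0
        target = (state.x, state.y, state.z)
        if instr.opcode in (MOVE_XY_ABS, MOVE_XY_REL, MOVE_Z_ABS, MOVE_Z_REL):
            if instr.opcode == MOVE_XY_ABS:
                target = (instr.arg1, instr.arg2, state.z)
            elif instr.opcode == MOVE_XY_REL:
                target = (state.x + instr.arg1, state.y + instr.arg2, state.z)
            elif instr.opcode == MOVE_Z_ABS:
                target = (state.x, state.y, instr.arg1)
            else:
                target = (state.x, state.y, state.z + instr.arg1)
            if not state.in_bounds(*target):
                status = "rejected"
                target = (state.x, state.y, state.z)
            else:
                dist = math.dist(target, (state.x, state.y, state.z))
                duration = dist / state.speed + state.delay_ms / 1000.0
                state.x, state.y, state.z = target
        elif instr.opcode == SET_DELAY:
            if instr.arg1 < 0:
                status = "rejected"
            else:
                state.delay_ms = float(instr.arg1)
        elif instr.opcode == SET_SPEED:
            if instr.arg1 <= 0:
                status = "rejected"
            elif instr.arg1 > state.max_speed:
                state.speed = state.max_speed
                status = "clamped"
            else:
                state.speed = float(instr.arg1)
        events.append({
            "index": index,
            "instruction": instr,
            "status": status,
            "duration_s": duration,
            "position": (state.x, state.y, state.z),
            "speed": state.speed,
            "delay_ms": state.delay_ms,
        })
    queue.executed.extend(events)
    queue.pending.clear()
    return state, events


@dataclass
class RoutePlan:
    """Boustrophedon scan route: waypoints in cm plus motion parameters."""

    waypoints_cm: list[tuple[float, float]]
    speed_cm_s: float
    z_cm: float
    lane_spacing_cm: float

    @property
    def n_lanes(self) -> int:
        return len(self.waypoints_cm) // 2

    def path_length_cm(self) -> float:
        return sum(
            math.dist(a, b) for a, b in zip(self.waypoints_cm, self.waypoints_cm[1:])
        )


def plan_serpentine(
    area_cm: tuple[float, float, float, float],
    lane_spacing_cm: float,
    speed_cm_s: float = OPTIMAL_SCAN_SPEED_CM_S,
    z_cm: float = 30.0,
    steps_per_cm: float = 40.0,
) -> tuple[RoutePlan, list[Instruction]]:
    """Cover a rectangle with back-and-forth lanes and compile to instructions.

    ``area_cm = (x0, y0, x1, y1)``.  Lanes run along X at Y = y0, y0 + s,
    ..., always ending with a lane at y1; each lane contributes two corner
    waypoints in serpentine order.  The compiled program sets the speed and
    Z height, then issues one absolute X/Y move per waypoint.
    """
    x0, y0, x1, y1 = area_cm
    if lane_spacing_cm <= 0:
        raise GeometryError("lane spacing must be positive")
    if not (x0 < x1 and y0 <= y1):
        raise GeometryError("degenerate scan area")
    if x0 < 0 or y0 < 0 or x1 > TRAVEL_CM[0] or y1 > TRAVEL_CM[1] or not 0 <= z_cm <= TRAVEL_CM[2]:
        raise GeometryError("scan area or height outside the travel box")
    if lane_spacing_cm > (y1 - y0) and y1 > y0:
        warnings.warn("lane spacing wider than the area: single-lane plan", stacklevel=2)
        ys = [y0]
    else:
        n = int(math.floor((y1 - y0) / lane_spacing_cm + 1e-9))
        ys = [y0 + i * lane_spacing_cm for i in range(n + 1)]
        if ys[-1] < y1 - 1e-9:
            ys.append(y1)
    waypoints: list[tuple[float, float]] = []
    for i, y in enumerate(ys):
        xs = (x0, x1) if i % 2 == 0 else (x1, x0)
        waypoints.extend([(xs[0], y), (xs[1], y)])
    plan = RoutePlan(waypoints_cm=waypoints, speed_cm_s=speed_cm_s, z_cm=z_cm,
                     lane_spacing_cm=lane_spacing_cm)
    program = [
        Instruction(SET_SPEED, int(round(speed_cm_s * steps_per_cm))),
        Instruction(MOVE_Z_ABS, int(round(z_cm * steps_per_cm))),
    ]
    program += [
        Instruction(MOVE_XY_ABS, int(round(wx * steps_per_cm)), int(round(wy * steps_per_cm)))
        for wx, wy in waypoints
    ]
    return plan, program


def workable_area_m2(travel_cm: tuple[float, float, float] = TRAVEL_CM) -> float:
    """Scan/workable area in m^2: the X by Y travel rectangle."""
    return (travel_cm[0] / 100.0) * (travel_cm[1] / 100.0)


def line_length_for_height(
    z_cm: float, fov_angle_deg: float, standoff_cm: float = 0.0
) -> float:
    """Scan-line footprint of the line scanner at height ``z_cm``.

    ``length = 2 (z + standoff) tan(fov/2)`` — proportional to the optical
    height.  ``standoff_cm`` is the fixed offset between the Z carriage
    zero and the lens (the published 0.53 cm minimum line length implies a
    small nonzero standoff, left as a parameter).
    """
    if not 0 <= z_cm <= TRAVEL_CM[2]:
        raise GeometryError(f"z={z_cm} cm outside Z travel 0..{TRAVEL_CM[2]}")
    if not 0.0 < fov_angle_deg < 180.0:
        raise GeometryError("FOV angle must be in (0, 180) degrees")
    return 2.0 * (z_cm + standoff_cm) * math.tan(math.radians(fov_angle_deg) / 2.0)


def load_route(path) -> list[tuple[float, float]]:
    """Read a plain-text route file of ``x_cm,y_cm`` lines."""
    waypoints = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            x, y = line.split(",")
            waypoints.append((float(x), float(y)))
    return waypoints


def save_route(waypoints: list[tuple[float, float]], path) -> None:
    """Write waypoints as ``x_cm,y_cm`` text lines."""
    with open(path, "w") as fh:
        for x, y in waypoints:
            fh.write(f"{x:.3f},{y:.3f}\n")
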