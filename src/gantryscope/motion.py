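"""Marlin-dialect G-code generation and stage transports.

A consumer 3D printer exposes its motion system over a serial line speaking
G-code: ``G0``/``G1`` linear moves, ``G28`` homing, ``M84`` stepper disable and
``M400`` "wait for moves to finish".  This module renders those commands,
implements the one-``ok``-per-command acknowledgement protocol, and provides
two interchangeable endpoints: a :class:`SerialTransport` for a real printer
and a :class:`VirtualStage` that tracks a *truth pose* through a configurable
positional-error model (Gaussian jitter plus direction-reversal backlash) so
that the whole acquisition stack can be exercised without hardware.

Coordinates are absolute millimetres (``G90`` is issued by
:func:`initialize`); feedrates are mm/min.  Commands are rendered without the
trailing newline — transports append the LF when writing to the wire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "StagePose",
    "MotionLimits",
    "StageErrorModel",
    "MotionError",
    "OutOfRangeError",
    "TransportError",
    "ProtocolError",
    "render_move",
    "home",
    "disable_steppers",
    "await_motion_complete",
    "absolute_positioning",
    "send",
    "initialize",
    "VirtualStage",
    "SerialTransport",
]


class MotionError(Exception):
    """Base class for motion-control errors."""


class OutOfRangeError(MotionError, ValueError):
    """A pose lies outside the stage's motion limits."""

    def __init__(self, axis: str, value: float, limit: float):
        self.axis = axis
        self.value = value
        self.limit = limit
        super().__init__(
            f"axis {axis}: commanded {value:.3f} mm outside [0, {limit:.3f}] mm"
        )


class TransportError(MotionError, IOError):
    """The endpoint is closed, unreachable, or timed out."""


class ProtocolError(MotionError):
    """The endpoint replied with an error line."""


@dataclass(frozen=True)
class MotionLimits:
    """Axis travel limits in mm (defaults: Ender 3 Pro build volume)."""

    x_max: float = 220.0
    y_max: float = 220.0
    z_max: float = 250.0

    def __post_init__(self) -> None:
        for axis in ("x", "y", "z"):
            if getattr(self, f"{axis}_max") <= 0:
                raise ValueError(f"{axis}_max must be strictly positive")


DEFAULT_LIMITS = MotionLimits()


@dataclass(frozen=True)
class StagePose:
    """Absolute stage coordinates in mm, with an optional feedrate in mm/min."""

    x: float
    y: float
    z: float
    feedrate: Optional[float] = None

    def __post_init__(self) -> None:
        for axis in ("x", "y", "z"):
            v = getattr(self, axis)
            if not math.isfinite(v):
                raise ValueError(f"{axis} must be finite, got {v!r}")
        if self.feedrate is not None and not (
            math.isfinite(self.feedrate) and self.feedrate > 0
        ):
            raise ValueError(f"feedrate must be positive, got {self.feedrate!r}")

    def validate(self, limits: MotionLimits = DEFAULT_LIMITS) -> "StagePose":
        for axis in ("x", "y", "z"):
            v = getattr(self, axis)
            lim = getattr(limits, f"{axis}_max")
            if not (0.0 <= v <= lim):
                raise OutOfRangeError(axis, v, lim)
        return self

    def replace(self, **kw) -> "StagePose":
        d = {"x": self.x, "y": self.y, "z": self.z, "feedrate": self.feedrate}
        d.update(kw)
        return StagePose(**d)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class StageErrorModel:
    """Positional-error model for the virtual stage.

    jitter_sd_um
        Per-axis standard deviation of an independent Gaussian error added to
        every motion command, in micrometres.  The measured repeatability of
        the physical instrument (max deviation within +-4 um over repeated
        6 mm moves) is reproduced with jitter_sd_um of a couple of microns.
    backlash_um
        Lost motion on direction reversal: when the last commanded move along
        an axis was in the negative direction the truth position lags the
        commanded position by this amount.
    seed
        Seed for the jitter stream; identical seeds replay identical error
        sequences.
    """

    jitter_sd_um: float = 0.0
    backlash_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_um < 0:
            raise ValueError("jitter_sd_um must be >= 0")
        if self.backlash_um < 0:
            raise ValueError("backlash_um must be >= 0")


def _fmt_feed(f: float) -> str:
    return f"{f:.0f}" if float(f).is_integer() else f"{f:g}"


def render_move(
    pose: StagePose,
    rapid: bool = False,
    limits: Optional[MotionLimits] = DEFAULT_LIMITS,
) -> str:
    """Render a linear move as a single G-code line.

    Coordinates are fixed to two decimal places (0.01 mm); ``rapid`` selects
    ``G0`` over ``G1``.  The pose is validated against ``limits`` unless
    ``limits`` is None.
    """
    if limits is not None:
        pose.validate(limits)
    word = "G0" if rapid else "G1"
    line = f"{word} X{pose.x:.2f} Y{pose.y:.2f} Z{pose.z:.2f}"
    if pose.feedrate is not None:
        line += f" F{_fmt_feed(pose.feedrate)}"
    return line


def home() -> str:
    return "G28"


def disable_steppers() -> str:
    return "M84"


def await_motion_complete() -> str:
    return "M400"


def absolute_positioning() -> str:
    return "G90"


def send(command: str, transport) -> str:
    """Send one command and block for its acknowledgement.

    Returns the ``ok`` reply; raises :class:`ProtocolError` on an
    ``error``-prefixed reply and :class:`TransportError` if the endpoint is
    closed or times out (raised by the transport itself).
    """
    reply = transport.send(command)
    if reply.startswith("error"):
        raise ProtocolError(reply)
    return reply


def initialize(transport) -> None:
    """Put the stage into absolute-positioning mode (issued on connect)."""
    send(absolute_positioning(), transport)


class VirtualStage:
    """In-memory stage endpoint with the same send/ack contract as a printer.

    Tracks both the *commanded* pose and a *truth* pose (commanded pose plus
    a draw from the :class:`StageErrorModel`), exposed for tests and for the
    virtual camera.  Truth poses for every motion command are logged in
    :attr:`truth_history`.
    """

    def __init__(
        self,
        limits: MotionLimits = DEFAULT_LIMITS,
        error_model: StageErrorModel = StageErrorModel(),
    ):
        self.limits = limits
        self.error_model = error_model
        self._open = True
        self._commanded = np.zeros(3)
        self._offset = np.zeros(3)  # jitter + backlash, mm
        self._last_dir = np.zeros(3)  # sign of last commanded move per axis
        self._rng = np.random.default_rng(error_model.seed)
        self.truth_history: list[StagePose] = []
        self.command_log: list[str] = []
        self._apply_error()  # power-on position carries an error draw

    # -- lifecycle -----------------------------------------------------
    def close(self) -> None:
        self._open = False

    def open(self) -> None:
        self._open = True

    @property
    def is_open(self) -> bool:
        return self._open

    def __enter__(self) -> "VirtualStage":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- state ---------------------------------------------------------
    @property
    def commanded_pose(self) -> StagePose:
        return StagePose(*self._commanded)

    @property
    def truth_pose(self) -> StagePose:
        t = self._commanded + self._offset
        return StagePose(t[0], t[1], t[2])

    def _apply_error(self) -> None:
        m = self.error_model
        jitter = self._rng.normal(0.0, m.jitter_sd_um / 1000.0, size=3)
        backlash = np.where(self._last_dir < 0, -m.backlash_um / 1000.0, 0.0)
        self._offset = jitter + backlash
        self.truth_history.append(self.truth_pose)

    # -- protocol --------------------------------------------------------
    def send(self, command: str) -> str:
        if not self._open:
            raise TransportError("virtual stage endpoint is closed")
        line = command.strip()
        self.command_log.append(line)
        if not line:
            return "ok"
        words = line.split()
        code = words[0].upper()
        if code in ("G0", "G1"):
            target = self._commanded.copy()
            for w in words[1:]:
                axis = w[0].upper()
                if axis in "XYZ":
                    target["XYZ".index(axis)] = float(w[1:])
                elif axis == "F":
                    float(w[1:])  # feedrate accepted, not modelled
                else:
                    return f"error:unknown word {w!r}"
            for i, axis in enumerate("xyz"):
                lim = getattr(self.limits, f"{axis}_max")
                if not (0.0 <= target[i] <= lim):
                    return f"error:axis {axis} target {target[i]:.2f} outside [0, {lim:.2f}]"
            delta = target - self._commanded
            moved = delta != 0
            self._last_dir[moved] = np.sign(delta[moved])
            self._commanded = target
            self._apply_error()
            return "ok"
        if code == "G28":
            self._commanded = np.zeros(3)
            self._last_dir = np.zeros(3)
            self._apply_error()
            return "ok"
        if code in ("G90", "M84", "M400"):
            return "ok"
        return f"error:unknown command {line!r}"


class SerialTransport:
    """Serial endpoint for a real printer (115200 baud 8N1 by default).

    Wraps pyserial, which is an optional dependency; the virtual stage is the
    reference endpoint for development and testing.
    """

    def __init__(self, port: str, baudrate: int = 115200, timeout: float = 30.0):
        try:
            import serial  # optional extra: gantryscope[serial]
        except ImportError as exc:  # pragma: no cover - hardware-only path
            raise TransportError(
                "pyserial is required for a real serial stage; "
                "install gantryscope[serial]"
            ) from exc
        self._ser = serial.Serial(port=port, baudrate=baudrate, timeout=timeout)

    def close(self) -> None:  # pragma: no cover - hardware-only path
        self._ser.close()

    def send(self, command: str) -> str:  # pragma: no cover - hardware-only path
        if not self._ser.is_open:
            raise TransportError("serial port is closed")
        self._ser.write((command.strip() + "\n").encode("ascii"))
        while True:
            raw = self._ser.readline()
            if not raw:
                raise TransportError(f"timeout waiting for ack of {command!r}")
            reply = raw.decode("ascii", errors="replace").strip()
            if reply.startswith("ok") or reply.startswith("error"):
                return reply
            # Marlin interleaves temperature/status chatter; keep waiting.
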