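"""Sensor fusion: from color-mark-sensor trigger events to a label position.

The sensing rig carries six color mark sensors whose beams sweep three
detection lines in image space: sensors 1 and 4 share line A, the middle
sensors 2 and 5 share line B (parallel to the travel direction), and
sensors 3 and 6 share line C.  A plant label is localized from the first
pair of triggers that arrive on two *distinct* lines: the time gap ``dt``
between the two triggers, scaled by the conveyor speed ``v`` (px/s),
fixes the intersection point of the two detection lines via a six-case
rule (one case per ordered line pair).

Coordinates are ``(x = column, y = row)`` with the origin at the top-left
corner of the image; travel is along +y.  The fused estimate always falls
on one of three loci through the image center ``(c, c)``: the main
diagonal, the vertical line ``x = c``, or the anti-diagonal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InvalidPairError, InvalidSensorError, PreconditionError

__all__ = [
    "LINE_OF",
    "SensorArray",
    "SensorEvent",
    "FusedSignal",
    "line_of",
    "is_valid_pair",
    "estimate_label_position",
    "select_signal",
    "load_events",
    "round_half_away",
]

#: Detection line of each sensor: {1,4} -> A, {2,5} -> B, {3,6} -> C.
LINE_OF = {1: "A", 4: "A", 2: "B", 5: "B", 3: "C", 6: "C"}


def line_of(sensor_id: int) -> str:
    """Return the detection line ("A", "B" or "C") of a sensor id."""
    try:
        return LINE_OF[sensor_id]
    except (KeyError, TypeError):
        raise InvalidSensorError(f"sensor id must be in 1..6, got {sensor_id!r}") from None


def is_valid_pair(a: int, b: int) -> bool:
    """True iff sensors ``a`` and ``b`` sit on distinct detection lines.

    Two triggers on the same line carry no cross-line intersection and
    cannot localize a label; such detections are discarded as invalid.
    """
    return line_of(a) != line_of(b)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class SensorArray:
    """Geometry and timing constants of the six-sensor rig.

    Parameters
    ----------
    center:
        Pixel coordinate of the image center on both axes; all three
        detection-line loci pass through ``(center, center)``.
    speed_px_s:
        Conveyor travel speed ``v`` in pixels per second (must be > 0).
    image_size:
        Side length of the (square) camera frame in pixels; always
        ``2 * center``.
    mirror:
        Swap the x/y axes of every estimate.  The mapping of image axes
        onto the belt is a convention (travel = +y by default); mirror
        flips it for rigs wired the other way round.
    """

    center: int = 360
    speed_px_s: float = 400.0
    image_size: int = 720
    mirror: bool = False
    sensor_ids: tuple[int, ...] = field(default=(1, 2, 3, 4, 5, 6), init=False)

    def __post_init__(self):
        if self.speed_px_s <= 0:
            raise ValueError(f"speed_px_s must be > 0, got {self.speed_px_s}")
        if self.image_size != 2 * self.center:
            raise ValueError(
                f"image_size must equal 2 * center ({2 * self.center}), got {self.image_size}"
            )


@dataclass(frozen=True)
class SensorEvent:
    """One trigger: a sensor id (1..6) and a timestamp in seconds."""

    sensor_id: int
    timestamp: float

    def __post_init__(self):
        line_of(self.sensor_id)  # validates the id
        if self.timestamp < 0:
            raise ValueError(f"timestamp must be >= 0, got {self.timestamp}")


@dataclass(frozen=True)
class FusedSignal:
    """A validated ordered sensor pair and the label position it implies.

    ``ser_1``/``ser_2`` are the first and second trigger of the earliest
    valid (cross-line) pair, ``dt`` their time gap in seconds, ``point``
    the estimated label pixel ``(x, y)``.  ``clamped`` flags estimates
    that fell outside the frame and were clamped to its border.
    """

    ser_1: int
    ser_2: int
    dt: float
    point: tuple[int, int]
    clamped: bool = False


def _case_point(la: str, lb: str, d: float, c: int) -> tuple[float, float]:
    # One branch per ordered line pair; d = dt * v in pixels.
    if la == "A" and lb == "B":
        return (c - d, c - d)
    if la == "A" and lb == "C":
        return (c - d / 2, c - d / 2)
    if la == "B" and lb == "A":
        return (c, c + d)
    if la == "B" and lb == "C":
        return (c, c - d)
    if la == "C" and lb == "A":
        return (c - d / 2, c + d / 2)
    if la == "C" and lb == "B":
        return (c - d, c + d)
    raise AssertionError(f"unreachable line pair {la}->{lb}")


def estimate_label_position(
    ser_1: int,
    ser_2: int,
    dt: float,
    array: SensorArray,
    *,
    with_flag: bool = False,
) -> tuple[int, int] | tuple[tuple[int, int], bool]:
    """Intersect the two detection lines of an ordered trigger pair.

    With ``d = dt * v`` and ``c = array.center`` the six ordered line
    pairs map to: (A,B) -> ``(c-d, c-d)``; (A,C) -> ``(c-d/2, c-d/2)``;
    (B,A) -> ``(c, c+d)``; (B,C) -> ``(c, c-d)``; (C,A) ->
    ``(c-d/2, c+d/2)``; (C,B) -> ``(c-d, c+d)``.  Coordinates are rounded
    to the nearest integer (ties away from zero) and clamped to the
    frame.  With ``with_flag=True`` also returns whether clamping fired.

    Raises
    ------
    InvalidPairError
        If both sensors share a detection line.
    """
    la, lb = line_of(ser_1), line_of(ser_2)
    if la == lb:
        raise InvalidPairError(
            f"sensors {ser_1} and {ser_2} share detection line {la}; cannot fuse"
        )
    if dt < 0:
        raise PreconditionError(f"dt must be >= 0, got {dt}")
    d = dt * array.speed_px_s
    x, y = _case_point(la, lb, d, array.center)
    if array.mirror:
        x, y = y, x
    xi, yi = round_half_away(x), round_half_away(y)
    hi = array.image_size - 1
    cx, cy = min(max(xi, 0), hi), min(max(yi, 0), hi)
    point = (cx, cy)
    if with_flag:
        return point, (cx, cy) != (xi, yi)
    return point


def _check_sorted(events: Sequence[SensorEvent]) -> None:
    for prev, cur in zip(events, events[1:]):
        if (prev.timestamp, prev.sensor_id) > (cur.timestamp, cur.sensor_id):
            raise PreconditionError(
                "events must be sorted by timestamp (ties by ascending sensor id)"
            )


def select_signal(events: Sequence[SensorEvent], array: SensorArray) -> FusedSignal | None:
    """Pick the earliest cross-line trigger pair and fuse it.

    Scans ordered pairs ``(e_i, e_j)``, ``i < j``, in lexicographic
    order and returns the first whose sensors sit on distinct detection
    lines.  Returns ``None`` when no valid pair exists — a missed
    detection (e.g. all triggers on one line, or fewer than two).
    """
    _check_sorted(events)
    n = len(events)
    for i in range(n):
        for j in range(i + 1, n):
            if is_valid_pair(events[i].sensor_id, events[j].sensor_id):
                dt = events[j].timestamp - events[i].timestamp
                point, clamped = estimate_label_position(
                    events[i].sensor_id, events[j].sensor_id, dt, array, with_flag=True
                )
                return FusedSignal(
                    ser_1=events[i].sensor_id,
                    ser_2=events[j].sensor_id,
                    dt=dt,
                    point=point,
                    clamped=clamped,
                )
    return None


def load_events(path: str | Path) -> list[SensorEvent]:
    """Read a JSON event stream ``[{"sensor": int, "t": seconds}, ...]``.

    Events are returned sorted by ``(timestamp, sensor_id)``, the order
    :func:`select_signal` requires.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise PreconditionError("event stream must be a JSON array")
    events = [SensorEvent(sensor_id=e["sensor"], timestamp=e["t"]) for e in raw]
    return sorted(events, key=lambda e: (e.timestamp, e.sensor_id))


def dump_events(events: Iterable[SensorEvent], path: str | Path) -> None:
    """Write an event stream as JSON ``[{"sensor": ..., "t": ...}, ...]``."""
    payload = [{"sensor": e.sensor_id, "t": e.timestamp} for e in events]
    Path(path).write_text(json.dumps(payload, indent=1))
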