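"""Posture protocol definition for the four-stage supine/walk/stand/supine test.

The measurement protocol is a fixed sequence of timed postures:
5 min supine baseline, 10 min corridor walking, 5 min quiet standing and
5 min supine recovery.  Segment intervals are half-open ``[start, end)`` in
seconds from protocol start.
"""

from __future__ import annotations

from dataclasses import dataclass, field


SEGMENT_NAMES = ("supine_baseline", "walk", "stand", "supine_end")

#: transitions between adjacent postures, in protocol order, plus the
#: start-to-end contrast used for the "did it recover" comparison
ADJACENT_TRANSITIONS = (
    ("supine_baseline", "walk"),
    ("walk", "stand"),
    ("stand", "supine_end"),
    ("supine_baseline", "supine_end"),
)


@dataclass(frozen=True)
class ProtocolDefinition:
    """Ordered posture segments with durations in seconds."""

    segments: tuple[tuple[str, float], ...] = field(
        default=(
            ("supine_baseline", 300.0),
            ("walk", 600.0),
            ("stand", 300.0),
            ("supine_end", 300.0),
        )
    )

    def __post_init__(self) -> None:
        names = [name for name, _ in self.segments]
        if len(set(names)) != len(names):
            raise ValueError(f"segment names must be unique, got {names}")
        for name, dur in self.segments:
            if dur <= 0:
                raise ValueError(f"segment {name!r} has non-positive duration {dur}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.segments)

    @property
    def total_duration(self) -> float:
        return float(sum(dur for _, dur in self.segments))

    def boundaries(self, start_time: float = 0.0) -> dict[str, tuple[float, float]]:
        """Half-open [start, end) interval of each segment, seconds."""
        out: dict[str, tuple[float, float]] = {}
        t = float(start_time)
        for name, dur in self.segments:
            out[name] = (t, t + dur)
            t += dur
        return out

    def sync_event_times(self, n_events: int = 6, start_time: float = 0.0) -> list[float]:
        """True (protocol-clock) instants of the shared synchronization events.

        Events are spread over the test from 10 s after start to 10 s before
        the end, mimicking marks entered on both acquisition laptops at the
        same moments.
        """
        import numpy as np

        lo = start_time + 10.0
        hi = start_time + self.total_duration - 10.0
        return [float(t) for t in np.linspace(lo, hi, n_events)]


DEFAULT_PROTOCOL = ProtocolDefinition()
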