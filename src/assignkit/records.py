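"""Lightweight peak records.

A :class:`PeakRecord` is the flat, serialisable form of a peak used by the
picker, the simulator, the aligner and the CSV reader/writer: an
N-dimensional ppm position, a height, and per-dimension lists of NmrAtom
PIDs (empty when unassigned).  The in-project :class:`~assignkit.model.Peak`
objects are built from these on import.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class PeakRecord:
    serial: int
    position: tuple[float, ...]
    height: float
    assignments: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        self.position = tuple(float(v) for v in self.position)
        if not self.assignments:
            self.assignments = tuple(() for _ in self.position)
        else:
            self.assignments = tuple(tuple(a) for a in self.assignments)
        if len(self.assignments) != len(self.position):
            raise ValueError("assignments must have one entry per dimension")

    @property
    def dimensionCount(self) -> int:
        return len(self.position)

    def translated(self, offsets) -> "PeakRecord":
        if len(offsets) != len(self.position):
            raise ValueError("offset dimensionality mismatch")
        pos = tuple(p + o for p, o in zip(self.position, offsets))
        return replace(self, position=pos)
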