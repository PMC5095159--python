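"""Project IDs.

Every object in a project is addressable by a PID — a short string of the
form ``TYPE:part1.part2...`` where ``TYPE`` is a two-letter tag for the
object kind and the dot-separated parts locate the object within its parent
chain, much like a URL path.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import PidError

__all__ = ["Pid"]

#: Registered type codes (kind -> code).  Skeletal child kinds get codes too
#: so every contained object is PID-addressable.
TYPE_CODES = {
    "Spectrum": "SP", "PeakList": "PL", "Peak": "PK",
    "Chain": "MC", "Residue": "MR", "Atom": "MA",
    "NmrChain": "NC", "NmrResidue": "NR", "NmrAtom": "NA",
    "ChemicalShiftList": "CL", "ChemicalShift": "CS",
    "SpectrumGroup": "SG", "Sample": "SA", "SampleComponent": "SC",
    "Substance": "SU", "Complex": "CX", "DataSet": "DS",
    "StructureEnsemble": "SE", "Note": "NO",
    "RestraintList": "RL", "Restraint": "RE", "Model": "MO",
    "Data": "DA", "CalculationStep": "CT",
}

_FORBIDDEN = {".", ":"}


@dataclass(frozen=True)
class Pid:
    typeCode: str
    keyParts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (2 <= len(self.typeCode) <= 3) or not self.typeCode.isalpha():
            raise PidError(f"bad PID type code: {self.typeCode!r}")
        if not self.keyParts:
            raise PidError("PID needs at least one key part")
        for part in self.keyParts:
            if not part or any(c in part for c in _FORBIDDEN):
                raise PidError(f"bad PID key part: {part!r}")

    def __str__(self) -> str:
        return f"{self.typeCode}:{'.'.join(self.keyParts)}"

    @classmethod
    def parse(cls, text: str) -> "Pid":
        if not isinstance(text, str) or ":" not in text:
            raise PidError(f"malformed PID: {text!r}")
        code, _, rest = text.partition(":")
        if not rest:
            raise PidError(f"malformed PID (empty key): {text!r}")
        return cls(code, tuple(rest.split(".")))
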