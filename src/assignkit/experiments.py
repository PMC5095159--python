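"""Experiment types: axis codes and expected peak patterns.

An axis code names the nucleus of a spectrum dimension plus, in lowercase,
the covalently bonded partner that defines the magnetisation transfer: the
two dimensions of a [15N,1H]-HSQC are "Hn" and "Nh".  Two sets of axis codes
are compatible — i.e. the spectra can share a display/strip — when some
pairing matches each code to one with the same leading nucleus letter and,
where both codes carry lowercase suffixes, the same suffix.

An experiment type additionally declares which atoms are observable: its
expected peak pattern is a list of (atom name, residue offset, sign) tuples
relative to the spin system anchoring the peak (amide H/N for the
triple-resonance set).  A small registry of eight common types is provided.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import AssignKitError
from .model import NmrAtom, NmrResidue

__all__ = [
    "PatternEntry", "ExperimentType", "EXPERIMENT_TYPES", "getExperimentType",
    "axisCodesCompatible", "expectedPeaks",
]


class ExperimentRegistryError(AssignKitError, KeyError):
    def __str__(self) -> str:
        return str(self.args[0]) if self.args else ""


@dataclass(frozen=True)
class PatternEntry:
    atomName: str
    offset: int          # 0 = intra-residue, -1 = preceding residue
    sign: int            # +1 or -1 expected peak sign


@dataclass(frozen=True)
class ExperimentType:
    name: str
    axisCodes: tuple[str, ...]
    #: axes whose position is pinned to a specific intra-residue atom
    anchorAtoms: tuple[tuple[str, str], ...]     # (axisCode, atomName)
    #: axis populated by the expected pattern (None for 2D fingerprints)
    patternAxis: str | None
    expectedPattern: tuple[PatternEntry, ...]

    @property
    def dimensionCount(self) -> int:
        return len(self.axisCodes)

    def anchorAtomForAxis(self, axisCode: str) -> str | None:
        return dict(self.anchorAtoms).get(axisCode)


def _et(name, axes, anchors, patternAxis, pattern):
    return ExperimentType(
        name, tuple(axes), tuple(anchors), patternAxis,
        tuple(PatternEntry(a, o, s) for a, o, s in pattern))


_HN = (("Hn", "H"), ("Nh", "N"))

EXPERIMENT_TYPES: dict[str, ExperimentType] = {
    et.name: et for et in [
        _et("hsqc15N", ("Hn", "Nh"), _HN, None,
            [("H", 0, +1), ("N", 0, +1)]),
        # CH fingerprint: one peak per bonded (HA,CA) and (HB,CB) pair
        _et("hsqc13C", ("Hc", "Ch"), (), None,
            [("HA", 0, +1), ("CA", 0, +1), ("HB", 0, +1), ("CB", 0, +1)]),
        _et("hnco", ("Hn", "Nh", "C"), _HN, "C",
            [("C", -1, +1)]),
        _et("hncaco", ("Hn", "Nh", "C"), _HN, "C",
            [("C", 0, +1), ("C", -1, +1)]),
        _et("hnca", ("Hn", "Nh", "C"), _HN, "C",
            [("CA", 0, +1), ("CA", -1, +1)]),
        _et("hncoca", ("Hn", "Nh", "C"), _HN, "C",
            [("CA", -1, +1)]),
        _et("hncacb", ("Hn", "Nh", "C"), _HN, "C",
            [("CA", 0, +1), ("CB", 0, -1), ("CA", -1, +1), ("CB", -1, -1)]),
        _et("cbcaconh", ("Hn", "Nh", "C"), _HN, "C",
            [("CA", -1, +1), ("CB", -1, +1)]),
    ]
}


def getExperimentType(name: str) -> ExperimentType:
    try:
        return EXPERIMENT_TYPES[name]
    except KeyError:
        known = ", ".join(sorted(EXPERIMENT_TYPES))
        raise ExperimentRegistryError(
            f"unknown experiment type {name!r} (registered: {known})") from None


def _codesMatch(a: str, b: str) -> bool:
    if not a or not b or a[0] != b[0]:
        return False
    sa, sb = a[1:], b[1:]
    if sa and sa.islower() and sb and sb.islower():
        return sa == sb
    return True


def axisCodesCompatible(a, b) -> tuple[bool, tuple[int, ...] | None]:
    """Whether axis-code lists can be overlaid, and the matching permutation.

    Returns ``(True, perm)`` with ``perm[i]`` the index into ``b`` paired
    with ``a[i]``, or ``(False, None)``.  Dimension counts must agree.
    """
    a, b = tuple(a), tuple(b)
    if len(a) != len(b):
        return False, None
    for perm in itertools.permutations(range(len(b))):
        if all(_codesMatch(a[i], b[j]) for i, j in enumerate(perm)):
            return True, perm
    return False, None


def expectedPeaks(expType: ExperimentType | str, nmrResidue: NmrResidue
                  ) -> list[tuple[NmrAtom, int, int]]:
    """Instantiate an experiment's expected pattern against an NmrResidue.

    Offset −1 entries are realised on the residue's "-1" offset NmrResidue
    (created on demand).  Returns (NmrAtom, offset, sign) tuples.
    """
    if isinstance(expType, str):
        expType = getExperimentType(expType)
    out = []
    for entry in expType.expectedPattern:
        target = (nmrResidue if entry.offset == 0
                  else nmrResidue.fetchOffsetNmrResidue(entry.offset))
        out.append((target.fetchNmrAtom(entry.atomName), entry.offset, entry.sign))
    return out
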