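"""The hierarchical project data model and its assignment semantics.

A :class:`Project` owns eleven kinds of top-level object; seven of those own
children of their own.  Two parallel hierarchies carry the science:

* the molecule side — Chain > Residue > Atom — whose names follow the NEF
  naming rules (integer sequence codes, upper-case three-letter residue
  types, upper-case atom names), and
* the NMR side — NmrChain > NmrResidue > NmrAtom — whose names are free.

An NMR-side object is *assigned* exactly when its names match a molecule-side
object: an NmrResidue whose NmrChain is named like a Chain and whose
sequenceCode/residueType match a Residue of that Chain is assigned to it.
The link is dynamic — it is recomputed from names, never stored.

Unassigned NmrResidues carry serial codes ("@13") issued from a single
project-wide counter; an *offset* NmrResidue ("@13-1") holds the resonances
observed at a sequence offset (here −1) relative to its main NmrResidue and
renames together with it.  A *connected stretch* is an NmrChain flagged
``isConnected`` whose residue order is meaningful (sequential neighbours).
"""
from __future__ import annotations

import math
import re
from typing import Iterable, Optional

from .errors import ConflictError, PidLookupError, TypeMismatchError
from .pid import TYPE_CODES, Pid

__all__ = [
    "Project", "Spectrum", "PeakList", "Peak", "Chain", "Residue", "Atom",
    "NmrChain", "NmrResidue", "NmrAtom", "ChemicalShiftList", "ChemicalShift",
    "makePid", "resolvePid", "connectStretch", "updateShifts",
    "DEFAULT_NMRCHAIN_NAME",
]

DEFAULT_NMRCHAIN_NAME = "@-"

_OFFSET_RE = re.compile(r"^(?P<base>.+?)(?P<offset>[+-]\d+)$")


class _ModelObject:
    """Shared PID machinery; subclasses define ``className`` and ``_key``."""

    className: str = ""
    #: child kinds, for hierarchy introspection
    childClasses: tuple[type, ...] = ()

    @property
    def pid(self) -> Pid:
        return Pid(TYPE_CODES[self.className], tuple(self._key()))

    def _key(self) -> list[str]:
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<{self.className} {self.pid}>"


# --------------------------------------------------------------------------
# Molecule side
# --------------------------------------------------------------------------

class Atom(_ModelObject):
    className = "Atom"

    def __init__(self, residue: "Residue", name: str):
        self.residue = residue
        self.name = name

    def _key(self) -> list[str]:
        return self.residue._key() + [self.name]


class Residue(_ModelObject):
    className = "Residue"
    childClasses = (Atom,)

    def __init__(self, chain: "Chain", sequenceCode: str, residueType: str):
        self.chain = chain
        self.sequenceCode = sequenceCode
        self.residueType = residueType
        self.atoms: list[Atom] = []

    def _key(self) -> list[str]:
        return [self.chain.code, self.sequenceCode, self.residueType]

    def newAtom(self, name: str) -> Atom:
        if any(a.name == name for a in self.atoms):
            raise ConflictError(f"atom {name} already exists in {self.pid}")
        atom = Atom(self, name)
        self.atoms.append(atom)
        return atom

    def getAtom(self, name: str) -> Optional[Atom]:
        return next((a for a in self.atoms if a.name == name), None)

    @property
    def index(self) -> int:
        return self.chain.residues.index(self)


class Chain(_ModelObject):
    className = "Chain"
    childClasses = (Residue,)

    def __init__(self, project: "Project", code: str):
        self.project = project
        self.code = code
        self.residues: list[Residue] = []

    def _key(self) -> list[str]:
        return [self.code]

    def newResidue(self, sequenceCode: str, residueType: str) -> Residue:
        if self.getResidue(sequenceCode) is not None:
            raise ConflictError(
                f"residue {sequenceCode} already exists in chain {self.code}")
        if self.residues and int(sequenceCode) <= int(self.residues[-1].sequenceCode):
            raise ConflictError("residue sequence codes must be ascending")
        residue = Residue(self, sequenceCode, residueType.upper())
        self.residues.append(residue)
        return residue

    def getResidue(self, sequenceCode: str) -> Optional[Residue]:
        return next((r for r in self.residues if r.sequenceCode == sequenceCode), None)


# --------------------------------------------------------------------------
# NMR side
# --------------------------------------------------------------------------

class NmrAtom(_ModelObject):
    className = "NmrAtom"

    def __init__(self, nmrResidue: "NmrResidue", name: str):
        self.nmrResidue = nmrResidue
        self.name = name

    def _key(self) -> list[str]:
        return self.nmrResidue._key() + [self.name]

    @property
    def isotopeLetter(self) -> str:
        """Leading nucleus letter of the name (H, N, C, ...)."""
        return self.name[:1]


class NmrResidue(_ModelObject):
    className = "NmrResidue"
    childClasses = (NmrAtom,)

    def __init__(self, nmrChain: "NmrChain", sequenceCode: str,
                 residueType: str = "", offset: Optional[int] = None,
                 mainResidue: Optional["NmrResidue"] = None):
        self.nmrChain = nmrChain
        self.sequenceCode = sequenceCode
        self.residueType = residueType.upper() if residueType else ""
        self.offset = offset
        self.mainResidue = mainResidue
        self.offsetNmrResidues: list[NmrResidue] = []
        self.nmrAtoms: list[NmrAtom] = []

    def _key(self) -> list[str]:
        parts = [self.nmrChain.name, self.sequenceCode]
        if self.residueType:
            parts.append(self.residueType)
        return parts

    # -- atoms ------------------------------------------------------------

    def fetchNmrAtom(self, name: str) -> NmrAtom:
        atom = self.getNmrAtom(name)
        if atom is None:
            atom = NmrAtom(self, name)
            self.nmrAtoms.append(atom)
        return atom

    def getNmrAtom(self, name: str) -> Optional[NmrAtom]:
        return next((a for a in self.nmrAtoms if a.name == name), None)

    # -- offsets ----------------------------------------------------------

    def fetchOffsetNmrResidue(self, offset: int) -> "NmrResidue":
        """Return (creating if needed) the NmrResidue at a sequence offset.

        Idempotent; the child is named ``<mainCode><offset:+d>`` (e.g.
        "@13-1") and renames with its main residue.
        """
        if self.offset is not None:
            raise ValueError("cannot take an offset of an offset NmrResidue")
        if offset == 0:
            raise ValueError("offset must be non-zero")
        for child in self.offsetNmrResidues:
            if child.offset == offset:
                return child
        code = f"{self.sequenceCode}{offset:+d}"
        child = NmrResidue(self.nmrChain, code, offset=offset, mainResidue=self)
        self.nmrChain.nmrResidues.append(child)
        self.offsetNmrResidues.append(child)
        return child

    # -- assignment semantics --------------------------------------------

    @property
    def residue(self) -> Optional[Residue]:
        """The molecular Residue this NmrResidue's names match, if any."""
        chain = self.nmrChain.project.getChain(self.nmrChain.name)
        if chain is None:
            return None
        residue = chain.getResidue(self.sequenceCode)
        if residue is None or residue.residueType != self.residueType:
            return None
        return residue

    @property
    def isAssigned(self) -> bool:
        return self.residue is not None

    def assignTo(self, residue: Residue) -> "NmrResidue":
        return assignNmrResidue(self, residue)

    def deassign(self) -> "NmrResidue":
        return deassign(self)


class NmrChain(_ModelObject):
    className = "NmrChain"
    childClasses = (NmrResidue,)

    def __init__(self, project: "Project", name: str, isConnected: bool = False):
        self.project = project
        self.name = name
        self.isConnected = isConnected
        self.nmrResidues: list[NmrResidue] = []

    def _key(self) -> list[str]:
        return [self.name]

    @property
    def mainNmrResidues(self) -> list[NmrResidue]:
        """Residues that are not offset children, in stored (stretch) order."""
        return [r for r in self.nmrResidues if r.offset is None]

    def newNmrResidue(self, sequenceCode: Optional[str] = None,
                      residueType: str = "") -> NmrResidue:
        """Create an NmrResidue, issuing a fresh serial code when none given.

        A sequenceCode of the form ``<base><±n>`` whose base already exists in
        this chain creates/fetches the corresponding offset NmrResidue.
        """
        project = self.project
        if sequenceCode is None:
            sequenceCode = f"@{project._nextSerial()}"
        else:
            m = _OFFSET_RE.match(sequenceCode)
            if m:
                base = self.getNmrResidue(m.group("base"))
                if base is not None and base.offset is None:
                    child = base.fetchOffsetNmrResidue(int(m.group("offset")))
                    if residueType:
                        child.residueType = residueType.upper()
                    return child
        if self.getNmrResidue(sequenceCode) is not None:
            raise ConflictError(
                f"NmrResidue {sequenceCode} already exists in NmrChain {self.name}")
        residue = NmrResidue(self, sequenceCode, residueType)
        self.nmrResidues.append(residue)
        return residue

    def getNmrResidue(self, sequenceCode: str) -> Optional[NmrResidue]:
        return next((r for r in self.nmrResidues
                     if r.sequenceCode == sequenceCode), None)

    def fetchNmrResidue(self, sequenceCode: str, residueType: str = "") -> NmrResidue:
        existing = self.getNmrResidue(sequenceCode)
        if existing is not None:
            return existing
        return self.newNmrResidue(sequenceCode, residueType)

    def _remove(self, nmrResidue: NmrResidue) -> None:
        self.nmrResidues.remove(nmrResidue)

    def _adopt(self, nmrResidue: NmrResidue, index: Optional[int] = None) -> None:
        if self.getNmrResidue(nmrResidue.sequenceCode) is not None:
            raise ConflictError(
                f"NmrResidue {nmrResidue.sequenceCode} already in NmrChain {self.name}")
        nmrResidue.nmrChain = self
        if index is None:
            self.nmrResidues.append(nmrResidue)
        else:
            self.nmrResidues.insert(index, nmrResidue)


# --------------------------------------------------------------------------
# Shifts
# --------------------------------------------------------------------------

class ChemicalShift(_ModelObject):
    className = "ChemicalShift"

    def __init__(self, shiftList: "ChemicalShiftList", nmrAtom: NmrAtom,
                 value: float, sd: float = 0.0, peakCount: int = 0):
        self.shiftList = shiftList
        self.nmrAtom = nmrAtom
        self.value = value
        self.sd = sd
        self.peakCount = peakCount

    def _key(self) -> list[str]:
        return [self.shiftList.name] + self.nmrAtom._key()


class ChemicalShiftList(_ModelObject):
    className = "ChemicalShiftList"
    childClasses = (ChemicalShift,)

    def __init__(self, project: "Project", name: str):
        self.project = project
        self.name = name
        self.shifts: list[ChemicalShift] = []

    def _key(self) -> list[str]:
        return [self.name]

    def getShift(self, nmrAtom: NmrAtom) -> Optional[ChemicalShift]:
        return next((s for s in self.shifts if s.nmrAtom is nmrAtom), None)

    def shiftValue(self, nmrAtom: Optional[NmrAtom]) -> Optional[float]:
        if nmrAtom is None:
            return None
        shift = self.getShift(nmrAtom)
        return None if shift is None else shift.value

    def setShift(self, nmrAtom: NmrAtom, value: float, sd: float = 0.0,
                 peakCount: int = 1) -> ChemicalShift:
        """Set or overwrite the shift for an NmrAtom (one entry per atom)."""
        existing = self.getShift(nmrAtom)
        if existing is not None:
            existing.value, existing.sd, existing.peakCount = value, sd, peakCount
            return existing
        shift = ChemicalShift(self, nmrAtom, value, sd, peakCount)
        self.shifts.append(shift)
        return shift


def updateShifts(shiftList: ChemicalShiftList, peaks: Iterable["Peak"]) -> ChemicalShiftList:
    """Recompute a shift list from assigned peak positions.

    For every NmrAtom appearing in any peak dimension the shift value is the
    unweighted mean of the assigned positions, sd their sample standard
    deviation (0 for a single observation) and peakCount the number of
    contributing peak dimensions.  Atoms with no contributing peaks are
    dropped; the result is independent of peak order.
    """
    observations: dict[NmrAtom, list[float]] = {}
    for peak in peaks:
        for dim, atoms in enumerate(peak.dimensionNmrAtoms):
            for atom in atoms:
                observations.setdefault(atom, []).append(peak.position[dim])
    shiftList.shifts = []
    for atom in sorted(observations, key=lambda a: str(a.pid)):
        values = observations[atom]
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
        shiftList.shifts.append(ChemicalShift(shiftList, atom, mean, sd, n))
    return shiftList


# --------------------------------------------------------------------------
# Spectra and peaks
# --------------------------------------------------------------------------

class Peak(_ModelObject):
    className = "Peak"

    def __init__(self, peakList: "PeakList", serial: int,
                 position: tuple[float, ...], height: float,
                 dimensionNmrAtoms: Optional[list[list[NmrAtom]]] = None):
        self.peakList = peakList
        self.serial = serial
        self.position = tuple(position)
        self.height = height
        self.dimensionNmrAtoms: list[list[NmrAtom]] = (
            dimensionNmrAtoms if dimensionNmrAtoms is not None
            else [[] for _ in position])

    def _key(self) -> list[str]:
        return self.peakList._key() + [str(self.serial)]


class PeakList(_ModelObject):
    className = "PeakList"
    childClasses = (Peak,)

    def __init__(self, spectrum: "Spectrum", serial: int):
        self.spectrum = spectrum
        self.serial = serial
        self.peaks: list[Peak] = []

    def _key(self) -> list[str]:
        return [self.spectrum.name, str(self.serial)]

    def newPeak(self, position: tuple[float, ...], height: float = 0.0,
                dimensionNmrAtoms: Optional[list[list[NmrAtom]]] = None) -> Peak:
        serial = max((p.serial for p in self.peaks), default=0) + 1
        peak = Peak(self, serial, position, height, dimensionNmrAtoms)
        self.peaks.append(peak)
        return peak

    def getPeak(self, serial: int) -> Optional[Peak]:
        return next((p for p in self.peaks if p.serial == serial), None)


class Spectrum(_ModelObject):
    className = "Spectrum"
    childClasses = (PeakList,)

    def __init__(self, project: "Project", name: str,
                 axisCodes: tuple[str, ...] = ()):
        self.project = project
        self.name = name
        self.axisCodes = tuple(axisCodes)
        self.peakLists: list[PeakList] = []

    def _key(self) -> list[str]:
        return [self.name]

    @property
    def dimensionCount(self) -> int:
        return len(self.axisCodes)

    def newPeakList(self) -> PeakList:
        serial = max((pl.serial for pl in self.peakLists), default=0) + 1
        peakList = PeakList(self, serial)
        self.peakLists.append(peakList)
        return peakList

    def getPeakList(self, serial: int) -> Optional[PeakList]:
        return next((pl for pl in self.peakLists if pl.serial == serial), None)


# --------------------------------------------------------------------------
# Skeletal kinds (name + parent links only)
# --------------------------------------------------------------------------

def _skeletal(className_, childClasses_=()):
    class _Skeletal(_ModelObject):
        className = className_
        childClasses = tuple(childClasses_)

        def __init__(self, parent, name: str):
            self.parent = parent
            self.name = name
            self.children: list[_ModelObject] = []

        def _key(self) -> list[str]:
            parentKey = self.parent._key() if isinstance(self.parent, _ModelObject) else []
            return parentKey + [self.name]

        def newChild(self, cls, name: str):
            child = cls(self, name)
            self.children.append(child)
            return child

    _Skeletal.__name__ = className_
    return _Skeletal


Restraint = _skeletal("Restraint")
RestraintList = _skeletal("RestraintList", (Restraint,))
Data = _skeletal("Data")
CalculationStep = _skeletal("CalculationStep")
Model = _skeletal("Model")
SampleComponent = _skeletal("SampleComponent")
SpectrumGroup = _skeletal("SpectrumGroup")
Substance = _skeletal("Substance")
Complex = _skeletal("Complex")
Note = _skeletal("Note")
Sample = _skeletal("Sample", (SampleComponent,))
DataSet = _skeletal("DataSet", (RestraintList, Data, CalculationStep))
StructureEnsemble = _skeletal("StructureEnsemble", (Model,))


#: The eleven top-level object kinds, in sidebar order.
TOP_LEVEL_CLASSES: tuple[type, ...] = (
    Spectrum, SpectrumGroup, Sample, Substance, Chain, Complex,
    NmrChain, ChemicalShiftList, DataSet, StructureEnsemble, Note,
)


# --------------------------------------------------------------------------
# Project
# --------------------------------------------------------------------------

class Project:
    """Root container; owns the eleven top-level collections.

    All contained objects are reachable via :meth:`getByPid`.  A single
    project-wide counter issues serial NmrResidue codes ("@1", "@2", ...);
    connected stretches are NmrChains named "#1", "#2", ... .
    """

    def __init__(self, name: str = "project"):
        self.name = name
        self.spectra: list[Spectrum] = []
        self.spectrumGroups: list[SpectrumGroup] = []
        self.samples: list[Sample] = []
        self.substances: list[Substance] = []
        self.chains: list[Chain] = []
        self.complexes: list[Complex] = []
        self.nmrChains: list[NmrChain] = []
        self.chemicalShiftLists: list[ChemicalShiftList] = []
        self.dataSets: list[DataSet] = []
        self.structureEnsembles: list[StructureEnsemble] = []
        self.notes: list[Note] = []
        self._serial = 0
        self._stretchSerial = 0
        #: opaque saveframe texts preserved across NEF round-trips
        self._opaqueSaveframes: list[str] = []

    # -- serials ----------------------------------------------------------

    def _nextSerial(self) -> int:
        self._serial += 1
        return self._serial

    def _nextStretchSerial(self) -> int:
        self._stretchSerial += 1
        return self._stretchSerial

    # -- creation / fetch --------------------------------------------------

    def newSpectrum(self, name: str, axisCodes: tuple[str, ...] = ()) -> Spectrum:
        if self.getSpectrum(name) is not None:
            raise ConflictError(f"spectrum {name} already exists")
        spectrum = Spectrum(self, name, axisCodes)
        self.spectra.append(spectrum)
        return spectrum

    def getSpectrum(self, name: str) -> Optional[Spectrum]:
        return next((s for s in self.spectra if s.name == name), None)

    def newChain(self, code: str) -> Chain:
        if self.getChain(code) is not None:
            raise ConflictError(f"chain {code} already exists")
        chain = Chain(self, code)
        self.chains.append(chain)
        return chain

    def getChain(self, code: str) -> Optional[Chain]:
        return next((c for c in self.chains if c.code == code), None)

    def newNmrChain(self, name: Optional[str] = None,
                    isConnected: bool = False) -> NmrChain:
        if name is None:
            name = f"#{self._nextStretchSerial()}"
            isConnected = True
        if self.getNmrChain(name) is not None:
            raise ConflictError(f"NmrChain {name} already exists")
        chain = NmrChain(self, name, isConnected)
        self.nmrChains.append(chain)
        return chain

    def fetchNmrChain(self, name: str = DEFAULT_NMRCHAIN_NAME) -> NmrChain:
        existing = self.getNmrChain(name)
        return existing if existing is not None else self.newNmrChain(name)

    def getNmrChain(self, name: str) -> Optional[NmrChain]:
        return next((c for c in self.nmrChains if c.name == name), None)

    def newChemicalShiftList(self, name: str = "default") -> ChemicalShiftList:
        if self.getChemicalShiftList(name) is not None:
            raise ConflictError(f"shift list {name} already exists")
        shiftList = ChemicalShiftList(self, name)
        self.chemicalShiftLists.append(shiftList)
        return shiftList

    def getChemicalShiftList(self, name: str) -> Optional[ChemicalShiftList]:
        return next((s for s in self.chemicalShiftLists if s.name == name), None)

    def newSpectrumGroup(self, name: str) -> SpectrumGroup:
        obj = SpectrumGroup(self, name); self.spectrumGroups.append(obj); return obj

    def newSample(self, name: str) -> Sample:
        obj = Sample(self, name); self.samples.append(obj); return obj

    def newSubstance(self, name: str) -> Substance:
        obj = Substance(self, name); self.substances.append(obj); return obj

    def newComplex(self, name: str) -> Complex:
        obj = Complex(self, name); self.complexes.append(obj); return obj

    def newDataSet(self, name: str) -> DataSet:
        obj = DataSet(self, name); self.dataSets.append(obj); return obj

    def newStructureEnsemble(self, name: str) -> StructureEnsemble:
        obj = StructureEnsemble(self, name); self.structureEnsembles.append(obj); return obj

    def newNote(self, name: str) -> Note:
        obj = Note(self, name); self.notes.append(obj); return obj

    # -- PID resolution ----------------------------------------------------

    def getByPid(self, pid) -> _ModelObject:
        return resolvePid(self, pid)

    def _allObjects(self) -> list[_ModelObject]:
        """Every PID-addressable object in the project."""
        out: list[_ModelObject] = []
        for spectrum in self.spectra:
            out.append(spectrum)
            for pl in spectrum.peakLists:
                out.append(pl)
                out.extend(pl.peaks)
        for chain in self.chains:
            out.append(chain)
            for res in chain.residues:
                out.append(res)
                out.extend(res.atoms)
        for nmrChain in self.nmrChains:
            out.append(nmrChain)
            for res in nmrChain.nmrResidues:
                out.append(res)
                out.extend(res.nmrAtoms)
        for shiftList in self.chemicalShiftLists:
            out.append(shiftList)
            out.extend(shiftList.shifts)
        for collection in (self.spectrumGroups, self.samples, self.substances,
                           self.complexes, self.dataSets,
                           self.structureEnsembles, self.notes):
            for obj in collection:
                out.append(obj)
                stack = list(getattr(obj, "children", []))
                while stack:
                    child = stack.pop()
                    out.append(child)
                    stack.extend(getattr(child, "children", []))
        return out


def makePid(obj: _ModelObject) -> Pid:
    return obj.pid


def resolvePid(project: Project, pid) -> _ModelObject:
    """Resolve a PID (object or string) to the object that produced it."""
    if isinstance(pid, str):
        pid = Pid.parse(pid)
    code, parts = pid.typeCode, pid.keyParts

    def fail() -> PidLookupError:
        return PidLookupError(f"no object for PID {pid}")

    def need(obj):
        if obj is None:
            raise fail()
        return obj

    if code == "SP":
        return need(len(parts) == 1 and project.getSpectrum(parts[0]) or None)
    if code == "PL":
        if len(parts) != 2:
            raise fail()
        spectrum = need(project.getSpectrum(parts[0]))
        return need(spectrum.getPeakList(_toInt(parts[1], fail)))
    if code == "PK":
        if len(parts) != 3:
            raise fail()
        spectrum = need(project.getSpectrum(parts[0]))
        peakList = need(spectrum.getPeakList(_toInt(parts[1], fail)))
        return need(peakList.getPeak(_toInt(parts[2], fail)))
    if code == "MC":
        return need(len(parts) == 1 and project.getChain(parts[0]) or None)
    if code in ("MR", "MA"):
        n = 3 if code == "MR" else 4
        if len(parts) != n:
            raise fail()
        chain = need(project.getChain(parts[0]))
        residue = need(chain.getResidue(parts[1]))
        if residue.residueType != parts[2]:
            raise fail()
        if code == "MR":
            return residue
        return need(residue.getAtom(parts[3]))
    if code == "NC":
        return need(len(parts) == 1 and project.getNmrChain(parts[0]) or None)
    if code == "NR":
        return _resolveNmrResidue(project, parts, fail)
    if code == "NA":
        if len(parts) < 3:
            raise fail()
        residue = _resolveNmrResidue(project, parts[:-1], fail)
        return need(residue.getNmrAtom(parts[-1]))
    if code == "CL":
        return need(len(parts) == 1 and project.getChemicalShiftList(parts[0]) or None)
    if code == "CS":
        if len(parts) < 4:
            raise fail()
        shiftList = need(project.getChemicalShiftList(parts[0]))
        atom = resolvePid(project, Pid("NA", tuple(parts[1:])))
        return need(shiftList.getShift(atom))
    # skeletal kinds: linear search by key
    for obj in project._allObjects():
        if TYPE_CODES.get(obj.className) == code and tuple(obj._key()) == tuple(parts):
            return obj
    raise fail()


def _toInt(text: str, fail) -> int:
    try:
        return int(text)
    except ValueError:
        raise fail() from None


def _resolveNmrResidue(project: Project, parts, fail) -> NmrResidue:
    if len(parts) not in (2, 3):
        raise fail()
    nmrChain = project.getNmrChain(parts[0])
    if nmrChain is None:
        raise fail()
    residue = nmrChain.getNmrResidue(parts[1])
    if residue is None:
        raise fail()
    if len(parts) == 3 and residue.residueType != parts[2]:
        raise fail()
    return residue


# --------------------------------------------------------------------------
# Assignment operations
# --------------------------------------------------------------------------

def assignNmrResidue(nmrResidue: NmrResidue, residue: Residue) -> NmrResidue:
    """Assign an NmrResidue to a molecular Residue by renaming.

    The NmrResidue moves to the NmrChain named after the Residue's Chain and
    takes the Residue's sequence code and type, so the name-match predicate
    holds afterwards.  Offset children rename with it.  Conflicts (target
    already claimed, incompatible residue type) raise and leave everything
    untouched.
    """
    if nmrResidue.offset is not None:
        raise ValueError("assign the main NmrResidue, not an offset child")
    project = nmrResidue.nmrChain.project
    for chain in project.nmrChains:
        for other in chain.nmrResidues:
            if other is not nmrResidue and other.residue is residue:
                raise ConflictError(f"{residue.pid} is already assigned to {other.pid}")
    if nmrResidue.residueType and nmrResidue.residueType != residue.residueType:
        raise TypeMismatchError(
            f"residue type {nmrResidue.residueType} does not match "
            f"{residue.residueType} of {residue.pid}")
    target = project.fetchNmrChain(residue.chain.code)
    _moveNmrResidue(nmrResidue, target, residue.sequenceCode, residue.residueType)
    return nmrResidue


def deassign(nmrResidue: NmrResidue) -> NmrResidue:
    """Drop the assignment: issue a fresh serial code in the default chain."""
    if nmrResidue.offset is not None:
        raise ValueError("deassign the main NmrResidue, not an offset child")
    project = nmrResidue.nmrChain.project
    target = project.fetchNmrChain(DEFAULT_NMRCHAIN_NAME)
    code = f"@{project._nextSerial()}"
    _moveNmrResidue(nmrResidue, target, code, nmrResidue.residueType)
    return nmrResidue


def _moveNmrResidue(nmrResidue: NmrResidue, target: NmrChain,
                    sequenceCode: str, residueType: str) -> None:
    source = nmrResidue.nmrChain
    source._remove(nmrResidue)
    nmrResidue.sequenceCode = sequenceCode
    nmrResidue.residueType = residueType.upper() if residueType else ""
    try:
        target._adopt(nmrResidue)
    except ConflictError:
        source.nmrResidues.append(nmrResidue)
        raise
    for child in nmrResidue.offsetNmrResidues:
        child.nmrChain._remove(child)
        child.sequenceCode = f"{sequenceCode}{child.offset:+d}"
        target._adopt(child)


def connectStretch(a: NmrResidue, b: NmrResidue, direction: str) -> NmrChain:
    """Connect two NmrResidues into (or extending) a connected stretch.

    direction "i_plus_1" makes ``b`` the sequential successor of ``a``;
    "i_minus_1" the predecessor.  Existing stretches are concatenated when
    the connection joins a tail to a head; anything else (same stretch,
    self-connection, non-terminal residues) is a conflict.
    """
    if direction not in ("i_plus_1", "i_minus_1"):
        raise ValueError(f"unknown direction {direction!r}")
    if a.offset is not None or b.offset is not None:
        raise ValueError("offset NmrResidues cannot form stretches")
    if a is b:
        raise ConflictError("cannot connect an NmrResidue to itself")
    pred, succ = (a, b) if direction == "i_plus_1" else (b, a)
    project = pred.nmrChain.project

    predChain = pred.nmrChain if pred.nmrChain.isConnected else None
    succChain = succ.nmrChain if succ.nmrChain.isConnected else None
    if predChain is not None and predChain is succChain:
        raise ConflictError("NmrResidues are already in the same connected stretch")
    if predChain is not None and predChain.mainNmrResidues[-1] is not pred:
        raise ConflictError(f"{pred.pid} is not the tail of its stretch")
    if succChain is not None and succChain.mainNmrResidues[0] is not succ:
        raise ConflictError(f"{succ.pid} is not the head of its stretch")

    if predChain is None and succChain is None:
        stretch = project.newNmrChain()
        _moveIntoStretch(pred, stretch)
        _moveIntoStretch(succ, stretch)
        return stretch
    if predChain is not None and succChain is None:
        _moveIntoStretch(succ, predChain)
        return predChain
    if predChain is None:
        _moveIntoStretch(pred, succChain, index=0)
        return succChain
    # concatenate two stretches: append all of succChain to predChain
    for residue in list(succChain.mainNmrResidues):
        _moveIntoStretch(residue, predChain)
    project.nmrChains.remove(succChain)
    return predChain


def _moveIntoStretch(nmrResidue: NmrResidue, stretch: NmrChain,
                     index: Optional[int] = None) -> None:
    source = nmrResidue.nmrChain
    source._remove(nmrResidue)
    try:
        stretch._adopt(nmrResidue, index)
    except ConflictError:
        source.nmrResidues.append(nmrResidue)
        raise
    for child in nmrResidue.offsetNmrResidues:
        child.nmrChain._remove(child)
        stretch._adopt(child)


def startStretch(nmrResidue: NmrResidue) -> NmrChain:
    """Put a single NmrResidue into a fresh connected stretch of length one."""
    if nmrResidue.nmrChain.isConnected:
        return nmrResidue.nmrChain
    stretch = nmrResidue.nmrChain.project.newNmrChain()
    _moveIntoStretch(nmrResidue, stretch)
    return stretch
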