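"""A minimal NEF dialect (STAR syntax subset).

Supported saveframe categories: ``nef_nmr_meta_data``, ``nef_molecular_system``
(loop ``_nef_sequence``), ``nef_chemical_shift_list`` (loop
``_nef_chemical_shift``) and ``nef_nmr_spectrum`` (dimension + ``_nef_peak``
loops), plus a ``ccpn_assignment``-style frame that serialises the NMR-side
hierarchy (NmrChain / NmrResidue / NmrAtom names and connected-stretch
order) so assignment state survives a round trip purely by name matching.

Any other ``nef_``-prefixed saveframe raises a named
:class:`~assignkit.errors.UnsupportedNefBlockError`; saveframes with other
prefixes are preserved verbatim and re-emitted on write, making
write -> read -> write byte-stable on the supported subset.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from ..errors import AssignKitError, UnsupportedNefBlockError
from ..model import Project

__all__ = ["readNef", "writeNef", "parseNefString", "projectToNefString"]

NULL = "."


class NefSyntaxError(AssignKitError, ValueError):
    pass


# --------------------------------------------------------------------------
# STAR tokenizing / generic frame parsing
# --------------------------------------------------------------------------

@dataclass
class Loop:
    columns: list[str]          # full tags, e.g. _nef_sequence.index
    rows: list[list[str]]

    @property
    def category(self) -> str:
        return self.columns[0].split(".")[0].lstrip("_")

    def get(self, row: list[str], column: str) -> str:
        tag = f"_{self.category}.{column}"
        return row[self.columns.index(tag)]

    def has(self, column: str) -> bool:
        return f"_{self.category}.{column}" in self.columns


@dataclass
class Saveframe:
    framecode: str
    items: dict[str, str] = field(default_factory=dict)   # tag tail -> value
    loops: list[Loop] = field(default_factory=list)
    rawText: str = ""

    @property
    def category(self) -> str:
        return self.items.get("sf_category", "")

    def loop(self, category: str) -> Loop | None:
        return next((lp for lp in self.loops if lp.category == category), None)


_TOKEN_RE = re.compile(r"""
    '(?P<sq>[^']*)'
  | "(?P<dq>[^"]*)"
  | (?P<bare>\S+)
""", re.VERBOSE)


def _tokenizeLine(line: str) -> list[str]:
    tokens = []
    for m in _TOKEN_RE.finditer(line):
        if m.group("bare") is not None:
            bare = m.group("bare")
            if bare.startswith("#"):
                break
            tokens.append(bare)
        elif m.group("sq") is not None:
            tokens.append(m.group("sq"))
        else:
            tokens.append(m.group("dq"))
    return tokens


def _splitFrames(text: str) -> tuple[str, list[str]]:
    """Split a STAR file into its data block name and raw saveframe texts."""
    dataName = None
    frames: list[str] = []
    current: list[str] | None = None
    inSemicolon = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith(";"):
            inSemicolon = not inSemicolon
        if current is not None:
            current.append(line)
            if not inSemicolon and stripped == "save_":
                frames.append("\n".join(current))
                current = None
            continue
        if inSemicolon or not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("data_"):
            dataName = stripped[len("data_"):]
        elif stripped.startswith("save_"):
            current = [line]
        elif stripped:
            raise NefSyntaxError(f"unexpected content outside saveframe: {stripped!r}")
    if current is not None:
        raise NefSyntaxError("unterminated saveframe")
    if dataName is None:
        raise NefSyntaxError("missing data_ block")
    return dataName, frames


def _parseFrame(raw: str) -> Saveframe:
    lines = raw.splitlines()
    framecode = lines[0].strip()[len("save_"):]
    frame = Saveframe(framecode, rawText=raw)
    tokens: list[str] = []
    inSemicolon = False
    semicolonBuf: list[str] = []
    for line in lines[1:]:
        stripped = line.strip()
        if stripped.startswith(";"):
            if inSemicolon:
                tokens.append("\n".join(semicolonBuf))
                semicolonBuf = []
            inSemicolon = not inSemicolon
            rest = stripped[1:]
            if inSemicolon and rest:
                semicolonBuf.append(rest)
            continue
        if inSemicolon:
            semicolonBuf.append(line)
            continue
        tokens.extend(_tokenizeLine(line))

    i = 0
    while i < len(tokens):
        token = tokens[i]
        if token == "save_":
            break
        if token == "loop_":
            i += 1
            columns = []
            while i < len(tokens) and tokens[i].startswith("_"):
                columns.append(tokens[i])
                i += 1
            if not columns:
                raise NefSyntaxError(f"empty loop in saveframe {framecode}")
            values = []
            while i < len(tokens) and tokens[i] not in ("stop_", "save_", "loop_"):
                values.append(tokens[i])
                i += 1
            if i < len(tokens) and tokens[i] == "stop_":
                i += 1
            if len(values) % len(columns) != 0:
                raise NefSyntaxError(
                    f"ragged loop {columns[0]} in saveframe {framecode}")
            rows = [values[j:j + len(columns)]
                    for j in range(0, len(values), len(columns))]
            frame.loops.append(Loop(columns, rows))
        elif token.startswith("_"):
            if i + 1 >= len(tokens):
                raise NefSyntaxError(f"tag {token} without value in {framecode}")
            tail = token.split(".", 1)[1] if "." in token else token[1:]
            frame.items[tail] = tokens[i + 1]
            i += 2
        else:
            raise NefSyntaxError(f"unexpected token {token!r} in saveframe {framecode}")
    return frame


def parseNefString(text: str) -> tuple[str, list[Saveframe]]:
    dataName, rawFrames = _splitFrames(text)
    return dataName, [_parseFrame(raw) for raw in rawFrames]


# --------------------------------------------------------------------------
# Canonical writing
# --------------------------------------------------------------------------

_BARE_OK_RE = re.compile(r"^[^\s'\"#_$][^\s]*$")
_KEYWORDS = ("data_", "save_", "loop_", "stop_", "global_")


def _quote(value: str) -> str:
    if value == "":
        return NULL
    if _BARE_OK_RE.match(value) and not value.lower().startswith(_KEYWORDS):
        return value
    if '"' not in value:
        return f'"{value}"'
    if "'" not in value:
        return f"'{value}'"
    raise NefSyntaxError(f"cannot quote value {value!r}")


def _fmt(value: float) -> str:
    return format(value, ".6f")


class _Writer:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def frame(self, framecode: str, category: str, items: list[tuple[str, str]],
              loops: list[tuple[str, list[str], list[list[str]]]]) -> None:
        w = self.lines.append
        w(f"save_{framecode}")
        pairs = [("sf_category", category), ("sf_framecode", framecode)] + items
        width = max(len(k) for k, _ in pairs) + len(category) + 2
        for key, value in pairs:
            tag = f"_{category}.{key}"
            w(f"   {tag:<{width}}  {_quote(value)}")
        for loopCategory, columns, rows in loops:
            w("   loop_")
            for col in columns:
                w(f"      _{loopCategory}.{col}")
            w("")
            for row in rows:
                w("      " + "  ".join(_quote(v) for v in row))
            w("   stop_")
        w("save_")
        w("")


# --------------------------------------------------------------------------
# Project -> NEF
# --------------------------------------------------------------------------

def projectToNefString(project: Project) -> str:
    writer = _Writer()
    writer.lines.append(f"data_{_safeDataName(project.name)}")
    writer.lines.append("")

    writer.frame("nef_nmr_meta_data", "nef_nmr_meta_data", [
        ("format_name", "nmr_exchange_format"),
        ("format_version", "1.1"),
        ("program_name", "assignkit"),
    ], [])

    if project.chains:
        rows = []
        index = 0
        for chain in project.chains:
            n = len(chain.residues)
            for k, residue in enumerate(chain.residues):
                index += 1
                linking = ("single" if n == 1 else "start" if k == 0
                           else "end" if k == n - 1 else "middle")
                rows.append([str(index), chain.code, residue.sequenceCode,
                             residue.residueType, linking])
        writer.frame("nef_molecular_system", "nef_molecular_system", [], [
            ("nef_sequence",
             ["index", "chain_code", "sequence_code", "residue_name", "linking"],
             rows),
        ])

    if project.nmrChains:
        chainRows = [[c.name, "true" if c.isConnected else "false"]
                     for c in project.nmrChains]
        residueRows, atomRows = [], []
        for chain in project.nmrChains:
            for residue in chain.nmrResidues:
                residueRows.append([chain.name, residue.sequenceCode,
                                    residue.residueType or NULL])
                for atom in residue.nmrAtoms:
                    atomRows.append([chain.name, residue.sequenceCode, atom.name])
        writer.frame("ccpn_assignment", "ccpn_assignment", [], [
            ("nmr_chain", ["short_name", "is_connected"], chainRows),
            ("nmr_residue", ["chain_code", "sequence_code", "residue_name"],
             residueRows),
            ("nmr_atom", ["chain_code", "sequence_code", "name"], atomRows),
        ])

    for shiftList in project.chemicalShiftLists:
        rows = []
        for shift in shiftList.shifts:
            atom = shift.nmrAtom
            residue = atom.nmrResidue
            rows.append([residue.nmrChain.name, residue.sequenceCode,
                         residue.residueType or NULL, atom.name,
                         _fmt(shift.value), _fmt(shift.sd), str(shift.peakCount)])
        writer.frame(f"nef_chemical_shift_list_{shiftList.name}",
                     "nef_chemical_shift_list", [], [
            ("nef_chemical_shift",
             ["chain_code", "sequence_code", "residue_name", "atom_name",
              "value", "value_uncertainty", "ccpn_peak_count"],
             rows),
        ])

    for spectrum in project.spectra:
        for peakList in spectrum.peakLists:
            ndim = spectrum.dimensionCount
            dimRows = [[str(d + 1), spectrum.axisCodes[d], "ppm"]
                       for d in range(ndim)]
            perDim = [f"_{d + 1}" for d in range(ndim)]
            columns = (["index", "peak_id"]
                       + [f"position{s}" for s in perDim] + ["height"]
                       + [col for s in perDim
                          for col in (f"chain_code{s}", f"sequence_code{s}",
                                      f"residue_name{s}", f"atom_name{s}")])
            rows = []
            index = 0
            for peak in peakList.peaks:
                depth = max([len(a) for a in peak.dimensionNmrAtoms] + [1])
                for level in range(depth):
                    index += 1
                    row = [str(index), str(peak.serial)]
                    row += [_fmt(p) for p in peak.position]
                    row.append(_fmt(peak.height))
                    for atoms in peak.dimensionNmrAtoms:
                        if level < len(atoms):
                            atom = atoms[level]
                            residue = atom.nmrResidue
                            row += [residue.nmrChain.name, residue.sequenceCode,
                                    residue.residueType or NULL, atom.name]
                        else:
                            row += [NULL, NULL, NULL, NULL]
                    rows.append(row)
            writer.frame(
                f"nef_nmr_spectrum_{spectrum.name}_{peakList.serial}",
                "nef_nmr_spectrum",
                [("num_dimensions", str(ndim)),
                 ("chemical_shift_list", NULL),
                 ("ccpn_spectrum_name", spectrum.name),
                 ("ccpn_peaklist_serial", str(peakList.serial))],
                [("nef_spectrum_dimension",
                  ["dimension_id", "axis_code", "axis_unit"], dimRows),
                 ("nef_peak", columns, rows)])

    for raw in project._opaqueSaveframes:
        writer.lines.append(raw)
        writer.lines.append("")

    return "\n".join(writer.lines)


def _safeDataName(name: str) -> str:
    return re.sub(r"\s+", "_", name) or "project"


def writeNef(project: Project, path) -> None:
    with open(path, "w") as handle:
        handle.write(projectToNefString(project))


# --------------------------------------------------------------------------
# NEF -> Project
# --------------------------------------------------------------------------

_SUPPORTED_NEF = {
    "nef_nmr_meta_data", "nef_molecular_system",
    "nef_chemical_shift_list", "nef_nmr_spectrum",
}


def nefStringToProject(text: str, project: Project | None = None) -> Project:
    dataName, frames = parseNefString(text)
    if project is None:
        project = Project(dataName)
    orphanCount = 0
    for frame in frames:
        category = frame.category or frame.framecode
        if category.startswith("nef_") and category not in _SUPPORTED_NEF:
            raise UnsupportedNefBlockError(
                f"unsupported NEF saveframe category {category!r} "
                f"(saveframe {frame.framecode!r})")
        if category == "nef_nmr_meta_data":
            continue
        if category == "nef_molecular_system":
            _readMolecularSystem(project, frame)
        elif category == "ccpn_assignment":
            _readAssignment(project, frame)
        elif category == "nef_chemical_shift_list":
            _readShiftList(project, frame)
        elif category == "nef_nmr_spectrum":
            orphanCount = _readSpectrum(project, frame, orphanCount)
        else:
            project._opaqueSaveframes.append(frame.rawText)
    return project


def readNef(path, project: Project | None = None) -> Project:
    with open(path) as handle:
        return nefStringToProject(handle.read(), project)


def _readMolecularSystem(project: Project, frame: Saveframe) -> None:
    loop = frame.loop("nef_sequence")
    if loop is None:
        return
    for row in loop.rows:
        code = loop.get(row, "chain_code")
        chain = project.getChain(code) or project.newChain(code)
        chain.newResidue(loop.get(row, "sequence_code"),
                         loop.get(row, "residue_name"))


def _readAssignment(project: Project, frame: Saveframe) -> None:
    chainLoop = frame.loop("nmr_chain")
    if chainLoop is not None:
        for row in chainLoop.rows:
            name = chainLoop.get(row, "short_name")
            connected = chainLoop.get(row, "is_connected") == "true"
            chain = project.getNmrChain(name)
            if chain is None:
                chain = project.newNmrChain(name, isConnected=connected)
            else:
                chain.isConnected = connected
    residueLoop = frame.loop("nmr_residue")
    if residueLoop is not None:
        for row in residueLoop.rows:
            chain = project.fetchNmrChain(residueLoop.get(row, "chain_code"))
            residueType = residueLoop.get(row, "residue_name")
            chain.fetchNmrResidue(residueLoop.get(row, "sequence_code"),
                                  "" if residueType == NULL else residueType)
    atomLoop = frame.loop("nmr_atom")
    if atomLoop is not None:
        for row in atomLoop.rows:
            chain = project.fetchNmrChain(atomLoop.get(row, "chain_code"))
            residue = chain.fetchNmrResidue(atomLoop.get(row, "sequence_code"))
            residue.fetchNmrAtom(atomLoop.get(row, "name"))


def _fetchNmrAtomByNames(project: Project, chainCode: str, sequenceCode: str,
                         residueType: str, atomName: str):
    chain = project.fetchNmrChain(chainCode)
    residue = chain.fetchNmrResidue(
        sequenceCode, "" if residueType == NULL else residueType)
    return residue.fetchNmrAtom(atomName)


def _readShiftList(project: Project, frame: Saveframe) -> None:
    name = frame.framecode
    prefix = "nef_chemical_shift_list_"
    if name.startswith(prefix):
        name = name[len(prefix):]
    shiftList = project.newChemicalShiftList(name or "default")
    loop = frame.loop("nef_chemical_shift")
    if loop is None:
        return
    for row in loop.rows:
        atom = _fetchNmrAtomByNames(
            project, loop.get(row, "chain_code"), loop.get(row, "sequence_code"),
            loop.get(row, "residue_name"), loop.get(row, "atom_name"))
        sd = loop.get(row, "value_uncertainty")
        count = (loop.get(row, "ccpn_peak_count")
                 if loop.has("ccpn_peak_count") else "1")
        shiftList.setShift(atom, float(loop.get(row, "value")),
                           0.0 if sd == NULL else float(sd),
                           1 if count == NULL else int(count))


def _readSpectrum(project: Project, frame: Saveframe, orphanCount: int) -> int:
    name = frame.items.get("ccpn_spectrum_name", "")
    if not name:
        prefix = "nef_nmr_spectrum_"
        if frame.framecode.startswith(prefix) and len(frame.framecode) > len(prefix):
            name = frame.framecode[len(prefix):]
        else:
            orphanCount += 1
            name = f"spectrum_{orphanCount}"
    ndim = int(frame.items.get("num_dimensions", "0"))
    dimLoop = frame.loop("nef_spectrum_dimension")
    if dimLoop is not None and dimLoop.has("axis_code"):
        axisCodes = tuple(dimLoop.get(row, "axis_code") for row in dimLoop.rows)
    else:
        axisCodes = tuple(f"dim{d + 1}" for d in range(ndim))
    spectrum = project.getSpectrum(name) or project.newSpectrum(name, axisCodes)
    peakList = spectrum.newPeakList()

    loop = frame.loop("nef_peak")
    if loop is None:
        return orphanCount
    ndim = len(axisCodes)
    byPeak: dict[str, list[list[str]]] = {}
    order: list[str] = []
    for row in loop.rows:
        peakId = loop.get(row, "peak_id")
        if peakId not in byPeak:
            byPeak[peakId] = []
            order.append(peakId)
        byPeak[peakId].append(row)
    for peakId in order:
        rows = byPeak[peakId]
        first = rows[0]
        position = tuple(float(loop.get(first, f"position_{d + 1}"))
                         for d in range(ndim))
        heightText = loop.get(first, "height") if loop.has("height") else NULL
        height = 0.0 if heightText == NULL else float(heightText)
        dimensionNmrAtoms: list[list] = [[] for _ in range(ndim)]
        for row in rows:
            for d in range(ndim):
                atomName = (loop.get(row, f"atom_name_{d + 1}")
                            if loop.has(f"atom_name_{d + 1}") else NULL)
                if atomName == NULL:
                    continue
                atom = _fetchNmrAtomByNames(
                    project, loop.get(row, f"chain_code_{d + 1}"),
                    loop.get(row, f"sequence_code_{d + 1}"),
                    loop.get(row, f"residue_name_{d + 1}"), atomName)
                dimensionNmrAtoms[d].append(atom)
        peak = peakList.newPeak(position, height, dimensionNmrAtoms)
        peak.serial = int(peakId)
    return orphanCount
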