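"""Format routing: map file extension / signature to the right loader.

The dispatch is total over the supported subset (FASTA, NEF, CSV peak
lists, .sgrid grids); recognised-but-unsupported NMR formats (Bruker,
Varian/Agilent, NmrPipe, UCSF, Azara, XEASY, NmrView, PDB, Excel, CCPN
projects) raise a named :class:`~assignkit.errors.UnsupportedFormatError`
rather than failing silently.
"""
from __future__ import annotations

from pathlib import Path

from ..errors import UnsupportedFormatError
from ..model import Project
from . import fasta, nef, peaks_csv, sgrid

__all__ = ["detectFormat", "loadFile", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("fasta", "nef", "peaks-csv", "sgrid")

_UNSUPPORTED_EXTENSIONS = {
    ".ucsf": "UCSF", ".pipe": "NmrPipe", ".ft2": "NmrPipe", ".ft3": "NmrPipe",
    ".par": "Azara", ".spc": "Azara", ".3D.param": "XEASY", ".nv": "NmrView",
    ".pdb": "PDB-v3", ".xlsx": "Excel", ".xls": "Excel", ".ccpn": "CCPN project",
}

_EXTENSIONS = {
    ".fasta": "fasta", ".fa": "fasta", ".faa": "fasta",
    ".nef": "nef",
    ".csv": "peaks-csv",
    ".sgrid": "sgrid",
}


def detectFormat(path) -> str:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _UNSUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"{path.name}: {_UNSUPPORTED_EXTENSIONS[suffix]} files are not "
            f"supported (supported: {', '.join(SUPPORTED_FORMATS)})")
    if suffix in _EXTENSIONS:
        return _EXTENSIONS[suffix]
    # signature sniffing for extensionless / odd-named files
    try:
        head = path.open("rb").read(64)
    except OSError as exc:
        raise UnsupportedFormatError(f"cannot read {path}: {exc}") from exc
    if head.startswith(sgrid.MAGIC):
        return "sgrid"
    if head.lstrip().startswith(b">"):
        return "fasta"
    if head.lstrip().startswith(b"data_"):
        return "nef"
    raise UnsupportedFormatError(
        f"{path.name}: unrecognised format "
        f"(supported: {', '.join(SUPPORTED_FORMATS)})")


def loadFile(path, project: Project | None = None):
    """Load any supported file, returning (format, loaded object).

    FASTA returns the created Chains (one per record), NEF the Project, a
    peak-list CSV the (peaks, axisCodes) pair, .sgrid the SpectrumGrid.
    """
    kind = detectFormat(path)
    if kind == "fasta":
        if project is None:
            project = Project(Path(path).stem)
        chains = []
        codes = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        for name, sequence in fasta.readFasta(path):
            chains.append(fasta.makeChain(project, sequence, next(codes)))
        return kind, chains
    if kind == "nef":
        return kind, nef.readNef(path, project)
    if kind == "peaks-csv":
        return kind, peaks_csv.readPeakListCsv(path)
    return kind, sgrid.readSpectrumGrid(path)
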