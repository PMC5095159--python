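"""The ``.sgrid`` gridded-spectrum format.

A deliberately simple, language-neutral container for processed spectrum
intensities: a UTF-8 text header of ``key: value`` lines terminated by an
``end_header`` line, followed by a row-major little-endian float32 payload.
ppm axes run *descending* with increasing point index (the NMR plotting
convention): point 0 sits at the highest ppm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import SpectrumFormatError

__all__ = ["SpectrumGrid", "readSpectrumGrid", "writeSpectrumGrid"]

MAGIC = b"SGRID 1"


@dataclass
class SpectrumGrid:
    """An N-dimensional grid of intensities with affine ppm axes.

    ``ppmStart[d]`` is the ppm at point 0 of dimension d, ``ppmEnd[d]`` the
    ppm at the last point; start > end (descending).
    """

    axisCodes: tuple[str, ...]
    pointCounts: tuple[int, ...]
    ppmStart: tuple[float, ...]
    ppmEnd: tuple[float, ...]
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.axisCodes = tuple(self.axisCodes)
        self.pointCounts = tuple(int(n) for n in self.pointCounts)
        self.ppmStart = tuple(float(v) for v in self.ppmStart)
        self.ppmEnd = tuple(float(v) for v in self.ppmEnd)
        ndim = len(self.axisCodes)
        if not (len(self.pointCounts) == len(self.ppmStart)
                == len(self.ppmEnd) == ndim):
            raise SpectrumFormatError("inconsistent dimension counts")
        if any(n < 1 for n in self.pointCounts):
            raise SpectrumFormatError("point counts must be positive")
        data = np.asarray(self.intensities, dtype=np.float32)
        if data.size != int(np.prod(self.pointCounts)):
            raise SpectrumFormatError(
                f"intensity count {data.size} does not match grid "
                f"{self.pointCounts}")
        self.intensities = data.reshape(self.pointCounts)

    @property
    def dimensionCount(self) -> int:
        return len(self.axisCodes)

    def ppmPerPoint(self, dim: int) -> float:
        n = self.pointCounts[dim]
        if n == 1:
            return 0.0
        return (self.ppmEnd[dim] - self.ppmStart[dim]) / (n - 1)

    def pointToPpm(self, dim: int, point: float) -> float:
        return self.ppmStart[dim] + point * self.ppmPerPoint(dim)

    def ppmToPoint(self, dim: int, ppm: float) -> float:
        step = self.ppmPerPoint(dim)
        if step == 0.0:
            return 0.0
        return (ppm - self.ppmStart[dim]) / step

    def axisPpm(self, dim: int) -> np.ndarray:
        return self.ppmStart[dim] + np.arange(self.pointCounts[dim]) * self.ppmPerPoint(dim)


def writeSpectrumGrid(grid: SpectrumGrid, path) -> None:
    header = [
        MAGIC.decode(),
        f"ndim: {grid.dimensionCount}",
        f"axis_codes: {','.join(grid.axisCodes)}",
        f"point_counts: {','.join(str(n) for n in grid.pointCounts)}",
        f"ppm_start: {','.join(format(v, '.6f') for v in grid.ppmStart)}",
        f"ppm_end: {','.join(format(v, '.6f') for v in grid.ppmEnd)}",
        "data: float32-le",
        "end_header",
        "",
    ]
    with open(path, "wb") as handle:
        handle.write("\n".join(header).encode())
        handle.write(np.ascontiguousarray(grid.intensities, dtype="<f4").tobytes())


def readSpectrumGrid(path) -> SpectrumGrid:
    with open(path, "rb") as handle:
        blob = handle.read()
    if not blob.startswith(MAGIC + b"\n"):
        raise SpectrumFormatError(f"{path}: not an sgrid file (bad magic)")
    headerEnd = blob.find(b"end_header\n")
    if headerEnd < 0:
        raise SpectrumFormatError(f"{path}: missing end_header")
    fields: dict[str, str] = {}
    for line in blob[len(MAGIC) + 1:headerEnd].decode().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    try:
        ndim = int(fields["ndim"])
        axisCodes = tuple(fields["axis_codes"].split(","))
        pointCounts = tuple(int(v) for v in fields["point_counts"].split(","))
        ppmStart = tuple(float(v) for v in fields["ppm_start"].split(","))
        ppmEnd = tuple(float(v) for v in fields["ppm_end"].split(","))
    except (KeyError, ValueError) as exc:
        raise SpectrumFormatError(f"{path}: bad header ({exc})") from exc
    if len(axisCodes) != ndim:
        raise SpectrumFormatError(f"{path}: ndim does not match axis_codes")
    payload = blob[headerEnd + len(b"end_header\n"):]
    expected = 4 * int(np.prod(pointCounts))
    if len(payload) != expected:
        raise SpectrumFormatError(
            f"{path}: payload has {len(payload)} bytes, expected {expected}")
    intensities = np.frombuffer(payload, dtype="<f4").astype(np.float32)
    return SpectrumGrid(axisCodes, pointCounts, ppmStart, ppmEnd, intensities)
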