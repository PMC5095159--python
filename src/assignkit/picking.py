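"""Threshold-based local-extremum peak picking with sub-grid refinement.

A peak is a grid point strictly greater than all of its 3^ndim − 1
neighbours with intensity above threshold (and, under sign policy "both" or
"negative", strict local minima below −threshold).  Plateau points tied
with a neighbour are never peaks, and neither are grid-edge points (their
neighbourhood is incomplete).  Each picked position is refined per
dimension by three-point parabolic interpolation, clamped to half a grid
step, and the reported height is the interpolated apex.

Restricted picking confines the search window around the known shifts of an
NmrResidue (amide H/N in the pick-and-assign workflow) and auto-assigns the
matched dimensions of every picked peak.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import ChemicalShiftList, NmrResidue
from .records import PeakRecord
from .io.sgrid import SpectrumGrid

__all__ = ["PickRegion", "pickPeaks", "restrictedPick", "DEFAULT_TOLERANCES"]

#: Per-isotope matching tolerances in ppm, keyed by leading nucleus letter.
DEFAULT_TOLERANCES: dict[str, float] = {"H": 0.05, "N": 0.4, "C": 0.4}


@dataclass
class PickRegion:
    """Per-dimension ppm windows plus a sign policy.

    ``ranges`` maps axisCode -> (ppmMin, ppmMax); axes omitted from the map
    are searched over their full range.
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    signPolicy: str = "positive"        # positive | negative | both

    def __post_init__(self) -> None:
        if self.signPolicy not in ("positive", "negative", "both"):
            raise ValueError(f"unknown sign policy {self.signPolicy!r}")
        for code, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"empty range for axis {code}: {lo} > {hi}")


def _regionBounds(grid: SpectrumGrid, region: PickRegion | None
                  ) -> list[tuple[float, float]]:
    """Resolve the region to (ppmMin, ppmMax) per grid dimension."""
    bounds = []
    matched = set()
    for d, code in enumerate(grid.axisCodes):
        lo = min(grid.ppmStart[d], grid.ppmEnd[d])
        hi = max(grid.ppmStart[d], grid.ppmEnd[d])
        if region is not None:
            window = region.ranges.get(code)
            if window is None:
                # fall back to unique leading-letter match
                candidates = [c for c in region.ranges if c[0] == code[0]]
                if len(candidates) == 1 and candidates[0] not in matched:
                    window = region.ranges[candidates[0]]
                    matched.add(candidates[0])
            else:
                matched.add(code)
            if window is not None:
                lo, hi = max(lo, window[0]), min(hi, window[1])
        bounds.append((lo, hi))
    return bounds


def _strictMaximaMask(data: np.ndarray) -> np.ndarray:
    """Boolean mask of interior points strictly above all 3^ndim−1 neighbours."""
    ndim = data.ndim
    inner = tuple(slice(1, -1) for _ in range(ndim))
    if any(s < 3 for s in data.shape):
        return np.zeros_like(data, dtype=bool)
    centre = data[inner]
    mask = np.ones(centre.shape, dtype=bool)
    for shifts in itertools.product((-1, 0, 1), repeat=ndim):
        if all(s == 0 for s in shifts):
            continue
        neighbour = data[tuple(slice(1 + s, data.shape[d] - 1 + s)
                               for d, s in enumerate(shifts))]
        mask &= centre > neighbour
    full = np.zeros_like(data, dtype=bool)
    full[inner] = mask
    return full


def _refine(data: np.ndarray, index: tuple[int, ...]) -> tuple[np.ndarray, float]:
    """Per-dimension parabolic refinement; returns (fractional index, apex)."""
    frac = np.array(index, dtype=float)
    apex = float(data[index])
    for d in range(data.ndim):
        lo = list(index); lo[d] -= 1
        hi = list(index); hi[d] += 1
        fm, f0, fp = float(data[tuple(lo)]), float(data[index]), float(data[tuple(hi)])
        denom = fm - 2.0 * f0 + fp
        if denom >= 0.0:        # not locally concave along this axis
            continue
        delta = 0.5 * (fm - fp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        frac[d] += delta
        apex += -0.25 * (fm - fp) * delta
    return frac, apex


def pickPeaks(grid: SpectrumGrid, region: PickRegion | None = None,
              threshold: float = 0.0, signPolicy: str | None = None
              ) -> list[PeakRecord]:
    """Pick strict local extrema above threshold inside a region.

    Returns PeakRecords sorted by |height| descending, serials 1..k; a
    region entirely outside the grid yields an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    policy = signPolicy or (region.signPolicy if region is not None else "positive")
    bounds = _regionBounds(grid, region)
    data = grid.intensities.astype(np.float64)

    found: list[tuple[tuple[float, ...], float]] = []
    passes = []
    if policy in ("positive", "both"):
        passes.append(1.0)
    if policy in ("negative", "both"):
        passes.append(-1.0)
    for sign in passes:
        signed = data * sign
        mask = _strictMaximaMask(signed) & (signed > threshold)
        for index in zip(*np.nonzero(mask)):
            ppm = [grid.pointToPpm(d, i) for d, i in enumerate(index)]
            if any(not (lo <= p <= hi) for p, (lo, hi) in zip(ppm, bounds)):
                continue
            frac, apex = _refine(signed, index)
            position = tuple(
                float(np.clip(grid.pointToPpm(d, frac[d]), lo, hi))
                for d, (lo, hi) in enumerate(bounds))
            found.append((position, sign * apex))

    found.sort(key=lambda item: (-abs(item[1]), item[0]))
    return [PeakRecord(serial=i + 1, position=pos, height=height)
            for i, (pos, height) in enumerate(found)]


def restrictedPick(grid: SpectrumGrid, nmrResidue: NmrResidue,
                   shiftList: ChemicalShiftList,
                   tolerances: dict[str, float] | None = None,
                   threshold: float = 0.0,
                   signPolicy: str = "both") -> list[PeakRecord]:
    """Chemical-shift-restricted pick driven by an NmrResidue's shifts.

    Axes whose leading nucleus letter matches an NmrAtom with a known shift
    are restricted to [shift − tol, shift + tol]; the remaining axes are
    searched full-range.  Matched dimensions of every returned peak are
    assigned to the restricting NmrAtoms.  Negative peaks are picked by
    default (HNCACB-style spectra carry negative CB correlations).
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)

    shifted = [(atom, shiftList.shiftValue(atom)) for atom in nmrResidue.nmrAtoms]
    shifted = [(atom, value) for atom, value in shifted if value is not None]
    ranges: dict[str, tuple[float, float]] = {}
    axisAtoms: dict[str, object] = {}
    for d, code in enumerate(grid.axisCodes):
        matching = sorted((a for a, _ in shifted if a.isotopeLetter == code[0]),
                          key=lambda a: a.name)
        if not matching:
            continue
        atom = matching[0]
        value = dict((id(a), v) for a, v in shifted)[id(atom)]
        width = tol.get(code[0], 0.0)
        ranges[code] = (value - width, value + width)
        axisAtoms[code] = atom
    if not ranges:
        raise ValueError(
            f"no axis of {grid.axisCodes} matches a shifted NmrAtom of "
            f"{nmrResidue.pid}")

    region = PickRegion(ranges=ranges, signPolicy=signPolicy)
    peaks = pickPeaks(grid, region, threshold)
    assigned = []
    for peak in peaks:
        assignments = tuple(
            (str(axisAtoms[code].pid),) if code in axisAtoms else ()
            for code in grid.axisCodes)
        assigned.append(PeakRecord(peak.serial, peak.position, peak.height,
                                   assignments))
    return assigned
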