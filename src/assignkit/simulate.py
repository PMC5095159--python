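"""Seeded synthetic data: ground-truth shifts, peak lists and gridded spectra.

The generator draws one "true" chemical shift per (residue, atom) from the
packaged reference distributions — the same table the predictors use, so
recovery tests are self-consistent and need no external data — and renders
experiment-specific peak lists and Gaussian-lineshape grids from them, with
configurable per-isotope position noise, random peak dropout, spurious
extra peaks and referencing offsets.

Conventions mirroring real triple-resonance data: prolines produce no
HN-anchored peaks (no amide proton); the first residue contributes only the
pattern entries that do not require a predecessor; glycines have no CB/HB.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .alignment import applyReferencing
from .experiments import ExperimentType, getExperimentType
from .io.fasta import ONE_TO_THREE
from .io.sgrid import SpectrumGrid
from .records import PeakRecord
from .refshifts import DEFAULT_TABLE, TABLE_ATOMS, ReferenceShiftTable

__all__ = ["GroundTruth", "simulateShifts", "simulatePeakList",
           "simulateSpectrumGrid", "buildSpinSystems", "misreference"]


@dataclass
class GroundTruth:
    """True per-residue shifts for a sequence, reproducible from its seed."""

    sequence: str
    trueShifts: dict[tuple[int, str], float]     # (1-based residue index, atom)
    seed: int
    generatorParams: dict = field(default_factory=dict)

    def residueType(self, index: int) -> str:
        return ONE_TO_THREE[self.sequence[index - 1]]

    def get(self, index: int, atom: str) -> float | None:
        return self.trueShifts.get((index, atom))

    def __len__(self) -> int:
        return len(self.sequence)


def simulateShifts(sequence: str, refTable: ReferenceShiftTable = DEFAULT_TABLE,
                   seed: int = 0) -> GroundTruth:
    """Draw true shifts ~ Normal(μ, σ) from the reference table per residue."""
    sequence = sequence.upper()
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid one-letter code(s): {sorted(set(bad))}")
    rng = np.random.default_rng(seed)
    shifts: dict[tuple[int, str], float] = {}
    for i, letter in enumerate(sequence, start=1):
        residueType = ONE_TO_THREE[letter]
        for atom in TABLE_ATOMS:
            stats = refTable.get(residueType, atom)
            if stats is None:
                continue
            shifts[(i, atom)] = float(rng.normal(stats[0], stats[1]))
    return GroundTruth(sequence, shifts, seed)


_DEFAULT_NOISE = {"H": 0.0, "N": 0.0, "C": 0.0}


def simulatePeakList(truth: GroundTruth, expType: ExperimentType | str,
                     noiseSd: dict[str, float] | None = None,
                     missingFraction: float = 0.0, extraPeaks: int = 0,
                     seed: int = 0) -> list[PeakRecord]:
    """Render the expected peaks of an experiment from ground-truth shifts.

    One peak per expected-pattern entry per residue where the target residue
    and atom exist, positions jittered by per-isotope Normal noise, heights
    ±1 following the pattern sign.  Peaks drop out independently with
    probability ``missingFraction``; ``extraPeaks`` spurious peaks are
    added uniformly over the occupied spectral ranges.
    """
    if isinstance(expType, str):
        expType = getExperimentType(expType)
    rng = np.random.default_rng(seed)
    noise = {**_DEFAULT_NOISE, **(noiseSd or {})}
    anchors = dict(expType.anchorAtoms)

    raw: list[tuple[tuple[float, ...], float]] = []
    n = len(truth)
    for i in range(1, n + 1):
        if anchors and truth.residueType(i) == "PRO":
            continue        # no amide proton to anchor the peak
        if anchors:
            anchorShifts = {code: truth.get(i, atom)
                            for code, atom in anchors.items()}
            if any(v is None for v in anchorShifts.values()):
                continue
            if expType.patternAxis is None:
                raw.append(_jitteredPeak(
                    expType.axisCodes, anchorShifts, {}, +1, noise, rng))
                continue
            for entry in expType.expectedPattern:
                value = truth.get(i + entry.offset, entry.atomName)
                if value is None:
                    continue
                raw.append(_jitteredPeak(
                    expType.axisCodes, anchorShifts,
                    {expType.patternAxis: value}, entry.sign, noise, rng))
        else:
            # CH-fingerprint style: pair H* and C* entries at equal offsets
            entries = list(expType.expectedPattern)
            pairs = [(h, c) for h in entries for c in entries
                     if h.atomName.startswith("H") and c.atomName.startswith("C")
                     and h.atomName[1:] == c.atomName[1:]
                     and h.offset == c.offset]
            for hEntry, cEntry in pairs:
                hValue = truth.get(i + hEntry.offset, hEntry.atomName)
                cValue = truth.get(i + cEntry.offset, cEntry.atomName)
                if hValue is None or cValue is None:
                    continue
                raw.append(_jitteredPeak(
                    expType.axisCodes,
                    {expType.axisCodes[0]: hValue, expType.axisCodes[1]: cValue},
                    {}, hEntry.sign, noise, rng))

    if missingFraction > 0:
        raw = [peak for peak in raw if rng.random() >= missingFraction]

    if extraPeaks > 0 and raw:
        positions = np.array([p for p, _ in raw])
        lo, hi = positions.min(axis=0), positions.max(axis=0)
        median = float(np.median([abs(h) for _, h in raw]))
        for _ in range(extraPeaks):
            position = tuple(float(rng.uniform(l, h)) for l, h in zip(lo, hi))
            height = float(rng.uniform(0.5, 1.5) * median)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            raw.append((position, sign * height))

    return [PeakRecord(serial=k + 1, position=pos, height=height)
            for k, (pos, height) in enumerate(raw)]


def _jitteredPeak(axisCodes, anchorShifts, extraShifts, sign, noise, rng):
    position = []
    for code in axisCodes:
        value = extraShifts.get(code, anchorShifts.get(code))
        position.append(value + rng.normal(0.0, noise.get(code[0], 0.0))
                        if noise.get(code[0], 0.0) > 0 else value)
    return tuple(position), float(sign)


def simulateSpectrumGrid(peaks: list[PeakRecord], lineWidths, pointCounts,
                         ppmRanges, noiseSd: float = 0.0, seed: int = 0,
                         axisCodes=None) -> SpectrumGrid:
    """Render peaks as axis-aligned Gaussians on a grid, plus white noise.

    ``ppmRanges`` is a (start, end) pair per dimension with start > end
    (descending ppm); ``lineWidths`` are Gaussian sigmas in ppm.
    """
    pointCounts = tuple(int(n) for n in pointCounts)
    ndim = len(pointCounts)
    starts = tuple(float(r[0]) for r in ppmRanges)
    ends = tuple(float(r[1]) for r in ppmRanges)
    if axisCodes is None:
        axisCodes = tuple(f"dim{d + 1}" for d in range(ndim))
    rng = np.random.default_rng(seed)

    axes = [np.linspace(starts[d], ends[d], pointCounts[d]) for d in range(ndim)]
    data = np.zeros(pointCounts, dtype=np.float64)
    for peak in peaks:
        factors = [np.exp(-0.5 * ((axes[d] - peak.position[d])
                                  / float(lineWidths[d])) ** 2)
                   for d in range(ndim)]
        shape = np.ones(ndim, dtype=int)
        contribution = np.array(peak.height, dtype=np.float64)
        for d, factor in enumerate(factors):
            s = shape.copy()
            s[d] = len(factor)
            contribution = contribution * factor.reshape(s)
        data = data + contribution
    if noiseSd > 0:
        data += rng.normal(0.0, noiseSd, size=pointCounts)
    return SpectrumGrid(axisCodes, pointCounts, starts, ends,
                        data.astype(np.float32))


def buildSpinSystems(project, truth: GroundTruth, shiftList,
                     noiseSd: dict[str, float] | None = None, seed: int = 0,
                     shuffle: bool = True,
                     ownAtoms=("H", "N", "CA", "CB"),
                     minusOneAtoms=("CA", "CB")):
    """Create unassigned spin systems from ground truth, as picking would.

    One serial NmrResidue ("@n") per non-proline residue, carrying its own
    amide and CA/CB shifts plus a "-1" offset child with the predecessor's
    CA/CB — the state left behind by the pick-and-assign workflow on HSQC +
    HNCACB/CBCAcoNH data.  Own and inter-residue observations get
    independent noise.  With ``shuffle`` the creation order is randomised so
    serial order carries no information about the sequence.

    Returns (nmrResidue, true 1-based sequence index) pairs in creation order.
    """
    rng = np.random.default_rng(seed)
    noise = {**_DEFAULT_NOISE, **(noiseSd or {})}
    indices = [i for i in range(1, len(truth) + 1)
               if truth.residueType(i) != "PRO"]
    if shuffle:
        rng.shuffle(indices)
    nmrChain = project.fetchNmrChain()
    out = []
    for i in indices:
        nmrResidue = nmrChain.newNmrResidue()
        for atom in ownAtoms:
            value = truth.get(i, atom)
            if value is None:
                continue
            sd = noise.get(atom[0], 0.0)
            observed = value + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            shiftList.setShift(nmrResidue.fetchNmrAtom(atom), observed)
        previous = i - 1
        if previous >= 1:
            child = nmrResidue.fetchOffsetNmrResidue(-1)
            for atom in minusOneAtoms:
                value = truth.get(previous, atom)
                if value is None:
                    continue
                sd = noise.get(atom[0], 0.0)
                observed = value + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                shiftList.setShift(child.fetchNmrAtom(atom), observed)
        out.append((nmrResidue, i))
    return out


def misreference(target, offsets):
    """Return a deep copy translated by per-dimension ppm offsets.

    The inverse of the referencing correction: ``applyReferencing`` with the
    negated offsets restores the original positions.
    """
    duplicate = copy.deepcopy(target)
    return applyReferencing(duplicate, offsets)
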