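"""Residue-type prediction and Bayesian placement of stretches on a sequence.

Observed shifts of a spin system are modelled as independent Gaussians
around per-(residue type, atom) reference means:

    P(type | shifts) ∝ prior(type) · Π_a N(δ_a; μ_{type,a}, σ_{type,a})

Atoms not observed contribute no factor (missing-at-random); an observed
shift for an atom the type does not possess (a CB observed on a candidate
glycine position) contributes a small constant ε = 1e−6, a strong but not
absolute veto.

A connected stretch of length L is placed on a chain by sliding: the log
likelihood of start position p is the sum over stretch residues i of the
type log-likelihood at chain position p+i, and the posterior over feasible
starts is the stable softmax of those log likelihoods.  Following the
interactive workflow, placements are only computed once a stretch has more
than three residues, and windows overlapping residues that already carry an
assignment are excluded.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.special import logsumexp

from .model import (Chain, ChemicalShiftList, NmrChain, NmrResidue, Residue,
                    assignNmrResidue)
from .errors import ConflictError, TypeMismatchError
from .refshifts import DEFAULT_TABLE, TABLE_ATOMS, ReferenceShiftTable

__all__ = ["StretchPlacement", "predictResidueType", "mapStretchToSequence",
           "assignStretch", "MIN_STRETCH_LENGTH"]

logger = logging.getLogger(__name__)

#: A stretch must be longer than this before placement is attempted.
MIN_STRETCH_LENGTH = 3

_LOG_EPSILON = math.log(1e-6)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _logNormal(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI


def typeLogLikelihood(shifts: dict[str, float], residueType: str,
                      refTable: ReferenceShiftTable = DEFAULT_TABLE) -> float:
    """log P(observed shifts | residue type) under the reference table."""
    total = 0.0
    for atom, value in shifts.items():
        stats = refTable.get(residueType, atom)
        total += _LOG_EPSILON if stats is None else _logNormal(value, *stats)
    return total


def observedShifts(nmrResidue: NmrResidue, shiftList: ChemicalShiftList,
                   refTable: ReferenceShiftTable = DEFAULT_TABLE
                   ) -> dict[str, float]:
    """Shifts of the residue's own NmrAtoms with reference-table atom names."""
    out = {}
    for atom in nmrResidue.nmrAtoms:
        if atom.name not in TABLE_ATOMS:
            continue
        value = shiftList.shiftValue(atom)
        if value is not None:
            out[atom.name] = value
    return out


def predictResidueType(nmrResidue: NmrResidue, shiftList: ChemicalShiftList,
                       refTable: ReferenceShiftTable = DEFAULT_TABLE,
                       prior: dict[str, float] | None = None
                       ) -> list[tuple[str, float]]:
    """Rank the 20 residue types by posterior probability given the shifts."""
    shifts = observedShifts(nmrResidue, shiftList, refTable)
    if not shifts:
        raise ValueError(f"{nmrResidue.pid} has no usable shifts")
    types = refTable.residueTypes
    logs = []
    for residueType in types:
        logPrior = math.log(prior[residueType]) if prior else 0.0
        logs.append(logPrior + typeLogLikelihood(shifts, residueType, refTable))
    norm = logsumexp(logs)
    ranked = [(t, math.exp(l - norm)) for t, l in zip(types, logs)]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


@dataclass(frozen=True)
class StretchPlacement:
    startResidue: Residue
    posterior: float
    perResidueLogLik: tuple[float, ...]

    @property
    def logLikelihood(self) -> float:
        return sum(self.perResidueLogLik)


def _claimedResidues(chain: Chain) -> set[int]:
    """Indices of chain residues already claimed by an assigned NmrResidue."""
    project = chain.project
    claimed = set()
    for nmrChain in project.nmrChains:
        for nmrResidue in nmrChain.nmrResidues:
            if nmrResidue.offset is not None:
                continue
            residue = nmrResidue.residue
            if residue is not None and residue.chain is chain:
                claimed.add(residue.index)
    return claimed


def mapStretchToSequence(stretch: NmrChain, chain: Chain,
                         shiftList: ChemicalShiftList,
                         refTable: ReferenceShiftTable = DEFAULT_TABLE
                         ) -> list[StretchPlacement]:
    """Rank feasible placements of a connected stretch on a molecular chain.

    Returns StretchPlacements in descending posterior order; posteriors over
    the feasible placements sum to 1.  Stretches of three or fewer residues,
    or longer than the chain, yield an empty list.
    """
    residues = stretch.mainNmrResidues
    length = len(residues)
    if length <= MIN_STRETCH_LENGTH:
        logger.info("stretch %s has %d residues (need > %d): no placements",
                    stretch.name, length, MIN_STRETCH_LENGTH)
        return []
    if length > len(chain.residues):
        return []

    shifts = [observedShifts(r, shiftList, refTable) for r in residues]
    claimed = _claimedResidues(chain)

    starts, logLiks, perResidue = [], [], []
    for p in range(len(chain.residues) - length + 1):
        window = range(p, p + length)
        if any(i in claimed for i in window):
            continue
        logs = tuple(
            typeLogLikelihood(shifts[i], chain.residues[p + i].residueType,
                              refTable) if shifts[i] else 0.0
            for i in range(length))
        starts.append(chain.residues[p])
        perResidue.append(logs)
        logLiks.append(sum(logs))
    if not starts:
        return []
    norm = logsumexp(logLiks)
    placements = [
        StretchPlacement(start, math.exp(l - norm), logs)
        for start, l, logs in zip(starts, logLiks, perResidue)]
    placements.sort(key=lambda pl: (-pl.posterior, pl.startResidue.index))
    return placements


def assignStretch(stretch: NmrChain, chain: Chain,
                  startResidue: Residue) -> list[NmrResidue]:
    """Assign a stretch to consecutive residues from a start position.

    All-or-nothing: every target residue is checked for availability and
    type compatibility before any assignment is made.
    """
    nmrResidues = stretch.mainNmrResidues
    start = startResidue.index
    if start + len(nmrResidues) > len(chain.residues):
        raise ConflictError("stretch runs past the end of the chain")
    targets = chain.residues[start:start + len(nmrResidues)]

    claimed = _claimedResidues(chain)
    for nmrResidue, target in zip(nmrResidues, targets):
        if target.index in claimed:
            raise ConflictError(f"{target.pid} is already assigned")
        if (nmrResidue.residueType
                and nmrResidue.residueType != target.residueType):
            raise TypeMismatchError(
                f"{nmrResidue.pid} type {nmrResidue.residueType} does not "
                f"match {target.pid}")
    for nmrResidue, target in zip(list(nmrResidues), targets):
        assignNmrResidue(nmrResidue, target)
    return nmrResidues
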