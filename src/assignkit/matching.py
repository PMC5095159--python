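"""Backbone strip matching and atom-selector prediction.

The sequential walk links spin system *i* to spin system *i−1* by comparing
the inter-residue CA/CB shifts observed in one strip with the intra-residue
CA/CB shifts of candidate strips.  The match metric is the
tolerance-normalised RMS deviation over the atoms both sides share,

    score = sqrt( mean_a (Δδ_a / tol_a)^2 ),

which is scale-free across nuclei and reduces to |Δδ|/tol for a single
shared atom.  Glycines (no CB) are scored on CA alone; a candidate sharing
no atom at all is excluded rather than penalised.

The atom selector scores an unassigned peak dimension against the candidate
(atom, offset) pairs an experiment type can produce, using the reference
shift distributions pooled over the 20 residue types with equal weight and
a soft sign-consistency factor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

from .experiments import ExperimentType, getExperimentType
from .model import ChemicalShiftList, NmrChain, NmrResidue, connectStretch
from .picking import DEFAULT_TOLERANCES
from .records import PeakRecord
from .refshifts import DEFAULT_TABLE, ReferenceShiftTable

__all__ = ["StripQuery", "matchStrips", "extendStretch", "predictAtomSelector"]

_SELECTOR_ATOMS = ("CA", "CB", "HA", "HB")
_SIGN_MISMATCH_FACTOR = 0.1


@dataclass
class StripQuery:
    """Shifts to match against candidate spin systems.

    For direction "i_minus_1" the query shifts are the inter-residue
    CA(i−1)/CB(i−1) values observed in the query strip and candidates are
    compared through their own (intra-residue) shifts; for "i_plus_1" the
    query shifts are the residue's own CA/CB and candidates through their
    "-1" offset children.
    """

    queryShifts: dict[str, float]
    direction: str = "i_minus_1"
    queryNmrResidue: NmrResidue | None = None
    tolerances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("i_minus_1", "i_plus_1"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.queryShifts:
            raise ValueError("query needs at least one shift (CA and/or CB)")
        self.tolerances = {**DEFAULT_TOLERANCES, **self.tolerances}


def _candidateShifts(candidate: NmrResidue, direction: str,
                     shiftList: ChemicalShiftList,
                     atomNames) -> dict[str, float]:
    """The candidate-side shifts compared against the query."""
    if direction == "i_minus_1":
        source = candidate
    else:
        source = next((c for c in candidate.offsetNmrResidues if c.offset == -1),
                      None)
        if source is None:
            return {}
    out = {}
    for name in atomNames:
        value = shiftList.shiftValue(source.getNmrAtom(name))
        if value is not None:
            out[name] = value
    return out


def matchStrips(query: StripQuery, candidates: list[NmrResidue],
                shiftList: ChemicalShiftList) -> list[tuple[NmrResidue, float]]:
    """Rank candidate spin systems by shift match, best (lowest score) first.

    Candidates sharing no atom with the query are excluded, as are the query
    residue itself and members of its connected stretch.  Ties break on PID.
    """
    excluded: set[int] = set()
    if query.queryNmrResidue is not None:
        excluded.add(id(query.queryNmrResidue))
        chain = query.queryNmrResidue.nmrChain
        if chain.isConnected:
            excluded.update(id(r) for r in chain.nmrResidues)

    scored = []
    for candidate in candidates:
        if id(candidate) in excluded:
            continue
        shifts = _candidateShifts(candidate, query.direction, shiftList,
                                  query.queryShifts)
        shared = sorted(set(shifts) & set(query.queryShifts))
        if not shared:
            continue
        terms = []
        for name in shared:
            tol = query.tolerances.get(name[0], 1.0)
            terms.append(((query.queryShifts[name] - shifts[name]) / tol) ** 2)
        score = math.sqrt(sum(terms) / len(terms))
        scored.append((candidate, score))
    scored.sort(key=lambda item: (item[1], str(item[0].pid)))
    return scored


def extendStretch(stretch: NmrChain, direction: str,
                  candidates: list[NmrResidue], shiftList: ChemicalShiftList,
                  tolerances: dict[str, float] | None = None,
                  atomNames=("CA", "CB"),
                  ) -> tuple[NmrChain, NmrResidue | None]:
    """Grow a connected stretch one residue in the given direction.

    Matches from the terminal residue and connects the top-ranked candidate;
    with no usable query shifts or no scoreable candidate the stretch is
    returned unchanged with ``None``.
    """
    mains = stretch.mainNmrResidues
    if not mains or not stretch.isConnected:
        raise ValueError("stretch must be a non-empty connected NmrChain")
    terminal = mains[0] if direction == "i_minus_1" else mains[-1]

    queryShifts: dict[str, float] = {}
    if direction == "i_minus_1":
        minusOne = next((c for c in terminal.offsetNmrResidues if c.offset == -1),
                        None)
        source = minusOne
    else:
        source = terminal
    if source is not None:
        for name in atomNames:
            value = shiftList.shiftValue(source.getNmrAtom(name))
            if value is not None:
                queryShifts[name] = value
    if not queryShifts:
        return stretch, None

    query = StripQuery(queryShifts, direction, queryNmrResidue=terminal,
                       tolerances=tolerances or {})
    ranked = matchStrips(query, candidates, shiftList)
    if not ranked:
        return stretch, None
    best = ranked[0][0]
    if direction == "i_minus_1":
        chain = connectStretch(best, terminal, "i_plus_1")
    else:
        chain = connectStretch(terminal, best, "i_plus_1")
    return chain, best


def predictAtomSelector(peaks: list[PeakRecord],
                        expType: ExperimentType | str,
                        refTable: ReferenceShiftTable = DEFAULT_TABLE
                        ) -> list[tuple[str, int, float]]:
    """Predict which atom an unassigned peak dimension corresponds to.

    Candidates are the (atom, offset) pairs of the experiment's expected
    pattern with atom in {CA, CB, HA, HB}; each is scored by the equal-weight
    mixture likelihood of the mean unassigned-dimension shift under the
    reference distributions of that atom over the 20 residue types, times a
    soft sign-consistency factor (×0.1 when the observed height sign
    contradicts the pattern sign).  Scores are normalised to sum to 1,
    descending.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    if isinstance(expType, str):
        expType = getExperimentType(expType)

    ndim = peaks[0].dimensionCount
    unassigned = [d for d in range(ndim)
                  if all(not p.assignments[d] for p in peaks)]
    if not unassigned:
        raise ValueError("peaks have no common unassigned dimension")
    dim = unassigned[0]
    if expType.patternAxis is not None and len(unassigned) > 1:
        try:
            dim = list(expType.axisCodes).index(expType.patternAxis)
        except ValueError:
            pass

    meanShift = sum(p.position[dim] for p in peaks) / len(peaks)
    meanHeight = sum(p.height for p in peaks) / len(peaks)
    observedSign = 1 if meanHeight >= 0 else -1

    types = refTable.residueTypes
    results = []
    for entry in expType.expectedPattern:
        if entry.atomName not in _SELECTOR_ATOMS:
            continue
        density = 0.0
        for residueType in types:
            stats = refTable.get(residueType, entry.atomName)
            if stats is not None:
                density += norm.pdf(meanShift, loc=stats[0], scale=stats[1])
        density /= len(types)
        factor = 1.0 if entry.sign == observedSign else _SIGN_MISMATCH_FACTOR
        results.append((entry.atomName, entry.offset, density * factor))
    total = sum(score for *_, score in results)
    if total > 0:
        results = [(a, o, s / total) for a, o, s in results]
    results.sort(key=lambda item: (-item[2], item[0], item[1]))
    return results
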