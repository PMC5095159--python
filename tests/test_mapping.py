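"""Residue-type prediction and Bayesian stretch-to-sequence mapping."""
import math

import numpy as np
import pytest

from assignkit.errors import ConflictError
from assignkit.io.fasta import makeChain
from assignkit.mapping import (assignStretch, mapStretchToSequence,
                               predictResidueType, typeLogLikelihood)
from assignkit.model import Project, connectStretch, startStretch
from assignkit.refshifts import DEFAULT_TABLE
from assignkit.simulate import buildSpinSystems, simulateShifts

from conftest import randomSequence


def _spinSystem(project, shiftList, shifts):
    residue = project.fetchNmrChain().newNmrResidue()
    for name, value in shifts.items():
        shiftList.setShift(residue.fetchNmrAtom(name), value)
    return residue


# -- residue type prediction ----------------------------------------------

def test_shifts_at_alanine_means_rank_alanine_first(project):
    shiftList = project.newChemicalShiftList("d")
    ca, _ = DEFAULT_TABLE.get("ALA", "CA")
    cb, _ = DEFAULT_TABLE.get("ALA", "CB")
    residue = _spinSystem(project, shiftList, {"CA": ca, "CB": cb})
    ranked = predictResidueType(residue, shiftList)
    assert ranked[0][0] == "ALA"
    assert sum(p for _, p in ranked) == pytest.approx(1.0)


def test_glycine_recognised_by_low_CA_without_CB(project):
    shiftList = project.newChemicalShiftList("d")
    ca, _ = DEFAULT_TABLE.get("GLY", "CA")
    residue = _spinSystem(project, shiftList, {"CA": ca})
    ranked = predictResidueType(residue, shiftList)
    # brute-force posterior over the 20 types
    logs = {t: typeLogLikelihood({"CA": ca}, t) for t in DEFAULT_TABLE.residueTypes}
    best = max(logs, key=logs.get)
    assert ranked[0][0] == best == "GLY"
    norm = math.log(sum(math.exp(v - max(logs.values())) for v in logs.values())) \
        + max(logs.values())
    for residueType, prob in ranked:
        assert prob == pytest.approx(math.exp(logs[residueType] - norm))


def test_observed_cb_vetoes_glycine(project):
    shiftList = project.newChemicalShiftList("d")
    ca, _ = DEFAULT_TABLE.get("GLY", "CA")
    residue = _spinSystem(project, shiftList, {"CA": ca, "CB": 33.0})
    ranked = predictResidueType(residue, shiftList)
    assert ranked[0][0] != "GLY"


def test_prior_changes_weights_not_support(project):
    shiftList = project.newChemicalShiftList("d")
    residue = _spinSystem(project, shiftList, {"CA": 56.0, "CB": 30.0})
    uniform = dict(predictResidueType(residue, shiftList))
    prior = {t: (2.0 if t == "LYS" else 0.5) for t in DEFAULT_TABLE.residueTypes}
    total = sum(prior.values())
    prior = {t: v / total for t, v in prior.items()}
    weighted = dict(predictResidueType(residue, shiftList, prior=prior))
    assert set(uniform) == set(weighted)
    assert weighted["LYS"] > uniform["LYS"]


def test_no_usable_shifts_rejected(project):
    shiftList = project.newChemicalShiftList("d")
    residue = project.fetchNmrChain().newNmrResidue()
    with pytest.raises(ValueError):
        predictResidueType(residue, shiftList)


# -- stretch placement ----------------------------------------------------

def _stretchFromTruth(project, truth, shiftList, indices):
    """Connected stretch of the spin systems at the given sequence indices."""
    systems = buildSpinSystems(project, truth, shiftList, seed=truth.seed + 1,
                               shuffle=False)
    byIndex = {index: residue for residue, index in systems}
    stretch = startStretch(byIndex[indices[0]])
    for previous, current in zip(indices, indices[1:]):
        connectStretch(byIndex[previous], byIndex[current], "i_plus_1")
    return stretch, byIndex


def test_noiseless_stretch_places_at_true_position():
    rng = np.random.default_rng(41)
    sequence = randomSequence(rng, 30)
    project = Project("place")
    chain = makeChain(project, sequence, "A")
    truth = simulateShifts(sequence, seed=42)
    shiftList = project.newChemicalShiftList("default")
    stretch, _ = _stretchFromTruth(project, truth, shiftList,
                                   indices=list(range(10, 15)))
    placements = mapStretchToSequence(stretch, chain, shiftList)
    assert placements[0].startResidue.sequenceCode == "10"
    assert placements[0].posterior > 0.99
    assert sum(p.posterior for p in placements) == pytest.approx(1.0, abs=1e-9)


def test_poly_alanine_gives_uniform_posteriors():
    project = Project("polyA")
    chain = makeChain(project, "A" * 12, "A")
    truth = simulateShifts("A" * 12, seed=43)
    shiftList = project.newChemicalShiftList("default")
    stretch, _ = _stretchFromTruth(project, truth, shiftList,
                                   indices=[3, 4, 5, 6])
    placements = mapStretchToSequence(stretch, chain, shiftList)
    feasible = 12 - 4 + 1
    assert len(placements) == feasible
    for placement in placements:
        assert placement.posterior == pytest.approx(1.0 / feasible)


def test_short_stretch_returns_no_placements():
    project = Project("short")
    chain = makeChain(project, "KLAETSVDRF", "A")
    truth = simulateShifts("KLAETSVDRF", seed=44)
    shiftList = project.newChemicalShiftList("default")
    stretch, _ = _stretchFromTruth(project, truth, shiftList, indices=[2, 3, 4])
    assert mapStretchToSequence(stretch, chain, shiftList) == []


def test_stretch_longer_than_chain_returns_empty():
    project = Project("long")
    chain = makeChain(project, "KLAE", "A")
    truth = simulateShifts("KLAETS", seed=45)
    shiftList = project.newChemicalShiftList("default")
    stretch, _ = _stretchFromTruth(project, truth, shiftList,
                                   indices=[1, 2, 3, 4, 5])
    assert mapStretchToSequence(stretch, chain, shiftList) == []


def test_log_domain_stays_finite_for_long_stretches():
    rng = np.random.default_rng(46)
    sequence = randomSequence(rng, 200)
    project = Project("long200")
    chain = makeChain(project, sequence, "A")
    truth = simulateShifts(sequence, seed=47)
    shiftList = project.newChemicalShiftList("default")
    stretch, _ = _stretchFromTruth(project, truth, shiftList,
                                   indices=list(range(1, 201)))
    placements = mapStretchToSequence(stretch, chain, shiftList)
    assert len(placements) == 1
    assert math.isfinite(placements[0].logLikelihood)
    assert placements[0].posterior == pytest.approx(1.0)


def test_recovery_rate_under_noise_at_least_80_percent():
    """Top-1 placement recovery over 50 seeded noisy simulations."""
    rng = np.random.default_rng(48)
    hits = 0
    for trial in range(50):
        sequence = randomSequence(rng, 30)
        project = Project(f"noisy{trial}")
        chain = makeChain(project, sequence, "A")
        truth = simulateShifts(sequence, seed=3000 + trial)
        shiftList = project.newChemicalShiftList("default")
        systems = buildSpinSystems(project, truth, shiftList,
                                   noiseSd={"C": 0.4}, seed=4000 + trial,
                                   shuffle=False)
        byIndex = {index: residue for residue, index in systems}
        start = int(rng.integers(1, 26))
        indices = list(range(start, start + 5))
        if any(i not in byIndex for i in indices):
            continue       # proline-free alphabet, never happens
        stretch = startStretch(byIndex[indices[0]])
        for previous, current in zip(indices, indices[1:]):
            connectStretch(byIndex[previous], byIndex[current], "i_plus_1")
        placements = mapStretchToSequence(stretch, chain, shiftList)
        if placements and placements[0].startResidue.sequenceCode == str(start):
            hits += 1
    assert hits >= 40


def test_placements_exclude_already_assigned_windows():
    project = Project("excl")
    chain = makeChain(project, "A" * 12, "A")
    truth = simulateShifts("A" * 12, seed=49)
    shiftList = project.newChemicalShiftList("default")
    stretch, _ = _stretchFromTruth(project, truth, shiftList, indices=[3, 4, 5, 6])
    blocker = project.fetchNmrChain().newNmrResidue()
    from assignkit.model import assignNmrResidue
    assignNmrResidue(blocker, chain.getResidue("2"))
    placements = mapStretchToSequence(stretch, chain, shiftList)
    # windows covering residue 2 are gone: feasible starts are 3..9
    starts = {p.startResidue.sequenceCode for p in placements}
    assert starts == {str(i) for i in range(3, 10)}


# -- stretch assignment ---------------------------------------------------

def test_assign_stretch_sets_all_predicates():
    project = Project("assign")
    chain = makeChain(project, "KLAETSVDRFHM", "A")
    truth = simulateShifts("KLAETSVDRFHM", seed=50)
    shiftList = project.newChemicalShiftList("default")
    stretch, byIndex = _stretchFromTruth(project, truth, shiftList,
                                         indices=[5, 6, 7, 8, 9])
    assigned = assignStretch(stretch, chain, chain.getResidue("5"))
    assert len(assigned) == 5
    assert all(r.isAssigned for r in assigned)
    assert [r.sequenceCode for r in assigned] == ["5", "6", "7", "8", "9"]


def test_overlapping_assignment_is_atomic():
    project = Project("atomic")
    chain = makeChain(project, "KLAETSVDRFHM", "A")
    truth = simulateShifts("KLAETSVDRFHM", seed=51)
    shiftList = project.newChemicalShiftList("default")
    stretchA, _ = _stretchFromTruth(project, truth, shiftList,
                                    indices=[5, 6, 7, 8, 9])
    assignStretch(stretchA, chain, chain.getResidue("5"))
    # second, overlapping stretch from an independent scenario
    project2 = Project("atomic2")
    chain2 = makeChain(project2, "KLAETSVDRFHM", "A")
    shiftList2 = project2.newChemicalShiftList("default")
    stretchB, _ = _stretchFromTruth(project2, truth, shiftList2,
                                    indices=[1, 2, 3, 4])
    assignStretch(stretchB, chain2, chain2.getResidue("1"))
    # within the first project: a second stretch overlapping residue 9
    shiftList3 = project.newChemicalShiftList("extra")
    chainNC = project.fetchNmrChain()
    others = [chainNC.newNmrResidue() for _ in range(4)]
    for r in others:
        shiftList3.setShift(r.fetchNmrAtom("CA"), 50.0)
    stretchC = startStretch(others[0])
    for a, b in zip(others, others[1:]):
        connectStretch(a, b, "i_plus_1")
    with pytest.raises(ConflictError):
        assignStretch(stretchC, chain, chain.getResidue("9"))
    assert all(not r.isAssigned for r in others)


def test_deassign_then_reassign_elsewhere_succeeds():
    project = Project("re")
    chain = makeChain(project, "A" * 10, "A")
    residue = project.fetchNmrChain().newNmrResidue()
    from assignkit.model import assignNmrResidue, deassign
    assignNmrResidue(residue, chain.getResidue("3"))
    deassign(residue)
    assignNmrResidue(residue, chain.getResidue("7"))
    assert residue.isAssigned
    assert residue.sequenceCode == "7"
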