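"""Shared fixtures: small populated projects and simulated assignment states."""
from __future__ import annotations

import numpy as np
import pytest

from assignkit.io.fasta import makeChain
from assignkit.model import Project
from assignkit.simulate import buildSpinSystems, simulateShifts

AMIDE_AA = "ARNDCQEGHILKMFSTWYV"      # one-letter codes minus proline


def randomSequence(rng: np.random.Generator, length: int,
                   alphabet: str = AMIDE_AA) -> str:
    return "".join(rng.choice(list(alphabet)) for _ in range(length))


@pytest.fixture
def project() -> Project:
    return Project("test")


@pytest.fixture
def populatedProject() -> Project:
    """A small project exercising every branch of the hierarchy."""
    p = Project("populated")
    makeChain(p, "GASKLV", "A")
    spectrum = p.newSpectrum("hsqc", ("Hn", "Nh"))
    peakList = spectrum.newPeakList()
    nmrChain = p.fetchNmrChain()
    shiftList = p.newChemicalShiftList("default")
    r1 = nmrChain.newNmrResidue()
    r1.fetchOffsetNmrResidue(-1)
    h, n = r1.fetchNmrAtom("H"), r1.fetchNmrAtom("N")
    peakList.newPeak((8.2, 118.0), 4.5, [[h], [n]])
    shiftList.setShift(h, 8.2)
    shiftList.setShift(n, 118.0)
    p.newSpectrumGroup("triples")
    sample = p.newSample("s1")
    sample.newChild(type(sample).childClasses[0], "protein")
    p.newSubstance("substance1")
    p.newComplex("complex1")
    dataSet = p.newDataSet("run1")
    rl = dataSet.newChild(type(dataSet).childClasses[0], "distances")
    rl.newChild(type(rl).childClasses[0], "r1")
    ensemble = p.newStructureEnsemble("ens1")
    ensemble.newChild(type(ensemble).childClasses[0], "model1")
    p.newNote("note1")
    return p


@pytest.fixture
def assignmentScenario():
    """Project + ground truth + spin systems for a 12-residue protein."""
    p = Project("scenario")
    sequence = "KLAETSVDRFHM"
    chain = makeChain(p, sequence, "A")
    truth = simulateShifts(sequence, seed=11)
    shiftList = p.newChemicalShiftList("default")
    systems = buildSpinSystems(p, truth, shiftList, seed=12)
    return {"project": p, "chain": chain, "truth": truth,
            "shiftList": shiftList, "systems": systems,
            "sequence": sequence}
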