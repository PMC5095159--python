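"""FASTA sequences -> molecular Chains."""
from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..errors import AssignKitError
from ..model import Chain, Project

__all__ = ["readFasta", "writeFasta", "makeChain", "ONE_TO_THREE", "THREE_TO_ONE"]

ONE_TO_THREE = {one: three.upper() for one, three in protein_letters_1to3.items()}
THREE_TO_ONE = {three: one for one, three in ONE_TO_THREE.items()}


class FastaError(AssignKitError, ValueError):
    pass


def readFasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, one-letter sequence) pairs."""
    with open(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def writeFasta(entries: list[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def makeChain(project: Project, sequence: str, chainCode: str = "A",
              startNumber: int = 1) -> Chain:
    """Create a Chain from a one-letter sequence, one Residue per letter.

    Residues are numbered consecutively from ``startNumber`` and carry the
    upper-case three-letter type; unknown letters are rejected with their
    position.
    """
    sequence = sequence.upper()
    bad = [(i + 1, c) for i, c in enumerate(sequence) if c not in ONE_TO_THREE]
    if bad:
        detail = ", ".join(f"{c!r} at position {i}" for i, c in bad)
        raise FastaError(f"non-amino-acid letter(s): {detail}")
    chain = project.newChain(chainCode)
    for i, letter in enumerate(sequence):
        chain.newResidue(str(startNumber + i), ONE_TO_THREE[letter])
    return chain


def chainSequence(chain: Chain) -> str:
    """One-letter sequence of a Chain (X for non-standard types)."""
    return "".join(THREE_TO_ONE.get(r.residueType, "X") for r in chain.residues)
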