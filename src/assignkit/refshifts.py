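"""Reference chemical-shift statistics for the 20 standard amino acids.

Per (residue type, atom name) mean and standard deviation of the chemical
shift in ppm, covering the backbone and beta atoms H, N, CA, CB, HA, HB.
The values are random-coil-centred statistics of the kind tabulated from
large shift databases; they drive three things that must stay mutually
consistent: the synthetic-shift generator, the residue-type predictor and
the atom-selector likelihoods.

Structural absences are real absences: glycine has no CB/HB entry and
proline has no amide-proton entry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ReferenceShiftTable", "DEFAULT_TABLE", "STANDARD_RESIDUE_TYPES"]

# (mean ppm, sd ppm) per residue type and atom. HB entries for residues with
# two beta protons use the averaged HB shift.
_REFERENCE_SHIFTS: dict[str, dict[str, tuple[float, float]]] = {
    "ALA": {"H": (8.19, 0.60), "N": (123.2, 3.5), "CA": (53.1, 2.0),
            "CB": (19.0, 1.9), "HA": (4.26, 0.44), "HB": (1.35, 0.26)},
    "ARG": {"H": (8.23, 0.61), "N": (120.8, 3.7), "CA": (56.8, 2.3),
            "CB": (30.7, 1.8), "HA": (4.30, 0.46), "HB": (1.79, 0.27)},
    "ASN": {"H": (8.33, 0.63), "N": (118.9, 4.0), "CA": (53.5, 1.9),
            "CB": (38.7, 1.7), "HA": (4.67, 0.36), "HB": (2.81, 0.32)},
    "ASP": {"H": (8.31, 0.58), "N": (120.6, 3.9), "CA": (54.7, 2.0),
            "CB": (40.9, 1.6), "HA": (4.59, 0.32), "HB": (2.72, 0.26)},
    "CYS": {"H": (8.38, 0.67), "N": (120.1, 4.6), "CA": (58.2, 3.3),
            "CB": (32.8, 6.1), "HA": (4.69, 0.57), "HB": (2.95, 0.45)},
    "GLN": {"H": (8.22, 0.59), "N": (119.9, 3.6), "CA": (56.6, 2.2),
            "CB": (29.2, 1.8), "HA": (4.27, 0.44), "HB": (2.05, 0.26)},
    "GLU": {"H": (8.33, 0.59), "N": (120.6, 3.5), "CA": (57.4, 2.1),
            "CB": (30.0, 1.7), "HA": (4.25, 0.41), "HB": (2.03, 0.22)},
    "GLY": {"H": (8.33, 0.64), "N": (109.6, 3.9), "CA": (45.4, 1.3),
            "HA": (3.96, 0.37)},
    "HIS": {"H": (8.25, 0.68), "N": (119.6, 4.0), "CA": (56.5, 2.3),
            "CB": (30.2, 2.1), "HA": (4.61, 0.44), "HB": (3.10, 0.36)},
    "ILE": {"H": (8.26, 0.69), "N": (121.5, 4.3), "CA": (61.6, 2.7),
            "CB": (38.6, 2.0), "HA": (4.17, 0.57), "HB": (1.78, 0.30)},
    "LEU": {"H": (8.22, 0.65), "N": (121.9, 3.9), "CA": (55.6, 2.1),
            "CB": (42.3, 1.9), "HA": (4.32, 0.47), "HB": (1.62, 0.33)},
    "LYS": {"H": (8.18, 0.60), "N": (121.1, 3.8), "CA": (56.9, 2.2),
            "CB": (32.8, 1.8), "HA": (4.26, 0.44), "HB": (1.78, 0.25)},
    "MET": {"H": (8.26, 0.59), "N": (120.1, 3.6), "CA": (56.1, 2.2),
            "CB": (32.9, 2.3), "HA": (4.41, 0.48), "HB": (2.03, 0.35)},
    "PHE": {"H": (8.36, 0.72), "N": (120.5, 4.2), "CA": (58.1, 2.6),
            "CB": (39.9, 2.1), "HA": (4.62, 0.57), "HB": (2.99, 0.37)},
    "PRO": {"N": (136.7, 4.5), "CA": (63.3, 1.5),
            "CB": (31.8, 1.2), "HA": (4.40, 0.33), "HB": (2.07, 0.35)},
    "SER": {"H": (8.29, 0.59), "N": (116.3, 3.6), "CA": (58.7, 2.1),
            "CB": (63.8, 1.5), "HA": (4.48, 0.40), "HB": (3.87, 0.26)},
    "THR": {"H": (8.24, 0.62), "N": (115.5, 4.8), "CA": (62.2, 2.6),
            "CB": (69.6, 1.6), "HA": (4.45, 0.48), "HB": (4.16, 0.33)},
    "TRP": {"H": (8.28, 0.79), "N": (121.7, 4.1), "CA": (57.7, 2.6),
            "CB": (29.9, 2.0), "HA": (4.69, 0.52), "HB": (3.18, 0.36)},
    "TYR": {"H": (8.31, 0.73), "N": (120.5, 4.3), "CA": (58.1, 2.5),
            "CB": (39.3, 2.2), "HA": (4.62, 0.55), "HB": (2.90, 0.37)},
    "VAL": {"H": (8.27, 0.67), "N": (121.1, 4.6), "CA": (62.5, 2.9),
            "CB": (32.7, 1.8), "HA": (4.17, 0.58), "HB": (1.98, 0.31)},
}

STANDARD_RESIDUE_TYPES: tuple[str, ...] = tuple(sorted(_REFERENCE_SHIFTS))

#: Atom names the table may carry, in canonical order.
TABLE_ATOMS: tuple[str, ...] = ("H", "N", "CA", "CB", "HA", "HB")


@dataclass(frozen=True)
class ReferenceShiftTable:
    """Mapping (residueType, atomName) -> (mean ppm, sd ppm).

    All sds are strictly positive; a missing entry means the atom does not
    exist in that residue type (GLY CB/HB, PRO H).
    """

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (_, sd) in self.entries.items():
            if sd <= 0:
                raise ValueError(f"non-positive sd for {key}")

    @classmethod
    def default(cls) -> "ReferenceShiftTable":
        entries = {
            (res, atom): stats
            for res, atoms in _REFERENCE_SHIFTS.items()
            for atom, stats in atoms.items()
        }
        return cls(entries)

    @property
    def residueTypes(self) -> tuple[str, ...]:
        return tuple(sorted({res for res, _ in self.entries}))

    def atoms(self, residueType: str) -> tuple[str, ...]:
        """Atom names defined for a residue type, in canonical order."""
        present = {atom for res, atom in self.entries if res == residueType}
        return tuple(a for a in TABLE_ATOMS if a in present)

    def get(self, residueType: str, atomName: str) -> tuple[float, float] | None:
        return self.entries.get((residueType, atomName))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries


DEFAULT_TABLE = ReferenceShiftTable.default()
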