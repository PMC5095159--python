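"""CSV peak lists.

Fixed column layout: ``serial``, one ``pos_<axisCode>`` per dimension,
``height``, one ``assign_<axisCode>`` per dimension holding
semicolon-separated NmrAtom PIDs (empty when unassigned).
"""
from __future__ import annotations

import pandas as pd

from ..errors import UnsupportedFormatError
from ..records import PeakRecord

__all__ = ["readPeakListCsv", "writePeakListCsv", "peaksToFrame", "frameToPeaks"]


def peaksToFrame(peaks: list[PeakRecord], axisCodes) -> pd.DataFrame:
    axisCodes = tuple(axisCodes)
    rows = []
    for peak in peaks:
        if peak.dimensionCount != len(axisCodes):
            raise ValueError("peak dimensionality does not match axis codes")
        row: dict[str, object] = {"serial": peak.serial}
        for code, pos in zip(axisCodes, peak.position):
            row[f"pos_{code}"] = pos
        row["height"] = peak.height
        for code, pids in zip(axisCodes, peak.assignments):
            row[f"assign_{code}"] = ";".join(pids)
        rows.append(row)
    columns = (["serial"] + [f"pos_{c}" for c in axisCodes] + ["height"]
               + [f"assign_{c}" for c in axisCodes])
    return pd.DataFrame(rows, columns=columns)


def frameToPeaks(frame: pd.DataFrame) -> tuple[list[PeakRecord], tuple[str, ...]]:
    axisCodes = tuple(c[len("pos_"):] for c in frame.columns if c.startswith("pos_"))
    if not axisCodes:
        raise UnsupportedFormatError("CSV has no pos_<axisCode> columns")
    peaks = []
    for _, row in frame.iterrows():
        assignments = []
        for code in axisCodes:
            cell = row.get(f"assign_{code}", "")
            cell = "" if pd.isna(cell) else str(cell)
            assignments.append(tuple(p for p in cell.split(";") if p))
        peaks.append(PeakRecord(
            serial=int(row["serial"]),
            position=tuple(float(row[f"pos_{c}"]) for c in axisCodes),
            height=float(row["height"]),
            assignments=tuple(assignments),
        ))
    return peaks, axisCodes


def writePeakListCsv(peaks: list[PeakRecord], axisCodes, path) -> None:
    peaksToFrame(peaks, axisCodes).to_csv(path, index=False, float_format="%.6f")


def readPeakListCsv(path) -> tuple[list[PeakRecord], tuple[str, ...]]:
    frame = pd.read_csv(path, keep_default_na=False)
    return frameToPeaks(frame)
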