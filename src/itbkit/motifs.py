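"""Tyrosine-motif scanning for integrin beta cytosolic tails.

Beta-subunit tails carry two four-residue tyrosine motifs recognised by
phosphotyrosine-binding adaptors: a membrane-proximal NPxY and a membrane-
distal NxxY.  NPxY is a special case of NxxY, so a window that matches NPxY
is reported once, as NPxY, never double-counted as NxxY.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    motif_class: str  # "NPXY" or "NXXY"
    start: int  # 1-based position of the motif's N
    matched_text: str

    def __post_init__(self) -> None:
        if self.motif_class not in ("NPXY", "NXXY"):
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if len(self.matched_text) != 4:
            raise ValueError("motif hits are 4-mers")


def scan_cyto_motifs(sequence: str, record_id: str = "") -> list[MotifHit]:
    """Find all NPxY / NxxY windows, left to right, overlaps allowed.

    A window N..Y with P at the second position is classified NPXY; any other
    N..Y window is NXXY.
    """
    if not sequence:
        raise ValueError("empty sequence")
    hits = []
    for i in range(len(sequence) - 3):
        window = sequence[i : i + 4]
        if window[0] == "N" and window[3] == "Y":
            cls = "NPXY" if window[1] == "P" else "NXXY"
            hits.append(
                MotifHit(record_id=record_id, motif_class=cls, start=i + 1, matched_text=window)
            )
    return hits
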