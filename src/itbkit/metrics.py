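"""Per-gene and per-protein summary metrics.

Gene spans in kilobases, average-mass molecular weight, and theoretical
isoelectric point by bisection over a Henderson--Hasselbalch net-charge
function with the Bjellqvist/Expasy pKa set.
"""

from __future__ import annotations

from .records import GeneModel

# Average (not monoisotopic) residue masses, Da; free water added once per chain.
WATER_MASS = 18.0153

RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist pKa set (as popularised by the Expasy pI tool): side chains plus
# free termini, with residue-specific adjustments for terminal D/E (C-term)
# and several N-terminal residues.
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}


def gene_span_kb(gene: GeneModel) -> float:
    """Gene size in kilobases, one decimal, from 1-based inclusive coordinates."""
    return round(gene.span_bp / 1000.0, 1)


def molecular_weight(sequence: str) -> float:
    """Average-mass molecular weight (Da) of an unmodified peptide chain.

    The ambiguity code X carries no defined mass; callers must mask or reject
    such sequences first.
    """
    if not sequence:
        raise ValueError("empty sequence")
    mass = WATER_MASS
    for pos, ch in enumerate(sequence, start=1):
        try:
            mass += RESIDUE_MASSES[ch]
        except KeyError:
            raise ValueError(
                f"residue {ch!r} at position {pos} has no defined mass"
            ) from None
    return mass


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH (Henderson--Hasselbalch per group)."""
    if not sequence:
        raise ValueError("empty sequence")
    counts: dict[str, int] = {}
    for ch in sequence:
        counts[ch] = counts.get(ch, 0) + 1

    def positive(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def negative(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = positive(PK_NTERMINAL.get(sequence[0], POSITIVE_PKS["Nterm"]))
    charge += negative(PK_CTERMINAL.get(sequence[-1], NEGATIVE_PKS["Cterm"]))
    for aa in ("K", "R", "H"):
        if counts.get(aa):
            charge += counts[aa] * positive(POSITIVE_PKS[aa])
    for aa in ("D", "E", "C", "Y"):
        if counts.get(aa):
            charge += counts[aa] * negative(NEGATIVE_PKS[aa])
    return charge


def isoelectric_point(sequence: str, tol: float = 0.01) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the zero is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
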