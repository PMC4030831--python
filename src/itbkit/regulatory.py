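"""Regulatory-element detectors: CpG islands and miRNA seed sites.

CpG islands follow the classical Gardiner-Garden & Frommer criteria that
also underlie common genome-browser tracks: a region of at least 200 bp with
G+C fraction >= 0.5 and observed/expected CpG ratio >= 0.6, where

    obs/exp = (#CG dinucleotides x length) / (#C x #G).

Detection is seed-and-extend over fixed-size windows; N acts as a hard mask.

miRNA target sites are classified by canonical seed-match types on the 3'
UTR: the seed is miRNA positions 2-8 (5'->3'), a 7mer-m8 site is a UTR match
to the reverse complement of positions 2-8, an 8mer adds an adenine across
from position 1, and a 7mer-A1 matches positions 2-7 plus that adenine.
Each occurrence is reported once with its strongest classification
(8mer > 7mer-m8 > 7mer-A1); bare 6mer matches are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")
_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class NucleotideSequence:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse complement; RNA input (U) is treated as DNA (T)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CpGIsland:
    start: int  # 1-based inclusive
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    cpg_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG dinucleotide ratio of a window."""
    c = window.count("C")
    g = window.count("G")
    if c == 0 or g == 0:
        raise ValueError("obs/exp CpG is undefined without both C and G")
    return window.count("CG") * len(window) / (c * g)


def _window_stats(window: str) -> tuple[float, float, int]:
    c = window.count("C")
    g = window.count("G")
    cpg = window.count("CG")
    gc = (c + g) / len(window)
    oe = cpg * len(window) / (c * g) if c and g else 0.0
    return gc, oe, cpg


def _passes(window: str, min_gc: float, min_obs_exp: float) -> bool:
    if "N" in window:
        return False
    gc, oe, _ = _window_stats(window)
    return gc >= min_gc and oe >= min_obs_exp


def find_cpg_islands(
    seq: NucleotideSequence | str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    window: int = 150,
) -> list[CpGIsland]:
    """Seed-and-extend CpG-island detection.

    Every ``window``-sized stretch meeting both thresholds seeds a candidate;
    overlapping or adjacent seed windows are merged, candidates are snapped
    to their outermost CpG dinucleotides (the scan window overhangs GC-poor
    flanks by up to half its width, and an island boundary without a CpG is
    all flank), trimmed until the whole region satisfies the thresholds, and
    reported if at least ``min_length`` long.  A scan window shorter than
    the minimum island length sharpens boundaries, as in classical island
    scanners.  Windows containing N never seed or join an island.
    """
    s = seq.sequence if isinstance(seq, NucleotideSequence) else seq
    n = len(s)
    window = min(window, min_length)
    if n < min_length:
        return []

    # Seed windows, collected as merged [start, end) candidate intervals.
    candidates: list[list[int]] = []
    for i in range(n - window + 1):
        w = s[i : i + window]
        if not _passes(w, min_gc, min_obs_exp):
            continue
        if candidates and i <= candidates[-1][1]:
            candidates[-1][1] = i + window
        else:
            candidates.append([i, i + window])

    islands = []
    for start, end in candidates:
        # Snap boundaries to the outermost CpG dinucleotides: windowed seeds
        # overhang into the flanks by up to half a window, and an island
        # without a terminal CpG is all flank.
        region = s[start:end]
        first = region.find("CG")
        last = region.rfind("CG")
        if first == -1:
            continue
        start, end = start + first, start + last + 2
        # Boundary refinement: each end of a genuine island must itself look
        # like island over a terminal sub-window; walk a failing boundary
        # inward CpG by CpG.
        k = max(50, min_length // 2)
        moved = True
        while moved and end - start >= min_length:
            moved = False
            if not _passes(s[start : start + k], min_gc, min_obs_exp):
                nxt = s.find("CG", start + 1, end - 1)
                if nxt != -1 and nxt + 2 <= end:
                    start = nxt
                    moved = True
            if not _passes(s[end - k : end], min_gc, min_obs_exp):
                prev = s.rfind("CG", start, end - 2)
                if prev != -1:
                    end = prev + 2
                    moved = True
        # Trim until the whole region passes; seeds guarantee termination at
        # or above min_length.
        while end - start >= min_length and not _passes(s[start:end], min_gc, min_obs_exp):
            gc_left, _, _ = _window_stats(s[start : start + min_length])
            gc_right, _, _ = _window_stats(s[end - min_length : end])
            if gc_left < gc_right:
                start += 1
            else:
                end -= 1
        if end - start < min_length:
            continue
        region = s[start:end]
        gc, oe, cpg = _window_stats(region)
        islands.append(
            CpGIsland(
                start=start + 1,
                end=end,
                gc_fraction=gc,
                obs_exp_cpg=oe,
                cpg_count=cpg,
            )
        )
    return islands


def islands_to_bed(islands: list[CpGIsland], chrom: str = "seq") -> str:
    """BED (0-based half-open) lines named CpG<count> after their CpG count."""
    lines = []
    for isl in islands:
        lines.append(f"{chrom}\t{isl.start - 1}\t{isl.end}\tCpG{isl.cpg_count}")
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class MirnaSite:
    utr_id: str
    mirna_id: str
    site_type: str  # 8mer, 7mer-m8, 7mer-A1
    start: int  # 1-based, leftmost base of the seed-complementary match

    def __post_init__(self) -> None:
        if self.site_type not in ("8mer", "7mer-m8", "7mer-A1"):
            raise ValueError(f"unknown site type {self.site_type!r}")


def scan_mirna_seed_sites(
    utr: NucleotideSequence, mirna_seq: str, mirna_id: str = ""
) -> list[MirnaSite]:
    """Scan a 3' UTR for canonical seed-match sites of one miRNA.

    ``mirna_seq`` is the mature miRNA 5'->3' (RNA or DNA alphabet); it must
    be at least 8 nt.  Sites are anchored on the 6mer core (reverse
    complement of seed positions 2-7) and upgraded by a position-8 match at
    the 5' flank and/or an A across from position 1 at the 3' flank.
    """
    m = mirna_seq.upper().replace("U", "T")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    s = utr.sequence
    core = reverse_complement(m[1:7])  # positions 2-7, 6 nt
    m8_base = reverse_complement(m[7])  # complement of position 8
    sites = []
    for i in range(len(s) - 5):
        if s[i : i + 6] != core:
            continue
        has_m8 = i >= 1 and s[i - 1] == m8_base
        has_a1 = i + 6 < len(s) and s[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start0 = "8mer", i - 1  # include the m8 base
        elif has_m8:
            site_type, start0 = "7mer-m8", i - 1
        elif has_a1:
            site_type, start0 = "7mer-A1", i
        else:
            continue
        sites.append(
            MirnaSite(
                utr_id=utr.id,
                mirna_id=mirna_id,
                site_type=site_type,
                start=start0 + 1,  # 1-based
            )
        )
    return sites


def sites_to_tsv(sites: list[MirnaSite]) -> str:
    lines = ["utr_id\tmirna_id\tsite_type\tstart"]
    for site in sites:
        lines.append(f"{site.utr_id}\t{site.mirna_id}\t{site.site_type}\t{site.start}")
    return "\n".join(lines) + "\n"
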