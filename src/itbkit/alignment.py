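"""Cytosolic-domain extraction, global alignment, identity and consensus.

Pairwise alignment is Needleman--Wunsch with affine (Gotoh) gap costs and a
fixed deterministic tie-break (diagonal, then up, then left) so that repeated
runs are bit-identical.  Multiple alignments are built progressively: each
sequence, in input order, is aligned against the profile of the running
alignment.  Default scoring is BLOSUM62 with gap open 10 / extend 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

from .records import DomainAnnotation, ProteinRecord

GAP = "-"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over an ordered set of protein records.

    ``column_map`` (optional) maps each current column to its index in the
    alignment this one was derived from by column filtering.
    """

    records: tuple[ProteinRecord, ...]
    rows: tuple[str, ...]
    column_map: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.rows):
            raise ValueError("one gapped row required per record")
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0])
        for rec, row in zip(self.records, self.rows):
            if len(row) != n:
                raise ValueError(f"row for {rec.id} has length {len(row)}, expected {n}")
            if row.replace(GAP, "") != rec.sequence:
                raise ValueError(f"row for {rec.id} does not reproduce its sequence")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)


def extract_domain(record: ProteinRecord, ann: DomainAnnotation) -> str:
    """Substring of the record at the annotation's 1-based inclusive interval."""
    if ann.record_id != record.id:
        raise ValueError(f"annotation is for {ann.record_id!r}, not {record.id!r}")
    if ann.end > record.length:
        raise ValueError(
            f"{record.id}: annotation end {ann.end} exceeds length {record.length}"
        )
    return record.sequence[ann.start - 1 : ann.end]


def global_align_pair(
    a: str,
    b: str,
    score=blosum62_score,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gap costs.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``.  Ties are broken
    deterministically: diagonal move first, then a gap in ``b`` (up), then a
    gap in ``a`` (left).  Returns (aligned_a, aligned_b, score).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    NEG = float("-inf")
    # M: a[i] aligned to b[j]; X: gap in b (consumes a, "up"); Y: gap in a ("left").
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = score(a[i - 1], b[j - 1]) + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            )
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )

    best = max(M[n][m], X[n][m], Y[n][m])
    # Traceback; state preference encodes the diagonal > up > left tie-break.
    if M[n][m] == best:
        state = "M"
    elif X[n][m] == best:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i - 1][j - 1]
            target = M[i][j] - score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i][j] - target) < 1e-9:
                state = "M"
            elif abs(X[i][j] - target) < 1e-9:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i][j]
            i -= 1
            if abs(M[i][j] - gap_open - val) < 1e-9:
                state = "M"
            elif abs(X[i][j] - gap_extend - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if abs(M[i][j] - gap_open - val) < 1e-9:
                state = "M"
            elif abs(Y[i][j] - gap_extend - val) < 1e-9:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), best


def _profile_column_scorer(rows: list[str], score) -> list[dict]:
    """Precompute per-column residue counts for profile scoring."""
    cols = []
    for j in range(len(rows[0])):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[j]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        cols.append(counts)
    return cols


def _align_profile_sequence(
    rows: list[str], seq: str, score, gap_open: float, gap_extend: float
) -> tuple[list[str], str]:
    """Globally align one sequence to the profile of existing rows."""
    cols = _profile_column_scorer(rows, score)

    def col_score(j: int, ch: str) -> float:
        counts = cols[j]
        total = sum(counts.values())
        if total == 0:
            return 0.0
        return sum(c * score(res, ch) for res, c in counts.items()) / total

    n, m = len(cols), len(seq)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = col_score(i - 1, seq[j - 1]) + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            )
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
    # Traceback with the same diagonal > up > left preference.
    best = max(M[n][m], X[n][m], Y[n][m])
    state = "M" if M[n][m] == best else ("X" if X[n][m] == best else "Y")
    moves: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        moves.append(state)
        if state == "M":
            target = M[i][j] - col_score(i - 1, seq[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i][j] - target) < 1e-9:
                state = "M"
            elif abs(X[i][j] - target) < 1e-9:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            val = X[i][j]
            i -= 1
            state = "M" if abs(M[i][j] - gap_open - val) < 1e-9 else "X"
        else:
            val = Y[i][j]
            j -= 1
            state = "M" if abs(M[i][j] - gap_open - val) < 1e-9 else "Y"
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    moves.reverse()
    new_rows = ["" for _ in rows]
    new_seq_row = []
    pi = si = 0
    for mv in moves:
        if mv == "M":
            for k, row in enumerate(rows):
                new_rows[k] += row[pi]
            new_seq_row.append(seq[si])
            pi += 1
            si += 1
        elif mv == "X":
            for k, row in enumerate(rows):
                new_rows[k] += row[pi]
            new_seq_row.append(GAP)
            pi += 1
        else:
            for k in range(len(rows)):
                new_rows[k] += GAP
            new_seq_row.append(seq[si])
            si += 1
    return new_rows, "".join(new_seq_row)


def progressive_align(
    records: list[ProteinRecord],
    score=blosum62_score,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Progressive multiple alignment: fold each sequence into the profile.

    Sequences are incorporated in input order; the engine is deliberately
    simple and configurable rather than a reimplementation of any particular
    aligner.
    """
    if not records:
        raise ValueError("no records to align")
    rows = [records[0].sequence]
    for rec in records[1:]:
        rows, new_row = _align_profile_sequence(rows, rec.sequence, score, gap_open, gap_extend)
        rows.append(new_row)
    return MultipleAlignment(records=tuple(records), rows=tuple(rows))


def percent_identity(row_i: str, row_j: str) -> float:
    """100 x identical columns / mutually non-gap columns."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    same = comparable = 0
    for a, b in zip(row_i, row_j):
        if a != GAP and b != GAP:
            comparable += 1
            if a == b:
                same += 1
    if comparable == 0:
        raise ValueError("no mutually non-gap columns")
    return 100.0 * same / comparable


def conserved_column_fraction(msa: MultipleAlignment) -> float:
    """Fraction of columns where every row has the same non-gap residue."""
    conserved = 0
    for j in range(msa.n_columns):
        col = msa.column(j)
        if GAP not in col and len(set(col)) == 1:
            conserved += 1
    return conserved / msa.n_columns


def family_identity_summary(msa: MultipleAlignment) -> dict[str, float]:
    """Min/mean/max pairwise identity plus fully-conserved column fraction."""
    if msa.n_rows < 2:
        raise ValueError("identity summary needs at least two rows")
    idents = []
    for i in range(msa.n_rows):
        for j in range(i + 1, msa.n_rows):
            idents.append(percent_identity(msa.rows[i], msa.rows[j]))
    return {
        "min_identity": min(idents),
        "mean_identity": sum(idents) / len(idents),
        "max_identity": max(idents),
        "conserved_fraction": conserved_column_fraction(msa),
    }


def consensus_sequence(msa: MultipleAlignment) -> str:
    """Columnwise plurality residue; 'X' on ties, '-' for all-gap columns."""
    out = []
    for j in range(msa.n_columns):
        counts: dict[str, int] = {}
        for row in msa.rows:
            ch = row[j]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append(GAP)
            continue
        top = max(counts.values())
        winners = [ch for ch, c in counts.items() if c == top]
        out.append(winners[0] if len(winners) == 1 else "X")
    return "".join(out)


def exclude_ambiguous_columns(
    msa: MultipleAlignment, max_gap_fraction: float = 0.0
) -> MultipleAlignment:
    """Drop columns whose gap fraction exceeds the threshold.

    The default (0.0) removes every column containing any gap, emulating the
    exclusion of alignment-ambiguous regions before distance analysis.
    Retained columns keep their order; their original indices are recorded in
    ``column_map``.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        if col.count(GAP) / msa.n_rows <= max_gap_fraction:
            keep.append(j)
    if not keep:
        raise ValueError("column filtering removed every column")
    new_rows = tuple("".join(row[j] for j in keep) for row in msa.rows)
    # Filtered rows may no longer reproduce the original sequences, so carry
    # stripped surrogate records with the same ids and labels.
    new_records = tuple(
        ProteinRecord(
            id=rec.id,
            sequence=row.replace(GAP, "") or rec.sequence,
            species=rec.species,
            family=rec.family,
        )
        if row.replace(GAP, "")
        else rec
        for rec, row in zip(msa.records, new_rows)
    )
    return MultipleAlignment(records=new_records, rows=new_rows, column_map=tuple(keep))


def read_aligned_fasta(path, metadata: dict[str, dict] | None = None) -> MultipleAlignment:
    """Read an aligned FASTA file (rows padded with '-') into an alignment."""
    from Bio import SeqIO

    metadata = metadata or {}
    records = []
    rows = []
    for entry in SeqIO.parse(str(path), "fasta"):
        row = str(entry.seq).upper()
        meta = metadata.get(entry.id, {})
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=row.replace(GAP, ""),
                species=meta.get("species", ""),
                family=meta.get("family"),
            )
        )
        rows.append(row)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return MultipleAlignment(records=tuple(records), rows=tuple(rows))


def write_aligned_fasta(msa: MultipleAlignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec, row in zip(msa.records, msa.rows):
            fh.write(f">{rec.id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
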