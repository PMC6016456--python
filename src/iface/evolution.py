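"""Sequence-level analysis of a protein-protein interface.

Links a structure's interface residues to columns of a multiple sequence
alignment, calls lineage-specific interface residues (positions where every
sequence of a clade shares one residue that never occurs outside the
clade — e.g. positions specific to great apes), and provides the two
composition/sequence statistics used to contextualize such interfaces:
pairwise percent identity from a global affine-gap alignment and the
isoelectric point from a Henderson-Hasselbalch charge model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError, MappingError

__all__ = [
    "Msa",
    "MsaRow",
    "ResidueMap",
    "CladeCall",
    "map_residues_to_columns",
    "lineage_specific_residues",
    "percent_identity",
    "isoelectric_point",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_MSA_ALPHABET = set(AA20) | {"-", "X"}


@dataclass
class MsaRow:
    id: str
    clade: str
    seq: str


@dataclass
class Msa:
    """Aligned rows with clade labels; alphabet = 20 aa + gap + X."""

    rows: list[MsaRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no rows")
        length = len(self.rows[0].seq)
        for row in self.rows:
            if len(row.seq) != length:
                raise InputError(f"row {row.id!r} has length {len(row.seq)}, expected {length}")
            bad = set(row.seq) - _MSA_ALPHABET
            if bad:
                raise InputError(f"row {row.id!r} contains non-alignment characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0].seq)

    def row(self, row_id: str) -> MsaRow:
        for row in self.rows:
            if row.id == row_id:
                return row
        raise LookupError(f"no alignment row with id {row_id!r}")

    def clade_ids(self, clade: str) -> set[str]:
        return {row.id for row in self.rows if row.clade == clade}


@dataclass
class ResidueMap:
    """Monotone map between structure residue indices and MSA columns (0-based)."""

    residue_to_column: dict[int, int]
    unmatched_residues: list[int] = field(default_factory=list)
    unmatched_columns: list[int] = field(default_factory=list)

    @property
    def column_to_residue(self) -> dict[int, int]:
        return {c: r for r, c in self.residue_to_column.items()}


def map_residues_to_columns(seq: str, row: str) -> ResidueMap:
    """Map structure residues to alignment columns by gap skipping.

    The k-th non-gap character of ``row`` corresponds to the k-th residue of
    the matched stretch of ``seq``; the degapped row must equal ``seq`` or be
    a substring/superstring of it. Unmatched tails (structure residues not
    covered by the row, or row columns not covered by the structure) are
    reported, not silently dropped.
    """
    if not seq:
        raise InputError("empty structure sequence")
    degapped = row.replace("-", "")
    if not degapped:
        raise InputError("alignment row is all gaps")
    columns = [i for i, ch in enumerate(row) if ch != "-"]

    if degapped == seq:
        res_start, row_start, n = 0, 0, len(seq)
    elif degapped in seq:
        res_start, row_start, n = seq.find(degapped), 0, len(degapped)
    elif seq in degapped:
        res_start, row_start, n = 0, degapped.find(seq), len(seq)
    else:
        limit = min(len(seq), len(degapped))
        for k in range(limit):
            if seq[k] != degapped[k]:
                raise MappingError(
                    f"structure sequence and degapped row disagree at aligned "
                    f"position {k}: {seq[k]!r} vs {degapped[k]!r}"
                )
        raise MappingError(
            "structure sequence and degapped alignment row are not "
            "substrings of one another"
        )

    residue_to_column = {
        res_start + k: columns[row_start + k] for k in range(n)
    }
    unmatched_residues = [i for i in range(len(seq)) if i not in residue_to_column]
    mapped_cols = set(residue_to_column.values())
    unmatched_columns = [c for c in columns if c not in mapped_cols]
    return ResidueMap(
        residue_to_column=residue_to_column,
        unmatched_residues=unmatched_residues,
        unmatched_columns=unmatched_columns,
    )


@dataclass
class CladeCall:
    """An alignment column where the clade carries a residue absent elsewhere."""

    column: int
    in_clade_residue: str
    out_clade_residues: tuple[str, ...]
    residue_index: int | None = None  # structure residue index via a ResidueMap


def lineage_specific_residues(
    msa: Msa,
    clade_ids: Iterable[str],
    interface_columns: Iterable[int],
    residue_map: ResidueMap | None = None,
    max_out_clade_freq: float = 0.0,
) -> list[CladeCall]:
    """Interface columns whose residue is specific to a clade.

    A column is called iff every clade row shares one non-gap, non-X residue
    and no out-clade row carries that residue (a gap in any clade row
    disqualifies the column). ``max_out_clade_freq`` relaxes the strict
    absence requirement to a tolerated out-clade frequency; the default 0.0
    is the strict rule.
    """
    clade_ids = set(clade_ids)
    all_ids = {row.id for row in msa.rows}
    if not clade_ids:
        raise InputError("clade must be non-empty")
    if not clade_ids <= all_ids:
        raise InputError(f"unknown clade ids: {sorted(clade_ids - all_ids)}")
    if clade_ids == all_ids:
        raise InputError("clade equals the full row set; specificity is undefined")
    interface_columns = sorted(set(interface_columns))
    if interface_columns and interface_columns[-1] >= msa.length:
        raise InputError(
            f"interface column {interface_columns[-1]} outside alignment of "
            f"length {msa.length}"
        )

    in_rows = [row.seq for row in msa.rows if row.id in clade_ids]
    out_rows = [row.seq for row in msa.rows if row.id not in clade_ids]
    calls: list[CladeCall] = []
    for col in interface_columns:
        in_chars = {s[col] for s in in_rows}
        if len(in_chars) != 1:
            continue
        residue = next(iter(in_chars))
        if residue in ("-", "X"):
            continue
        out_chars = [s[col] for s in out_rows]
        out_freq = out_chars.count(residue) / len(out_chars)
        if out_freq > max_out_clade_freq:
            continue
        calls.append(
            CladeCall(
                column=col,
                in_clade_residue=residue,
                out_clade_residues=tuple(sorted(out_chars)),
                residue_index=(
                    residue_map.column_to_residue.get(col) if residue_map else None
                ),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# percent identity (global affine-gap alignment, Gotoh)


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise InputError(f"{name}: empty sequence")
    bad = set(seq) - set(AA20) - {"X"}
    if bad:
        raise InputError(f"{name}: non-amino-acid characters {sorted(bad)}")


def _gotoh_align(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> tuple[str, str, float]:
    """Global alignment with affine gaps (first gap −open, each further −extend)."""
    n, m = len(a), len(b)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend

    def score(x: str, y: str) -> float:
        if x == "X" or y == "X":
            return 0.0
        return float(matrix[x, y])

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = score(ai, b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)

    # traceback from the best terminal state; ties prefer match, then X, then Y
    states = {"M": M, "X": X, "Y": Y}
    state = max("MXY", key=lambda st: states[st][n, m])
    best = states[state][n, m]
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = score(a[i - 1], b[j - 1])
            target = M[i, j] - s
            for prev in "MXY":
                if abs(states[prev][i - 1, j - 1] - target) < tol:
                    state = prev
                    break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            if abs(M[i - 1, j] - gap_open - X[i, j]) < tol:
                state = "M"
            i -= 1
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            if abs(M[i, j - 1] - gap_open - Y[i, j]) < tol:
                state = "M"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(best)


def identity_from_alignment(aligned_a: str, aligned_b: str) -> float:
    """Percent identity of a pairwise alignment.

    Denominator = alignment columns excluding terminal gap columns; columns
    with X on either side are excluded from numerator and denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise InputError("aligned sequences differ in length")
    # trim terminal gap columns on either end
    start, end = 0, len(aligned_a)
    while start < end and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    while end > start and (aligned_a[end - 1] == "-" or aligned_b[end - 1] == "-"):
        end -= 1
    matches = 0
    columns = 0
    for x, y in zip(aligned_a[start:end], aligned_b[start:end]):
        if x == "X" or y == "X":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        return 0.0
    return round(100.0 * matches / columns, 1)


def percent_identity(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> float:
    """Pairwise percent identity from a global affine-gap alignment.

    The alignment maximizes the substitution-matrix score with gap cost
    open + (k−1)·extend for a gap of length k (end gaps penalized). Identity
    is identical aligned pairs over alignment columns, terminal gap columns
    excluded, reported to 1 decimal.
    """
    _check_protein(a, "a")
    _check_protein(b, "b")
    mat = substitution_matrices.load(matrix)
    aligned_a, aligned_b, _ = _gotoh_align(a, b, mat, gap_open, gap_extend)
    return identity_from_alignment(aligned_a, aligned_b)


def alignment_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> float:
    """Optimal global affine-gap alignment score (for cross-checks)."""
    _check_protein(a, "a")
    _check_protein(b, "b")
    mat = substitution_matrices.load(matrix)
    return _gotoh_align(a, b, mat, gap_open, gap_extend)[2]


# ---------------------------------------------------------------------------
# isoelectric point

# Bjellqvist pKa set: side chains plus residue-specific terminal values.
_PKA_SETS = {
    "Bjellqvist": {
        "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
        "nterm": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
        "nterm_default": 7.5,
        "cterm": {"D": 4.55, "E": 4.75},
        "cterm_default": 3.55,
    }
}


def net_charge(seq: str, ph: float, pka_set: str = "Bjellqvist") -> float:
    """Net charge Z(pH) of a peptide from the Henderson-Hasselbalch equation.

    Counts the free termini plus the ionizable side chains D, E, C, Y, H, K,
    R; X positions contribute nothing. Disulfides are ignored (Cys counted
    as free).
    """
    _check_protein(seq, "seq")
    pka = _PKA_SETS[pka_set]
    comp = Counter(seq)
    z = 0.0
    nterm_pka = pka["nterm"].get(seq[0], pka["nterm_default"])
    z += 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    for res, pk in pka["positive"].items():
        z += comp[res] / (1.0 + 10 ** (ph - pk))
    cterm_pka = pka["cterm"].get(seq[-1], pka["cterm_default"])
    z -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for res, pk in pka["negative"].items():
        z -= comp[res] / (1.0 + 10 ** (pk - ph))
    return z


def isoelectric_point(seq: str, pka_set: str = "Bjellqvist", tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge is zero, by bisection on [0, 14].

    Z(pH) is strictly decreasing, so the root is unique; bisection runs to
    ``tol`` pH units. Report to 2 decimals for presentation.
    """
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, pka_set) < 0:
        return lo
    if net_charge(seq, hi, pka_set) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
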