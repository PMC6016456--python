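"""Residue-column mapping, clade-specific calls, identity, isoelectric point."""

import itertools

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from iface import (
    Msa,
    MsaRow,
    isoelectric_point,
    lineage_specific_residues,
    make_msa,
    map_residues_to_columns,
    net_charge,
    percent_identity,
)
from iface.errors import InputError, MappingError
from iface.evolution import alignment_score, identity_from_alignment


# ---------------------------------------------------------------------------
# residue -> column mapping

def test_gap_skipping_map():
    m = map_residues_to_columns("AGT", "A-GT")
    assert m.residue_to_column == {0: 0, 1: 2, 2: 3}
    assert m.unmatched_residues == [] and m.unmatched_columns == []


def test_identity_map_gapless():
    m = map_residues_to_columns("ACDE", "ACDE")
    assert m.residue_to_column == {i: i for i in range(4)}


def test_map_substring_and_superstring():
    # row covers only the middle of the structure sequence
    m = map_residues_to_columns("KACDEK", "A-CDE")
    assert m.residue_to_column == {1: 0, 2: 2, 3: 3, 4: 4}
    assert m.unmatched_residues == [0, 5]
    # row extends beyond the structure sequence
    m2 = map_residues_to_columns("CDE", "KAC-DEK")
    assert m2.residue_to_column == {0: 2, 1: 4, 2: 5}
    assert sorted(m2.unmatched_columns) == [0, 1, 6]


def test_map_monotone_in_both_coordinates():
    msa, truth = make_msa(n_cols=40, gap_rate=0.1, seed=8)
    for row in msa.rows:
        m = map_residues_to_columns(truth["degapped"][row.id], row.seq)
        cols = [m.residue_to_column[r] for r in sorted(m.residue_to_column)]
        assert cols == sorted(cols)
        assert len(m.residue_to_column) == len(truth["degapped"][row.id])


def test_map_mismatch_error_names_position():
    with pytest.raises(MappingError, match="position 1"):
        map_residues_to_columns("AGT", "AC-T")


# ---------------------------------------------------------------------------
# clade-specific residues

def brute_force_calls(msa, clade_ids, columns):
    calls = []
    in_rows = [r.seq for r in msa.rows if r.id in clade_ids]
    out_rows = [r.seq for r in msa.rows if r.id not in clade_ids]
    for c in sorted(set(columns)):
        chars = {s[c] for s in in_rows}
        if len(chars) == 1:
            ch = chars.pop()
            if ch not in "-X" and all(s[c] != ch for s in out_rows):
                calls.append(c)
    return calls


def test_clade_call_definition():
    rows = [
        MsaRow("h1", "in", "TKA"),
        MsaRow("h2", "in", "TKA"),
        MsaRow("m1", "out", "KKA"),
        MsaRow("m2", "out", "KKA"),
        MsaRow("m3", "out", "KKA"),
    ]
    msa = Msa(rows)
    calls = lineage_specific_residues(msa, {"h1", "h2"}, range(3))
    assert [c.column for c in calls] == [0]
    assert calls[0].in_clade_residue == "T"
    assert set(calls[0].out_clade_residues) == {"K"}
    # column 1 uniform across all rows: not called; column 2 likewise


def test_clade_call_gap_disqualifies():
    rows = [
        MsaRow("h1", "in", "T-"),
        MsaRow("h2", "in", "TT"),
        MsaRow("m1", "out", "KK"),
        MsaRow("m2", "out", "KK"),
    ]
    calls = lineage_specific_residues(Msa(rows), {"h1", "h2"}, range(2))
    assert [c.column for c in calls] == [0]
    # gapped clade row at column 1 blocks the call even though out-clade lacks T


def test_planted_columns_called_exactly(tmp_path):
    msa, truth = make_msa(specific_columns=(5, 33), seed=3)
    calls = lineage_specific_residues(msa, truth["clade_ids"], range(msa.length))
    assert sorted(c.column for c in calls) == [5, 33]
    for c in calls:
        assert c.in_clade_residue == truth["specific_columns"][c.column]
    assert [c.column for c in calls] == brute_force_calls(
        msa, set(truth["clade_ids"]), range(msa.length)
    )


def test_no_planted_columns_no_calls():
    msa, truth = make_msa(specific_columns=(), seed=4)
    assert lineage_specific_residues(msa, truth["clade_ids"], range(msa.length)) == []


def test_calls_invariant_under_row_reordering():
    msa, truth = make_msa(specific_columns=(7, 20), seed=5)
    shuffled = Msa(rows=list(reversed(msa.rows)))
    a = lineage_specific_residues(msa, truth["clade_ids"], range(msa.length))
    b = lineage_specific_residues(shuffled, truth["clade_ids"], range(msa.length))
    assert [(c.column, c.in_clade_residue) for c in a] == [
        (c.column, c.in_clade_residue) for c in b
    ]


def test_clade_direction_matters():
    """Specificity is directional: complementing the clade changes the calls."""
    rows = [
        MsaRow("h1", "in", "T"),
        MsaRow("h2", "in", "T"),
        MsaRow("m1", "out", "K"),
        MsaRow("m2", "out", "A"),
    ]
    msa = Msa(rows)
    assert [c.column for c in lineage_specific_residues(msa, {"h1", "h2"}, [0])] == [0]
    # the complement clade {m1, m2} is not uniform -> no call
    assert lineage_specific_residues(msa, {"m1", "m2"}, [0]) == []


def test_clade_call_errors():
    msa, truth = make_msa(seed=6)
    all_ids = {r.id for r in msa.rows}
    with pytest.raises(InputError):
        lineage_specific_residues(msa, all_ids, [0])
    with pytest.raises(InputError):
        lineage_specific_residues(msa, set(), [0])
    with pytest.raises(InputError):
        lineage_specific_residues(msa, truth["clade_ids"], [msa.length + 5])


# ---------------------------------------------------------------------------
# percent identity

def test_identity_trivial_cases():
    assert percent_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0
    assert percent_identity("AAAA", "CCCC") == 0.0
    with pytest.raises(InputError):
        percent_identity("", "AAA")
    with pytest.raises(InputError):
        percent_identity("AB1", "AAA")


def test_identity_symmetric():
    rng = np.random.default_rng(9)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(5):
        a = "".join(rng.choice(aa, size=15))
        b = "".join(rng.choice(aa, size=12))
        assert percent_identity(a, b) == percent_identity(b, a)


def test_identity_100_iff_identical():
    assert percent_identity("PEPTIDE", "PEPTIDE") == 100.0
    assert percent_identity("PEPTIDE", "PEPTIDA") < 100.0


def exhaustive_best_alignments(a, b, matrix, gap_open, gap_extend):
    """Enumerate every global alignment of two short sequences recursively,
    scoring affine gaps exactly; returns (best score, identities of co-optima)."""
    best = {"score": -np.inf, "identities": set()}

    def walk(i, j, cols, score, state):
        if i == len(a) and j == len(b):
            if score > best["score"] + 1e-9:
                best["score"] = score
                best["identities"] = set()
            if abs(score - best["score"]) < 1e-9:
                matches = sum(1 for x, y in cols if x == y and x != "-")
                # terminal gap columns excluded from the denominator
                lo, hi = 0, len(cols)
                while lo < hi and "-" in cols[lo]:
                    lo += 1
                while hi > lo and "-" in cols[hi - 1]:
                    hi -= 1
                denom = hi - lo
                matches = sum(
                    1 for x, y in cols[lo:hi] if x == y and x != "-"
                )
                best["identities"].add(
                    round(100.0 * matches / denom, 1) if denom else 0.0
                )
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + [(a[i], b[j])],
                 score + float(matrix[a[i], b[j]]), "M")
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open
            walk(i + 1, j, cols + [(a[i], "-")], score - cost, "X")
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open
            walk(i, j + 1, cols + [("-", b[j])], score - cost, "Y")

    walk(0, 0, [], 0.0, "M")
    return best["score"], best["identities"]


@pytest.mark.parametrize("seed", range(6))
def test_identity_against_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aa, size=5))
    b = "".join(rng.choice(aa, size=6))
    matrix = substitution_matrices.load("BLOSUM62")
    oracle_score, oracle_identities = exhaustive_best_alignments(a, b, matrix, 10.0, 0.5)
    assert alignment_score(a, b) == pytest.approx(oracle_score, abs=1e-9)
    assert percent_identity(a, b) in oracle_identities


@pytest.mark.parametrize("seed", range(5))
def test_alignment_score_matches_independent_aligner(seed):
    rng = np.random.default_rng(100 + seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aa, size=40))
    b = "".join(rng.choice(aa, size=35))
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    assert alignment_score(a, b) == pytest.approx(float(aligner.score(a, b)), abs=1e-9)


def test_identity_x_positions_excluded():
    # X columns drop out of numerator and denominator alike
    assert identity_from_alignment("AXCD", "AYCD") == 100.0
    # whereas a real mismatch stays in the denominator
    assert identity_from_alignment("AKCD", "AYCD") == pytest.approx(75.0)
    assert identity_from_alignment("--CD", "AACD") == 100.0  # terminal gaps trimmed


# ---------------------------------------------------------------------------
# isoelectric point

def test_pi_root_self_consistency():
    for seq in ("ACDKLYR", "DDDDKKKK", "GGGG", "MKWVTFISLLLLFSSAYS"):
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 1e-3


def test_pi_acidic_below_basic():
    assert isoelectric_point("DDDDDDDD") < isoelectric_point("KKKKKKKK")


def test_pi_composition_only():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    shuffled = "".join(np.random.default_rng(0).permutation(list(seq[1:-1])))
    # shuffle interior only: terminal pKa values depend on the end residues
    assert isoelectric_point(seq) == pytest.approx(
        isoelectric_point(seq[0] + shuffled + seq[-1]), abs=1e-3
    )


def test_pi_matches_fine_grid_oracle():
    for seq in ("ACDKLYRE", "HHHHDDDD", "WYCKRDEH"):
        grid = np.arange(0.0, 14.0, 1e-4)
        z = np.array([net_charge(seq, ph) for ph in grid])
        crossing = grid[np.argmax(z < 0)]  # first sign change on the fine grid
        assert isoelectric_point(seq) == pytest.approx(crossing, abs=2e-4)


def test_pi_matches_independent_protparam():
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    for seq in ("MKWVTFISLLLLFSSAYS", "ACDKLYRE", "DDKKHHCC"):
        ours = isoelectric_point(seq)
        theirs = IsoelectricPoint(seq).pi()
        assert ours == pytest.approx(theirs, abs=0.02)
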