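"""Global affine-gap protein alignment kernel (Gotoh three-state DP).

Scoring is fixed across the package: BLOSUM62 substitution scores, gap open
11, gap extend 1 (a gap of length ``t`` costs ``11 + t``).  The kernel
returns, for a pair of sequences, the triple

    (optimal score, identical pairs, residue-residue columns)

maximised *lexicographically*: among all alignments reachable by the
three-state recurrence it first maximises the raw score, then the number of
identical aligned residue pairs, then the number of residue-residue columns.
This makes identity and coverage well-defined scalar functions of the two
sequences — independent of traceback tie-breaking — so independent
implementations of the same recurrence agree exactly.

The lexicographic maximisation is carried out in a single int64 DP by
packing the three objectives into one integer::

    packed = score * 2**24 + identical_pairs * 2**12 + aligned_columns

which is exact for sequences shorter than 4096 residues (the secondary
terms then fit below ``2**24`` and total magnitudes stay far below 2**63).

Recurrence (documented contract, shared with the test oracle):

* ``M[i,j] = max(M,X,Y)[i-1,j-1] + s(a_i, b_j)``  (residue-residue column)
* ``X[i,j] = max(M[i-1,j] - 12, X[i-1,j] - 1)``   (gap in b, consumes a)
* ``Y[i,j] = max(M[i,j-1] - 12, Y[i,j-1] - 1)``   (gap in a, consumes b)
* boundary gaps are penalised like internal ones (true global alignment);
  direct X<->Y transitions are disallowed (standard Gotoh simplification).
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

GAP_OPEN = 11
GAP_EXTEND = 1

W_COV = 1
W_ID = 1 << 12
W_SCORE = 1 << 24
MAX_LEN = W_ID - 1  # 4095 residues

_NEG = -(1 << 60)

__all__ = [
    "GAP_OPEN",
    "GAP_EXTEND",
    "MAX_LEN",
    "encode_sequence",
    "substitution_table",
    "align_stats",
]


def _build_substitution_table() -> np.ndarray:
    """128x128 int64 BLOSUM62 lookup indexed by ASCII code.

    Pairs outside the scored alphabet get a large (but overflow-safe)
    penalty; :func:`encode_sequence` rejects such residues up front anyway.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    table = np.full((128, 128), -(1 << 16), dtype=np.int64)
    letters = blosum.alphabet
    for x in letters:
        for y in letters:
            table[ord(x), ord(y)] = int(blosum[x, y])
    # Residues biopython's BLOSUM62 lacks: score like X (unknown).
    for extra in "JUO":
        for y in letters:
            table[ord(extra), ord(y)] = int(blosum["X", y])
            table[ord(y), ord(extra)] = int(blosum[y, "X"])
        for other in "JUO":
            table[ord(extra), ord(other)] = int(blosum["X", "X"])
    return table


_SUBST = _build_substitution_table()


def substitution_table() -> np.ndarray:
    """Return the package-wide ASCII-indexed BLOSUM62 table (read-only view)."""
    view = _SUBST.view()
    view.setflags(write=False)
    return view


_SCORED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO*")


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a residue string as an int8 array of ASCII codes."""
    if len(sequence) > MAX_LEN:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds alignment kernel "
            f"limit of {MAX_LEN} residues"
        )
    bad = set(sequence) - _SCORED_RESIDUES
    if bad:
        raise ValueError(f"unalignable residues in sequence: {sorted(bad)}")
    return np.frombuffer(sequence.encode("ascii"), dtype=np.int8).copy()


@njit(cache=False)
def _gotoh_packed(a, b, subst):  # pragma: no cover - exercised via wrapper
    n = a.size
    m = b.size
    neg = -(1 << 60)
    open_cost = (GAP_OPEN + GAP_EXTEND) * W_SCORE
    ext_cost = GAP_EXTEND * W_SCORE

    m_prev = np.full(m + 1, neg, np.int64)
    x_prev = np.full(m + 1, neg, np.int64)
    y_prev = np.full(m + 1, neg, np.int64)
    m_cur = np.full(m + 1, neg, np.int64)
    x_cur = np.full(m + 1, neg, np.int64)
    y_cur = np.full(m + 1, neg, np.int64)

    m_prev[0] = 0
    for j in range(1, m + 1):
        y_prev[j] = -(GAP_OPEN + j * GAP_EXTEND) * W_SCORE

    for i in range(1, n + 1):
        ai = a[i - 1]
        m_cur[0] = neg
        y_cur[0] = neg
        x_cur[0] = -(GAP_OPEN + i * GAP_EXTEND) * W_SCORE
        for j in range(1, m + 1):
            bj = b[j - 1]
            diag = m_prev[j - 1]
            if x_prev[j - 1] > diag:
                diag = x_prev[j - 1]
            if y_prev[j - 1] > diag:
                diag = y_prev[j - 1]
            gain = subst[ai, bj] * W_SCORE + W_COV
            if ai == bj:
                gain += W_ID
            m_cur[j] = diag + gain

            xo = m_prev[j] - open_cost
            xe = x_prev[j] - ext_cost
            x_cur[j] = xo if xo > xe else xe

            yo = m_cur[j - 1] - open_cost
            ye = y_cur[j - 1] - ext_cost
            y_cur[j] = yo if yo > ye else ye

        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev

    best = m_prev[m]
    if x_prev[m] > best:
        best = x_prev[m]
    if y_prev[m] > best:
        best = y_prev[m]
    return best


def align_stats(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Align two residue strings globally; return (score, identical, aligned).

    ``identical`` is the number of identical aligned residue pairs and
    ``aligned`` the number of residue-residue columns, both taken from the
    lexicographically optimal alignment described in the module docstring.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    packed = int(_gotoh_packed(encode_sequence(seq_a), encode_sequence(seq_b), _SUBST))
    score, rem = divmod(packed, W_SCORE)
    identical, aligned = divmod(rem, W_ID)
    return int(score), int(identical), int(aligned)
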