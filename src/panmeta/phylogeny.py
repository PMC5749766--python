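"""Core-gene phylogeny: alignment, concatenation, Poisson-NJ, bootstrap.

Per-core-cluster protein alignments are concatenated strain-wise in a fixed
cluster order; pairwise distances use the Poisson correction
``d = -ln(1 - p)`` with pairwise deletion of gap columns; trees are built
with canonical Saitou-Nei neighbor joining (Studier-Keppler Q criterion)
and internal-edge support comes from whole-column bootstrap resampling.

The built-in aligner is a minimal progressive Needleman-Wunsch (k-mer
distance guide tree, BLOSUM62, affine gaps 11/1).  Parity with external
aligners is a non-goal; externally prealigned clusters are accepted and
validated instead.  Gap symbol is ``-`` only; ambiguous residues count as
mismatches under pairwise deletion.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from panmeta._align import GAP_EXTEND, GAP_OPEN, substitution_table
from panmeta.seqio import GeneRecord

logger = logging.getLogger(__name__)

GAP = "-"

__all__ = [
    "ConcatenatedAlignment",
    "DistanceMatrix",
    "align_core_cluster",
    "concatenate",
    "poisson_distance",
    "neighbor_joining",
    "bootstrap_support",
    "tree_bipartitions",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal.

    ``saturated`` flags pairs whose p-distance reached 1, for which the
    Poisson correction is undefined (the value cell holds ``inf``).
    """

    def __init__(self, labels: Sequence[str], values, saturated=None) -> None:
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        finite = np.isfinite(values)
        if not np.allclose(values[finite], values.T[finite.T]):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diagonal(values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(values[finite] < 0):
            raise ValueError("negative distances")
        self.values = values
        if saturated is None:
            saturated = ~np.isfinite(values)
        self.saturated = np.asarray(saturated, dtype=bool)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[self._index[a], self._index[b]])


@dataclass
class ConcatenatedAlignment:
    """Per-strain concatenation of per-cluster alignments in fixed order."""

    sequences: dict[str, str]
    boundaries: list[tuple[int, int]]
    cluster_order: list

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sequences.values()}
        if len(widths) > 1:
            raise ValueError("concatenated sequences have unequal lengths")

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> list[str]:
        return list(self.sequences)


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = Counter(a[i : i + k] for i in range(max(0, len(a) - k + 1)))
    kb = Counter(b[i : i + k] for i in range(max(0, len(b) - k + 1)))
    shared = sum(min(n, kb[w]) for w, n in ka.items())
    denom = min(sum(ka.values()), sum(kb.values()))
    if denom == 0:
        return 1.0
    return 1.0 - shared / denom


def _column_score(col_a: tuple, col_b: tuple, subst) -> float:
    """Average BLOSUM62 score over residue pairs; gap pairs contribute 0."""
    total = 0.0
    pairs = 0
    for x in col_a:
        if x == GAP:
            continue
        ox = ord(x)
        for y in col_b:
            if y == GAP:
                continue
            total += subst[ox, ord(y)]
            pairs += 1
    if pairs == 0:
        return 0.0
    return total / pairs


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles with traceback.

    Three-state Gotoh; ties broken match > gap-in-b > gap-in-a so the
    result is deterministic.
    """
    subst = substitution_table()
    cols_a = list(zip(*rows_a))
    cols_b = list(zip(*rows_b))
    n, m = len(cols_a), len(cols_b)
    open_cost = float(GAP_OPEN + GAP_EXTEND)
    ext_cost = float(GAP_EXTEND)
    neg = -math.inf

    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    # predecessor-state pointers: 0 = M, 1 = X, 2 = Y
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + i * GAP_EXTEND)
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + j * GAP_EXTEND)
        ptr_y[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sc = _column_score(cols_a[i - 1], cols_b[j - 1], subst)
            # preference on ties: M, then X, then Y (deterministic)
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cand))
            M[i, j] = cand[k] + sc
            ptr_m[i, j] = k

            xo, xe = M[i - 1, j] - open_cost, X[i - 1, j] - ext_cost
            if xo >= xe:
                X[i, j], ptr_x[i, j] = xo, 0
            else:
                X[i, j], ptr_x[i, j] = xe, 1

            yo, ye = M[i, j - 1] - open_cost, Y[i, j - 1] - ext_cost
            if yo >= ye:
                Y[i, j], ptr_y[i, j] = yo, 0
            else:
                Y[i, j], ptr_y[i, j] = ye, 2

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    path: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        path.append(state)
        if state == 0:
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptr_x[i, j])
            i -= 1
        else:
            state = int(ptr_y[i, j])
            j -= 1
    path.reverse()
    path = ["MXY"[k] for k in path]
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    ia = jb = 0
    for move in path:
        if move == "M":
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[jb])
            ia += 1
            jb += 1
        elif move == "X":
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            for out in out_b:
                out.append(GAP)
            ia += 1
        else:
            for out in out_a:
                out.append(GAP)
            for r, row in enumerate(rows_b):
                out_b[r].append(row[jb])
            jb += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_core_cluster(
    records: Sequence[GeneRecord], prealigned: bool = False
) -> list[GeneRecord]:
    """Multiple-align the records of one core cluster.

    With ``prealigned=True`` the sequences are only validated for equal
    length.  A single record is returned unchanged with a warning.
    Progressive order follows a UPGMA guide tree on k-mer distances and is
    deterministic (inputs are processed in id-sorted order).
    """
    records = list(records)
    if not records:
        raise ValueError("align_core_cluster requires at least one record")
    if prealigned:
        widths = {len(r.sequence) for r in records}
        if len(widths) > 1:
            raise ValueError(
                f"prealigned cluster has unequal sequence lengths: {sorted(widths)}"
            )
        return records
    if len(records) == 1:
        logger.warning(
            "align_core_cluster: single sequence %s returned unaligned",
            records[0].id,
        )
        return records

    ordered = sorted(records, key=lambda r: r.id)
    n = len(ordered)
    # UPGMA guide tree on k-mer distances
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _kmer_distance(
                ordered[i].sequence, ordered[j].sequence
            )
    merges = linkage(squareform(dmat, checks=False), method="average")

    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [ordered[i].sequence]) for i in range(n)
    }
    next_id = n
    for a, b, _, _ in merges:
        ids_a, rows_a = profiles.pop(int(a))
        ids_b, rows_b = profiles.pop(int(b))
        al_a, al_b = _profile_align(rows_a, rows_b)
        profiles[next_id] = (ids_a + ids_b, al_a + al_b)
        next_id += 1

    ids, rows = profiles.popitem()[1]
    by_index = dict(zip(ids, rows))
    return [
        GeneRecord(id=ordered[i].id, source=ordered[i].source, sequence=by_index[i])
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate(
    alignments: Mapping[object, Sequence[GeneRecord]],
    strain_list: Sequence[str],
    cluster_order: Sequence | None = None,
) -> ConcatenatedAlignment:
    """Join per-cluster alignments strain-wise in a fixed cluster order.

    Every alignment must contain exactly one sequence per strain (record
    ``source`` is the strain label); violations raise naming the cluster
    and strain.
    """
    if cluster_order is None:
        cluster_order = sorted(alignments, key=str)
    parts: dict[str, list[str]] = {s: [] for s in strain_list}
    boundaries: list[tuple[int, int]] = []
    offset = 0
    for cid in cluster_order:
        alignment = alignments[cid]
        by_strain: dict[str, str] = {}
        for rec in alignment:
            if rec.source in by_strain:
                raise ValueError(
                    f"cluster {cid!r}: strain {rec.source!r} appears more than once"
                )
            by_strain[rec.source] = rec.sequence
        widths = {len(s) for s in by_strain.values()}
        if len(widths) > 1:
            raise ValueError(f"cluster {cid!r}: unaligned (unequal lengths)")
        width = widths.pop()
        for strain in strain_list:
            if strain not in by_strain:
                raise ValueError(f"cluster {cid!r}: missing strain {strain!r}")
            parts[strain].append(by_strain[strain])
        boundaries.append((offset, offset + width))
        offset += width
    return ConcatenatedAlignment(
        sequences={s: "".join(parts[s]) for s in strain_list},
        boundaries=boundaries,
        cluster_order=list(cluster_order),
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _alignment_matrix(concat: ConcatenatedAlignment) -> tuple[list[str], np.ndarray]:
    labels = list(concat.sequences)
    mat = np.array(
        [np.frombuffer(concat.sequences[s].encode("ascii"), dtype=np.uint8) for s in labels]
    )
    return labels, mat


def _poisson_from_matrix(labels: Sequence[str], mat: np.ndarray) -> DistanceMatrix:
    gap = ord(GAP)
    n = len(labels)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    nongap = mat != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            used = int(both.sum())
            if used == 0:
                raise ValueError(
                    f"no shared ungapped columns for pair "
                    f"({labels[i]!r}, {labels[j]!r})"
                )
            mism = int((mat[i, both] != mat[j, both]).sum())
            p = mism / used
            if p >= 1.0:
                values[i, j] = values[j, i] = math.inf
                saturated[i, j] = saturated[j, i] = True
            else:
                d = -math.log1p(-p)
                values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, saturated)


def poisson_distance(concat: ConcatenatedAlignment) -> DistanceMatrix:
    """Poisson-corrected distances with pairwise deletion.

    For each pair only columns where both sequences are non-gap are used;
    ``p`` = mismatch fraction, ``d = -ln(1 - p)``.  A pair with ``p = 1``
    is flagged saturated (``inf``); a pair with no shared columns raises.
    """
    if len(concat.sequences) < 2:
        raise ValueError("poisson_distance requires at least two strains")
    labels, mat = _alignment_matrix(concat)
    return _poisson_from_matrix(labels, mat)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei NJ with Studier-Keppler Q criterion.

    Deterministic: the joined pair minimises Q with ties broken toward the
    lexicographically lowest pair of subtree labels (a subtree is labeled
    by its smallest leaf).  Negative branch lengths are clamped to zero
    with a log entry.  Saturated entries raise.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor_joining requires at least 3 taxa")
    if dm.saturated.any():
        raise ValueError(
            "distance matrix contains saturated (p=1) pairs; filter the "
            "alignment before tree building"
        )

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.info("neighbor_joining: clamping negative branch %s: %g", what, x)
            return 0.0
        return x

    # active node: key -> (newick fragment, min leaf label)
    nodes: dict[int, tuple[str, str]] = {}
    for i, lab in enumerate(dm.labels):
        nodes[i] = (lab, lab)
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.values[i, j])
    next_key = n

    while len(nodes) > 3:
        active = sorted(nodes)
        na = len(active)
        r = {
            i: sum(dist[frozenset((i, k))] for k in active if k != i) for i in active
        }
        best = None
        for ai in range(na):
            for aj in range(ai + 1, na):
                i, j = active[ai], active[aj]
                q = (na - 2) * dist[frozenset((i, j))] - r[i] - r[j]
                tag = tuple(sorted((nodes[i][1], nodes[j][1])))
                cand = (q, tag, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        dij = dist[frozenset((i, j))]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (na - 2))
        lj = dij - li
        li = clamp(li, f"to {nodes[i][1]}")
        lj = clamp(lj, f"to {nodes[j][1]}")
        newick = f"({nodes[i][0]}:{li:.12g},{nodes[j][0]}:{lj:.12g})"
        min_leaf = min(nodes[i][1], nodes[j][1])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (
                dist[frozenset((i, k))] + dist[frozenset((j, k))] - dij
            )
            dist[frozenset((next_key, k))] = dk
        del nodes[i], nodes[j]
        nodes[next_key] = (newick, min_leaf)
        next_key += 1

    (a, b, c) = sorted(nodes)
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = clamp(0.5 * (dab + dac - dbc), f"to {nodes[a][1]}")
    lb = clamp(0.5 * (dab + dbc - dac), f"to {nodes[b][1]}")
    lc = clamp(0.5 * (dac + dbc - dab), f"to {nodes[c][1]}")
    newick = (
        f"({nodes[a][0]}:{la:.12g},{nodes[b][0]}:{lb:.12g},{nodes[c][0]}:{lc:.12g});"
    )
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted tree as normalized leaf sets.

    Each internal edge splits the leaves into two sides; the side whose
    sorted label tuple is smallest represents the bipartition.
    """
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    parts: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        other = all_leaves - clade
        if len(clade) < 2 or len(other) < 2:
            continue
        side = min(clade, other, key=lambda s: tuple(sorted(s)))
        parts.add(side)
    return parts


def bootstrap_support(
    concat: ConcatenatedAlignment, n_replicates: int, seed: int
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree plus per-internal-edge bootstrap support.

    Whole alignment columns are resampled with replacement; per replicate
    the Poisson-NJ tree is rebuilt and each original internal bipartition
    is scored by the percentage of replicates containing it.  Deterministic
    for a fixed seed.  Replicates whose distances fail (saturation, empty
    overlap) support nothing and are logged.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, mat = _alignment_matrix(concat)
    if mat.shape[1] < 2:
        raise ValueError("alignment must have at least 2 columns to bootstrap")

    tree = neighbor_joining(_poisson_from_matrix(labels, mat))
    original = tree_bipartitions(tree)
    counts = {bp: 0 for bp in original}

    rng = np.random.default_rng(seed)
    width = mat.shape[1]
    for rep in range(n_replicates):
        idx = rng.integers(0, width, size=width)
        sub = mat[:, idx]
        try:
            rep_tree = neighbor_joining(_poisson_from_matrix(labels, sub))
        except ValueError as exc:
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            continue
        rep_parts = tree_bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1

    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}

    # annotate internal nodes of the original tree with their support
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_leaves - clade
        if len(clade) < 2 or len(other) < 2:
            continue
        side = min(clade, other, key=lambda s: tuple(sorted(s)))
        node.label = f"{supports[side]:g}"
    return tree, supports
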