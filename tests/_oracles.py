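"""Independent reference implementations used only to cross-check results.

Each oracle is coded from the definition, separately from the package's
production path (plain Python data structures, no shared helpers), so
agreement is a meaningful dual-route check.
"""

from __future__ import annotations

import itertools
import math


def gotoh_oracle(seq_a: str, seq_b: str, score_of) -> tuple[int, int, int]:
    """Quadratic three-state DP for (score, identical pairs, aligned columns).

    Same documented recurrence and lexicographic objective as the package
    kernel (packed integers, gap open 11 / extend 1, boundary gaps
    penalised), but written as full lists-of-lists in pure Python with
    arbitrary-precision ints.
    """
    w_cov, w_id, w_sc = 1, 1 << 12, 1 << 24
    neg = -(10**18)
    open_cost = 12 * w_sc
    ext_cost = 1 * w_sc
    n, m = len(seq_a), len(seq_b)

    mm = [[neg] * (m + 1) for _ in range(n + 1)]
    xx = [[neg] * (m + 1) for _ in range(n + 1)]
    yy = [[neg] * (m + 1) for _ in range(n + 1)]
    mm[0][0] = 0
    for i in range(1, n + 1):
        xx[i][0] = -(11 + i) * w_sc
    for j in range(1, m + 1):
        yy[0][j] = -(11 + j) * w_sc

    for i in range(1, n + 1):
        ca = seq_a[i - 1]
        for j in range(1, m + 1):
            cb = seq_b[j - 1]
            gain = score_of(ca, cb) * w_sc + w_cov + (w_id if ca == cb else 0)
            mm[i][j] = max(mm[i - 1][j - 1], xx[i - 1][j - 1], yy[i - 1][j - 1]) + gain
            xx[i][j] = max(mm[i - 1][j] - open_cost, xx[i - 1][j] - ext_cost)
            yy[i][j] = max(mm[i][j - 1] - open_cost, yy[i][j - 1] - ext_cost)

    packed = max(mm[n][m], xx[n][m], yy[n][m])
    score, rest = divmod(packed, w_sc)
    identical, aligned = divmod(rest, w_id)
    return score, identical, aligned


def leaf_path_lengths(tree) -> dict[frozenset, float]:
    """Pairwise leaf-to-leaf path lengths by explicit root-path traversal."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node.parent_node is not None:
            chain.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    out = {}
    for la, lb in itertools.combinations(paths, 2):
        ids_a = {nid for nid, _ in paths[la]}
        ids_b = {nid for nid, _ in paths[lb]}
        total = sum(ln for nid, ln in paths[la] if nid not in ids_b)
        total += sum(ln for nid, ln in paths[lb] if nid not in ids_a)
        out[frozenset((la, lb))] = total
    return out


def jaccard_oracle(sets: dict[str, set]) -> dict[frozenset, float]:
    """Brute-force set-arithmetic Jaccard for every pair of labels."""
    out = {}
    for a, b in itertools.combinations(sorted(sets), 2):
        union = sets[a] | sets[b]
        out[frozenset((a, b))] = (
            len(sets[a] & sets[b]) / len(union) if union else 0.0
        )
    return out


def average_linkage_heights(points) -> list[float]:
    """O(n^3) agglomerative average linkage on Euclidean distances.

    Returns the sorted merge heights.  Cluster-to-cluster distance is the
    mean pairwise distance between original points (UPGMA).
    """

    def euclid(p, q):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(p, q)))

    n = len(points)
    base = {(i, j): euclid(points[i], points[j]) for i in range(n) for j in range(n)}
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = sum(
                base[(i, j)] for i in clusters[a] for j in clusters[b]
            ) / (len(clusters[a]) * len(clusters[b]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def interval_union_bitmap(intervals, genome_length: int) -> int:
    """Covered bases of 1-based inclusive intervals via a per-base bitmap."""
    covered = [False] * (genome_length + 1)
    for start, end in intervals:
        lo, hi = min(start, end), max(start, end)
        for pos in range(lo, hi + 1):
            covered[pos] = True
    return sum(covered[1:])


def pair_transition_pdistance(branch_lengths, divergence) -> float:
    """Expected p-distance along a path by explicit 20x20 matrix products.

    Per branch the per-site transition matrix is
    ``P = (1-q) I + q (J - I)/19`` with ``q = 1 - exp(-b d)``; a uniform
    start composed through the path gives P(differ).
    """
    import numpy as np

    P = np.eye(20)
    for b in branch_lengths:
        q = 1.0 - math.exp(-b * divergence)
        step = (1.0 - q) * np.eye(20) + q * (np.ones((20, 20)) - np.eye(20)) / 19.0
        P = P @ step
    p_same = float(np.trace(P)) / 20.0
    return 1.0 - p_same
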