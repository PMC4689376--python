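"""Independent brute-force oracles used by the test suite.

Deliberately implemented without the package's own machinery: plain
substring scanning for motifs, recursive enumeration for global
alignment, and exhaustive topology enumeration with least-squares branch
fitting for tree reconstruction.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
       "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
       "D": "H", "H": "D", "N": "N"}


def revcomp(pattern: str) -> str:
    return "".join(_RC[c] for c in reversed(pattern))


def _matches_at(seq: str, i: int, pattern: str) -> bool:
    if i + len(pattern) > len(seq):
        return False
    return all(seq[i + j] in IUPAC[c] for j, c in enumerate(pattern))


def motif_counts(seq: str, pattern: str, both_strands: bool = True) -> int:
    """Count occurrences by testing every position (both strands)."""
    patterns = [pattern, revcomp(pattern)] if both_strands else [pattern]
    return sum(
        _matches_at(seq, i, p) for p in patterns for i in range(len(seq))
    )


def motif_hits(seq: str, pattern: str) -> list[tuple[int, str]]:
    out = []
    for i in range(len(seq)):
        if _matches_at(seq, i, pattern):
            out.append((i, "+"))
        if _matches_at(seq, i, revcomp(pattern)):
            out.append((i, "-"))
    return out


# --- global alignment oracle (tiny sequences only) -------------------------


def nw_score_bruteforce(a: str, b: str, matrix, gap_open=-10.0, gap_ext=-0.5):
    """Best global alignment score by recursive enumeration of alignment
    states (affine gaps: a length-k gap scores open + (k-1)*extend).
    Exponential: only for very short sequences."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(matrix[a[i], b[j]] + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_ext if state == "a" else gap_open
            options.append(cost + best(i + 1, j, "a"))
        if j < len(b):
            cost = gap_ext if state == "b" else gap_open
            options.append(cost + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "m")


# --- tree enumeration oracle ------------------------------------------------


def all_unrooted_trees(taxa: list[str]):
    """All unrooted binary topologies as edge lists; internal nodes are
    negative ints."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")

    def extend(edges, next_internal, remaining):
        if not remaining:
            yield list(edges)
            return
        t = remaining[0]
        for k in range(len(edges)):
            u, v = edges[k]
            w = next_internal
            new_edges = edges[:k] + edges[k + 1:] + [(u, w), (w, v), (w, t)]
            yield from extend(new_edges, next_internal - 1, remaining[1:])

    base = [(-1, taxa[0]), (-1, taxa[1]), (-1, taxa[2])]
    yield from extend(base, -2, taxa[3:])


def tree_splits(edges, taxa):
    """Non-trivial bipartitions, each as the side without min(taxa)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    ref = min(taxa)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge removed
        seen, stack = {u, v}, [v]
        side = []
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                side.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        fs = frozenset(side)
        if ref in fs:
            fs = frozenset(set(taxa) - fs)
        if 2 <= len(fs) <= len(taxa) - 2:
            splits.add(fs)
    return splits


def path_edges(edges, taxa):
    """For each taxon pair, the set of edge indices on its path."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(s, t):
        stack = [(s, [])]
        seen = {s}
        while stack:
            node, used = stack.pop()
            if node == t:
                return used
            for nxt, idx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, used + [idx]))
        raise RuntimeError("disconnected tree")

    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a, b)] = path(a, b)
    return out


def lstsq_residual(edges, taxa, dist):
    """Least-squares residual of fitting branch lengths to distances."""
    pe = path_edges(edges, taxa)
    pairs = sorted(pe)
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for row, (x, y) in enumerate(pairs):
        for idx in pe[(x, y)]:
            A[row, idx] = 1.0
        b[row] = dist[(x, y)]
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(np.sum((A @ x - b) ** 2))


def best_fit_topology(taxa, dist):
    """Topology (as split set) minimizing the least-squares residual."""
    best_res, best_splits = None, None
    for edges in all_unrooted_trees(taxa):
        res = lstsq_residual(edges, taxa, dist)
        if best_res is None or res < best_res - 1e-12:
            best_res, best_splits = res, tree_splits(edges, taxa)
    return best_splits, best_res


def random_additive_tree(taxa, rng):
    """A random unrooted topology with random branch lengths; returns
    (edge list, {edge: length}, pairwise distance dict, split set)."""
    topologies = None  # built on the fly: random insertion order
    edges = [(-1, taxa[0]), (-1, taxa[1]), (-1, taxa[2])]
    nxt = -2
    for t in taxa[3:]:
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        edges += [(u, nxt), (nxt, v), (nxt, t)]
        nxt -= 1
    lengths = {i: float(rng.uniform(0.1, 1.0)) for i in range(len(edges))}
    pe = path_edges(edges, taxa)
    dist = {pair: sum(lengths[i] for i in idxs) for pair, idxs in pe.items()}
    return edges, lengths, dist, tree_splits(edges, taxa)
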