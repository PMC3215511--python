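"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's optimised code paths: subsets are
enumerated exhaustively, tail probabilities are summed from binomial
coefficients, and Fisher tables are enumerated over their margins.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from ssmotif import GeneMotifSet, SSMType, extended_distance, extract_nodes


def brute_force_ssms(
    g1: GeneMotifSet, g2: GeneMotifSet, type: SSMType
) -> set[tuple[str, ...]]:
    """All SSMs by exhaustive subset enumeration over PreSSM nodes.

    A subset qualifies when (2) all pairwise extended distances are <= d,
    (3) no outside node can be added preserving (2), and (1) its nodes
    jointly cover both genes.  Returns sorted canonical-key tuples.
    """
    nodes = extract_nodes(g1, g2, type.l)
    n = len(nodes)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = extended_distance(nodes[i].ext, nodes[j].ext)

    def is_clique(subset: tuple[int, ...]) -> bool:
        return all(dist[(a, b)] <= type.d for a, b in combinations(subset, 2))

    cliques = [
        subset
        for r in range(1, n + 1)
        for subset in combinations(range(n), r)
        if is_clique(subset)
    ]
    out: set[tuple[str, ...]] = set()
    for subset in cliques:
        extendable = any(
            v not in subset
            and all(dist[(min(v, u), max(v, u))] <= type.d for u in subset)
            for v in range(n)
        )
        if extendable:
            continue
        covered = frozenset().union(*(nodes[i].gene_ids for i in subset))
        if {g1.gene_id, g2.gene_id} <= covered:
            out.add(tuple(sorted(nodes[i].canonical for i in subset)))
    return out


def brute_hypergeom_upper_tail(k: int, n_universe: int, big_k: int, m: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, m) by summing point masses."""
    total = comb(n_universe, m)
    return sum(
        comb(big_k, x) * comb(n_universe - big_k, m - x)
        for x in range(k, min(big_k, m) + 1)
        if m - x <= n_universe - big_k
    ) / total


def brute_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating tables with fixed margins,
    summing probabilities of tables no more probable than the observed one
    (with a small relative tolerance for float ties)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x: int) -> float:
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0.0
        return comb(row1, x) * comb(row2, col1 - x) / denom

    p_obs = prob(a)
    return sum(
        p for x in range(0, min(row1, col1) + 1)
        if (p := prob(x)) <= p_obs * (1 + 1e-9)
    )
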