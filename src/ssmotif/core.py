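"""The Simple Shared Motif (SSM) algorithm.

For a gene pair and a type (l, d), every length-``l`` window of every
atomic motif of both genes is mapped to its extended sequence (orbit
under complement / reversal / reverse complement).  Windows with the
same orbit merge into a single *PreSSM node* tagged with the genes they
came from.  A graph is built with an edge between two nodes whenever
their extended distance (min Hamming over members) is at most ``d``.
An SSM is a maximal clique of that graph whose nodes jointly cover both
genes of the pair:

1. it contains material from both genes,
2. every pairwise extended distance is at most ``d``,
3. it is maximal: no further node can be added preserving (1)-(2).

Because (1) can only improve by adding nodes, maximality reduces to
clique maximality; the algorithm enumerates maximal cliques (pivoting
Bron-Kerbosch via igraph) and discards single-gene ones.  A node whose
windows occur in both genes is by itself a valid (singleton) SSM when
isolated — this is what exact sharing means at d = 0, where the graph
has no edges between distinct orbits.

Two counting conventions coexist deliberately: PreSSM nodes merge
duplicate windows, but the *potential* SSM count — the SSMC denominator
— counts windows positionally without deduplication (the product of the
two genes' window totals).

``SSMEngine`` is the batch interface: it caches per-gene window profiles
and shares the node distance matrix across all ``d`` values of a length,
which is what makes database-scale null sampling tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import igraph as ig
import numpy as np

from .extended import ExtendedSequence, canonical_key, extended_members
from .motifs import GeneMotifSet, MotifDatabase

__all__ = [
    "SSMType",
    "ssm_type_grid",
    "window_count",
    "potential_ssm_count",
    "PreSSMNode",
    "extract_nodes",
    "SSM",
    "enumerate_ssms",
    "SSMCountResult",
    "ssm_count_result",
    "SSMEngine",
]

L_MIN, L_MAX = 6, 14
D_MAX = 5


@dataclass(frozen=True, order=True)
class SSMType:
    """An SSM type: window length ``l`` and maximum Hamming distance ``d``.

    The distance budget is at most a third of the window length
    (d <= floor(l/3)), capped at 5.
    """

    l: int
    d: int

    def __post_init__(self) -> None:
        if not L_MIN <= self.l <= L_MAX:
            raise ValueError(f"l must be in [{L_MIN}, {L_MAX}], got {self.l}")
        if not 0 <= self.d <= min(D_MAX, self.l // 3):
            raise ValueError(
                f"d must be in [0, min({D_MAX}, floor({self.l}/3))], got {self.d}"
            )

    def __repr__(self) -> str:  # ({l},{d})SSM notation used in reports
        return f"({self.l},{self.d})SSM"


def ssm_type_grid() -> tuple[SSMType, ...]:
    """All valid (l, d) types, ordered by (l, d); 31 types."""
    return tuple(
        SSMType(l, d)
        for l in range(L_MIN, L_MAX + 1)
        for d in range(0, min(D_MAX, l // 3) + 1)
    )


def window_count(motif_length: int, l: int) -> int:
    """Number of length-``l`` windows in a motif of the given length."""
    if l < 1:
        raise ValueError("window length must be >= 1")
    return max(0, motif_length - l + 1)


def _gene_window_total(gene: GeneMotifSet, l: int) -> int:
    return sum(window_count(m.length, l) for m in gene.motifs)


def potential_ssm_count(g1: GeneMotifSet, g2: GeneMotifSet, l: int) -> int:
    """Product of the two genes' total numbers of length-``l`` windows.

    Windows are counted positionally, without deduplicating identical
    sequences; this is the SSMC denominator.
    """
    return _gene_window_total(g1, l) * _gene_window_total(g2, l)


@dataclass(frozen=True)
class PreSSMNode:
    """One graph node: an extended sequence, the genes whose atomic motifs
    contain a generating window, and the total number of such windows."""

    ext: ExtendedSequence
    gene_ids: frozenset[str]
    occurrence_count: int

    @property
    def canonical(self) -> str:
        return self.ext.canonical


def _iter_windows(gene: GeneMotifSet, l: int) -> Iterator[str]:
    for m in gene.motifs:
        seq = m.sequence
        for i in range(len(seq) - l + 1):
            yield seq[i : i + l]


def extract_nodes(
    g1: GeneMotifSet, g2: GeneMotifSet, l: int
) -> tuple[PreSSMNode, ...]:
    """PreSSM nodes for a gene pair: one node per distinct orbit among all
    length-``l`` windows of both genes, sorted by canonical key."""
    acc: dict[str, tuple[set[str], int]] = {}
    for gene in (g1, g2):
        for w in _iter_windows(gene, l):
            key = canonical_key(w)
            entry = acc.get(key)
            if entry is None:
                acc[key] = ({gene.gene_id}, 1)
            else:
                entry[0].add(gene.gene_id)
                acc[key] = (entry[0], entry[1] + 1)
    return tuple(
        PreSSMNode(
            ext=ExtendedSequence(frozenset(extended_members(key))),
            gene_ids=frozenset(gids),
            occurrence_count=occ,
        )
        for key, (gids, occ) in sorted(acc.items())
    )


@dataclass(frozen=True)
class SSM:
    """One Simple Shared Motif: a maximal clique of PreSSM nodes spanning
    both genes of the pair at type (l, d)."""

    nodes: frozenset[PreSSMNode]
    type: SSMType
    gene_pair: tuple[str, str]

    @property
    def canonical_keys(self) -> tuple[str, ...]:
        return tuple(sorted(n.canonical for n in self.nodes))


@dataclass(frozen=True)
class SSMCountResult:
    """SSM and potential-SSM counts for one gene pair and type.

    ``ssmc`` is the ratio ssm_count / potential_count, or None when the
    pair has no window material on one side (degenerate)."""

    gene_pair: tuple[str, str]
    type: SSMType
    ssm_count: int
    potential_count: int

    @property
    def ssmc(self) -> float | None:
        if self.potential_count == 0:
            return None
        return self.ssm_count / self.potential_count


# ---------------------------------------------------------------------------
# Numeric engine: 2-bit packed sequences, vectorised Hamming, igraph cliques.
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK01 = np.uint64(0x5555555555555555)
_ONE = np.uint64(1)

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE_LUT[ord(_ch)] = _i


def _encode(w: str) -> int:
    """Pack a DNA word (length <= 32) into 2 bits per base."""
    code = 0
    for ch in w:
        code = (code << 2) | _BASE_CODE[ch]
    return code


def _pack_windows(seq: str, l: int) -> np.ndarray:
    """Packed codes of all length-``l`` windows of ``seq``, in order."""
    if len(seq) < l:
        return np.empty(0, dtype=np.uint64)
    b = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.uint64)
    sw = np.lib.stride_tricks.sliding_window_view(b, l)
    powers = np.uint64(4) ** np.arange(l - 1, -1, -1, dtype=np.uint64)
    return (sw * powers).sum(axis=1, dtype=np.uint64)


def _member_matrix(fwd: np.ndarray, rev: np.ndarray, l: int) -> np.ndarray:
    """(W, 4) member codes {w, w_c, w_r, w_rc} per window from the packed
    forward and reversed-window codes.  The complement of a packed word
    flips every base code (3 - b), i.e. bitwise NOT under the 2l-bit mask."""
    mask = np.uint64((1 << (2 * l)) - 1)
    return np.stack([fwd, ~fwd & mask, rev, ~rev & mask], axis=1)


def _node_distance_matrix(canon: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Pairwise extended distances between nodes.

    Hamming distance is invariant under complement and reversal applied
    to both words, so min over the 16 member cross pairs of two orbits
    equals min over one fixed representative of the first orbit against
    the 4 members of the second: d(canon_i, members_j) suffices.
    Hamming distance of packed words is the popcount of the per-base OR
    of the XOR's two bit planes.
    """
    x = canon[:, None, None] ^ members[None, :, :]
    mism = (x | (x >> _ONE)) & _MASK01
    return np.bitwise_count(mism).min(axis=2).astype(np.uint8)


def _spanning_clique_indices(
    dist: np.ndarray, span1: np.ndarray, span2: np.ndarray, d: int
) -> list[list[int]]:
    """Maximal cliques (as node-index lists) covering both genes.

    Early exit when no node covers both genes and no edge joins a
    gene-1 node to a gene-2 node: every clique is then single-gene.
    Isolated single-gene nodes are pruned beforehand — they are maximal
    singleton cliques that would be discarded, and cannot extend any
    other clique.
    """
    adj = dist <= d
    np.fill_diagonal(adj, False)
    both = span1 & span2
    if not both.any() and not (adj & (span1[:, None] & span2[None, :])).any():
        return []
    keep = adj.any(axis=1) | both
    idx = np.flatnonzero(keep)
    sub = adj[np.ix_(idx, idx)]
    s1 = span1[idx].tolist()
    s2 = span2[idx].tolist()
    edges = np.argwhere(np.triu(sub))
    graph = ig.Graph(n=int(idx.size), edges=edges.tolist())
    out: list[list[int]] = []
    for clique in graph.maximal_cliques():
        has1 = has2 = False
        for v in clique:
            has1 = has1 or s1[v]
            has2 = has2 or s2[v]
        if has1 and has2:
            out.append([int(idx[v]) for v in clique])
    return out


def _node_arrays(
    nodes: Sequence[PreSSMNode], gid1: str, gid2: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    canon = np.empty(len(nodes), dtype=np.uint64)
    members = np.empty((len(nodes), 4), dtype=np.uint64)
    span1 = np.zeros(len(nodes), dtype=bool)
    span2 = np.zeros(len(nodes), dtype=bool)
    for i, node in enumerate(nodes):
        canon[i] = _encode(node.canonical)
        mem = sorted(node.ext.members)
        for j in range(4):  # pad collapsed orbits with repeats; min unaffected
            members[i, j] = _encode(mem[j % len(mem)])
        span1[i] = gid1 in node.gene_ids
        span2[i] = gid2 in node.gene_ids
    return canon, members, span1, span2


def enumerate_ssms(
    g1: GeneMotifSet, g2: GeneMotifSet, type: SSMType
) -> tuple[SSM, ...]:
    """All (l, d)SSMs of a gene pair, sorted by their canonical keys."""
    nodes = extract_nodes(g1, g2, type.l)
    if not nodes:
        return ()
    canon, members, span1, span2 = _node_arrays(nodes, g1.gene_id, g2.gene_id)
    dist = _node_distance_matrix(canon, members)
    cliques = _spanning_clique_indices(dist, span1, span2, type.d)
    ssms = [
        SSM(
            nodes=frozenset(nodes[i] for i in clique),
            type=type,
            gene_pair=(g1.gene_id, g2.gene_id),
        )
        for clique in cliques
    ]
    return tuple(sorted(ssms, key=lambda s: s.canonical_keys))


def ssm_count_result(
    g1: GeneMotifSet, g2: GeneMotifSet, type: SSMType
) -> SSMCountResult:
    """SSM count, potential count and SSMC for one pair and type."""
    return SSMCountResult(
        gene_pair=(g1.gene_id, g2.gene_id),
        type=type,
        ssm_count=len(enumerate_ssms(g1, g2, type)),
        potential_count=potential_ssm_count(g1, g2, type.l),
    )


class _GeneProfile:
    """Per-gene, per-length window index in packed form: sorted unique
    canonical codes, their (K, 4) member-code rows, per-orbit positional
    occurrence counts and the positional window total."""

    __slots__ = ("window_total", "canon", "members", "occurrences")

    def __init__(self, gene: GeneMotifSet, l: int) -> None:
        fwd_parts: list[np.ndarray] = []
        rev_parts: list[np.ndarray] = []
        for m in gene.motifs:
            if m.length < l:
                continue
            fwd_parts.append(_pack_windows(m.sequence, l))
            # reversal of window i of s is window (n-l-i) of reversed s
            rev_parts.append(_pack_windows(m.sequence[::-1], l)[::-1])
        if not fwd_parts:
            self.window_total = 0
            self.canon = np.empty(0, dtype=np.uint64)
            self.members = np.empty((0, 4), dtype=np.uint64)
            self.occurrences = np.empty(0, dtype=np.int64)
            return
        fwd = np.concatenate(fwd_parts)
        rev = np.concatenate(rev_parts)
        members = _member_matrix(fwd, rev, l)
        canon_all = members.min(axis=1)
        canon, first, counts = np.unique(canon_all, return_index=True, return_counts=True)
        self.window_total = int(len(fwd))
        self.canon = canon
        self.members = members[first]
        self.occurrences = counts.astype(np.int64)


class SSMEngine:
    """Batch SSM counting over a database.

    Caches per-gene window profiles and, for each pair, computes the node
    distance matrix once per length and reuses it for every ``d`` of that
    length in the grid.  Results are identical to the reference
    single-pair path (``ssm_count_result``).
    """

    def __init__(self, db: MotifDatabase, grid: Iterable[SSMType] | None = None):
        self.db = db
        self.grid: tuple[SSMType, ...] = tuple(grid) if grid is not None else ssm_type_grid()
        self._ds_by_l: dict[int, tuple[int, ...]] = {}
        for t in self.grid:
            ds = self._ds_by_l.setdefault(t.l, ())
            self._ds_by_l[t.l] = tuple(sorted(set(ds) | {t.d}))
        self._profiles: dict[tuple[str, int], _GeneProfile] = {}

    def _profile(self, gene_id: str, l: int) -> _GeneProfile:
        key = (gene_id, l)
        prof = self._profiles.get(key)
        if prof is None:
            prof = _GeneProfile(self.db[gene_id], l)
            self._profiles[key] = prof
        return prof

    def _pair_length_counts(
        self, gid1: str, gid2: str, l: int, ds: tuple[int, ...]
    ) -> tuple[int, dict[int, int]]:
        p1 = self._profile(gid1, l)
        p2 = self._profile(gid2, l)
        potential = p1.window_total * p2.window_total
        if potential == 0:
            return potential, {d: 0 for d in ds}
        canon = np.union1d(p1.canon, p2.canon)
        k = len(canon)
        span1 = np.zeros(k, dtype=bool)
        span2 = np.zeros(k, dtype=bool)
        members = np.empty((k, 4), dtype=np.uint64)
        pos1 = np.searchsorted(canon, p1.canon)
        pos2 = np.searchsorted(canon, p2.canon)
        span1[pos1] = True
        span2[pos2] = True
        members[pos1] = p1.members
        members[pos2] = p2.members  # shared orbits: identical rows
        counts: dict[int, int] = {}
        need_dist = any(d > 0 for d in ds)
        dist = _node_distance_matrix(canon, members) if need_dist else None
        for d in ds:
            if d == 0:
                # no edges between distinct orbits: maximal cliques are the
                # singleton nodes, SSMs the ones present in both genes
                counts[d] = int((span1 & span2).sum())
            else:
                counts[d] = len(_spanning_clique_indices(dist, span1, span2, d))
        return potential, counts

    def pair_results(self, gid1: str, gid2: str) -> dict[SSMType, SSMCountResult]:
        """SSMCountResult for every grid type of one gene pair."""
        out: dict[SSMType, SSMCountResult] = {}
        for l, ds in sorted(self._ds_by_l.items()):
            potential, counts = self._pair_length_counts(gid1, gid2, l, ds)
            for d in ds:
                out[SSMType(l, d)] = SSMCountResult(
                    gene_pair=(gid1, gid2),
                    type=SSMType(l, d),
                    ssm_count=counts[d],
                    potential_count=potential,
                )
        return {t: out[t] for t in self.grid}

    def pair_result(self, gid1: str, gid2: str, type: SSMType) -> SSMCountResult:
        potential, counts = self._pair_length_counts(gid1, gid2, type.l, (type.d,))
        return SSMCountResult(
            gene_pair=(gid1, gid2),
            type=type,
            ssm_count=counts[type.d],
            potential_count=potential,
        )


def write_pair_results_tsv(
    results: Mapping[SSMType, SSMCountResult], path
) -> None:
    """Export per-pair results: gene1, gene2, l, d, ssm_count,
    potential_count, ssmc (empty field when degenerate)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tl\td\tssm_count\tpotential_count\tssmc\n")
        for t in sorted(results):
            r = results[t]
            ssmc = "" if r.ssmc is None else f"{r.ssmc:.8g}"
            fh.write(
                f"{r.gene_pair[0]}\t{r.gene_pair[1]}\t{t.l}\t{t.d}\t"
                f"{r.ssm_count}\t{r.potential_count}\t{ssmc}\n"
            )
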