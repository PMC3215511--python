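"""Functional statistics for gene lists (CEXlists).

* ``hypergeom_enrich`` — plain hypergeometric over-representation of
  annotation categories (GO/KEGG-like), upper tail P(X >= k), no
  ontology-graph conditioning, no multiple-testing correction.
* ``c_score`` — sum over over-represented categories of ln(1/p - 19);
  the constant 19 anchors the score at 0 for a category p-value of 0.05
  (the inclusion gate of the hypergeometric test).  Natural logarithm.
* ``build_cscore_null`` / ``z_score`` — null c_scores from random gene
  lists of a fixed size, standardised as (c - mu) / sigma.
* ``coexpression_density`` — fraction of a gene list found in an
  external co-expression set, |G ∩ S| / |S|.
* ``fisher_in_out`` — two-sided Fisher exact test of co-expressed genes
  inside versus outside the list, with the enrichment ratio
  (|G∩S|/|S|) / (|G\\S|/|U\\S|).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "AnnotationTable",
    "read_annotations",
    "write_annotations",
    "EnrichmentResult",
    "hypergeom_enrich",
    "c_score",
    "CScoreNull",
    "build_cscore_null",
    "z_score",
    "coexpression_density",
    "fisher_in_out",
    "read_coexpression",
    "write_coexpression",
]

C_SCORE_P_MAX = 0.05  # inclusion gate; also where ln(1/p - 19) = 0


@dataclass(frozen=True)
class AnnotationTable:
    """category_id -> gene set, over a fixed gene universe."""

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for cat, genes in self.categories.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"category {cat!r} annotates genes outside the universe: "
                    f"{sorted(extra)[:5]!r}"
                )


def read_annotations(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationTable:
    """Read a `category_id<TAB>gene_id` table; universe defaults to the
    union of annotated genes."""
    cats: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 fields, got {len(fields)}")
            cats.setdefault(fields[0], set()).add(fields[1])
    uni = frozenset(universe) if universe is not None else frozenset().union(*cats.values()) if cats else frozenset()
    return AnnotationTable({c: frozenset(g) for c, g in cats.items()}, uni)


def write_annotations(annot: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cat in sorted(annot.categories):
            for gid in sorted(annot.categories[cat]):
                fh.write(f"{cat}\t{gid}\n")


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    overlap: int  # k
    list_size: int  # m (after restriction to the universe)
    category_size: int  # K
    universe_size: int  # N
    p_value: float
    over_represented: bool


def hypergeom_enrich(
    gene_list: Iterable[str], annot: AnnotationTable, alpha: float = C_SCORE_P_MAX
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail over-representation per category.

    Categories with zero overlap are omitted; genes outside the universe
    are dropped with a warning.  Results sorted by ascending p-value.
    """
    if not annot.universe:
        raise ValueError("annotation universe is empty")
    genes = set(gene_list)
    outside = genes - annot.universe
    if outside:
        warnings.warn(
            f"{len(outside)} gene(s) outside the annotation universe dropped",
            stacklevel=2,
        )
        genes &= annot.universe
    n_universe = len(annot.universe)
    m = len(genes)
    out: list[EnrichmentResult] = []
    for cat, members in annot.categories.items():
        k = len(genes & members)
        if k == 0:
            continue
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, m))
        out.append(
            EnrichmentResult(
                category_id=cat,
                overlap=k,
                list_size=m,
                category_size=big_k,
                universe_size=n_universe,
                p_value=p,
                over_represented=p <= alpha,
            )
        )
    out.sort(key=lambda r: (r.p_value, r.category_id))
    return out


def c_score(p_values: Iterable[float]) -> float:
    """Sum of ln(1/p - 19) over category p-values in (0, 0.05].

    Zero for an empty list and for a single category at p = 0.05;
    strictly decreasing in each p.  Values above 0.05 (which approach
    the 1/19 singularity) are a caller error.
    """
    total = 0.0
    for p in p_values:
        if not 0 < p <= C_SCORE_P_MAX:
            raise ValueError(f"c_score is defined for p in (0, {C_SCORE_P_MAX}]; got {p}")
        total += math.log(1.0 / p - 19.0)
    return total


@dataclass(frozen=True)
class CScoreNull:
    """Null c_score sample from random gene lists of one size."""

    list_size: int
    scores: np.ndarray
    mean: float
    sd: float  # sample standard deviation
    n_lists: int


def build_cscore_null(
    genes: Iterable[str],
    annot: AnnotationTable,
    list_size: int,
    n_lists: int = 200,
    seed: int = 0,
    alpha: float = C_SCORE_P_MAX,
) -> CScoreNull:
    """c_score null over ``n_lists`` random lists sampled without
    replacement from ``genes``; each list's score sums its
    over-represented categories (p <= alpha)."""
    genes = sorted(set(genes))
    if list_size > len(genes):
        raise ValueError(f"list_size {list_size} exceeds universe of {len(genes)} genes")
    if n_lists < 2:
        raise ValueError("n_lists must be >= 2")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_lists)
    for i in range(n_lists):
        chosen = rng.choice(genes, size=list_size, replace=False)
        results = hypergeom_enrich(chosen, annot, alpha=alpha)
        scores[i] = c_score([r.p_value for r in results if r.over_represented])
    return CScoreNull(
        list_size=list_size,
        scores=scores,
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)),
        n_lists=n_lists,
    )


def z_score(c: float, null: CScoreNull) -> float:
    """Standardised c_score: (c - mu) / sigma against the random-list null."""
    if null.sd <= 0:
        raise ValueError("degenerate c_score null (sigma = 0)")
    return (c - null.mean) / null.sd


def coexpression_density(coexpressed: Iterable[str], list_genes: Iterable[str]) -> float | None:
    """|G ∩ S| / |S|; None (undefined) for an empty list S."""
    s = set(list_genes)
    if not s:
        return None
    return len(set(coexpressed) & s) / len(s)


def fisher_in_out(
    coexpressed: Iterable[str],
    list_genes: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, float]:
    """Enrichment of co-expressed genes inside vs outside a gene list.

    Returns (enrichment_ratio, two-sided Fisher exact p) for the 2x2
    table {in/out of list} x {co-expressed or not} over the universe.
    The ratio is (|G∩S|/|S|) / (|G\\S|/|U\\S|): 0.0 when the list holds
    no co-expressed gene, inf when all co-expressed genes are inside.
    """
    u = set(universe)
    s = set(list_genes)
    g = set(coexpressed)
    if not s <= u or not g <= u:
        raise ValueError("list and co-expression sets must be subsets of the universe")
    if not s or len(u) == len(s):
        raise ValueError("need a non-empty list and a non-empty complement")
    a = len(g & s)
    b = len(s - g)
    c = len(g - s)
    d = len(u) - len(s) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    in_rate = a / len(s)
    out_rate = c / (len(u) - len(s))
    if a == 0:
        ratio = 0.0
    elif out_rate == 0:
        ratio = math.inf
    else:
        ratio = in_rate / out_rate
    return ratio, float(p)


def read_coexpression(path: str | Path) -> dict[str, set[str]]:
    """Read a symmetric `gene<TAB>gene` co-expression table."""
    table: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 fields, got {len(fields)}")
            a, b = fields
            table.setdefault(a, set()).add(b)
            table.setdefault(b, set()).add(a)
    return table


def write_coexpression(table: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write each unordered pair once, smaller gene id first."""
    pairs = sorted(
        {(min(a, b), max(a, b)) for a, partners in table.items() for b in partners}
    )
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
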