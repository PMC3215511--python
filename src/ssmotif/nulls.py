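"""Empirical SSMC nulls, pair p-values, cp-values and CEXlists.

The SSMC of an observed gene pair is judged against an empirical null
built from random pairs of distinct genes drawn from the database.  The
right-tail probability of an observed SSMC under the null sample of size
n is estimated with add-one smoothing,

    p = (#{null >= observed} + 1) / (n + 1),

which is bounded in [1/(n+1), 1] and never zero from a finite sample.
Degenerate pairs (zero potential SSMs on one side) contribute SSMC = 0
to null samples and receive p = 1 when scored: absence of material is
absence of evidence.

The cp-value of a pair is the minimum p-value over the (l, d) type grid
— a raw minimum, deliberately uncorrected for the ~31 types, so it is
anti-conservative as an absolute probability and is used as a ranking /
thresholding score.  The CEXlist of a query gene at threshold ``t``
holds every other gene whose cp-value against the query is below ``t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import SSMEngine, SSMType, ssm_type_grid
from .motifs import GeneMotifSet, MotifDatabase

__all__ = [
    "NullDistribution",
    "sample_null",
    "build_nulls",
    "empirical_p",
    "TypeScore",
    "PairScore",
    "score_pair",
    "CexMember",
    "CEXList",
    "build_cexlist",
    "save_nulls",
    "load_nulls",
    "write_cexlist_tsv",
    "read_cexlist_tsv",
]


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null sample of SSMC values for one SSM type."""

    type: SSMType
    sample: np.ndarray  # sorted ascending
    n: int

    def __post_init__(self) -> None:
        if self.n < 1 or len(self.sample) != self.n:
            raise ValueError("null sample must be non-empty and match n")


def _sample_pairs(
    gene_ids: Sequence[str], n_pairs: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Unordered pairs of distinct genes, uniform with replacement across
    pairs (a pair may repeat; the two genes of a pair never coincide)."""
    n = len(gene_ids)
    i = rng.integers(0, n, n_pairs)
    j = rng.integers(0, n - 1, n_pairs)
    j = j + (j >= i)
    return [(gene_ids[a], gene_ids[b]) for a, b in zip(i, j)]


def build_nulls(
    db: MotifDatabase,
    grid: Iterable[SSMType] | None = None,
    n_pairs: int = 50_000,
    seed: int = 0,
    engine: SSMEngine | None = None,
) -> dict[SSMType, NullDistribution]:
    """Null distributions for every grid type from one shared seeded pair list.

    All types are evaluated on the same ``n_pairs`` random distinct-gene
    pairs, so ``build_nulls(db, [t], n, s)[t] == sample_null(db, t, n, s)``.
    Degenerate pairs contribute SSMC = 0.
    """
    if len(db) < 2:
        raise ValueError("null sampling requires a database with >= 2 genes")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    grid = tuple(grid) if grid is not None else ssm_type_grid()
    engine = engine or SSMEngine(db, grid)
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(db.gene_ids, n_pairs, rng)
    values: dict[SSMType, list[float]] = {t: [] for t in grid}
    for g1, g2 in pairs:
        results = engine.pair_results(g1, g2)
        for t in grid:
            ssmc = results[t].ssmc
            values[t].append(0.0 if ssmc is None else ssmc)
    return {
        t: NullDistribution(type=t, sample=np.sort(np.asarray(v)), n=n_pairs)
        for t, v in values.items()
    }


def sample_null(
    db: MotifDatabase, type: SSMType, n_pairs: int, seed: int
) -> NullDistribution:
    """Empirical SSMC null for one type (see ``build_nulls``)."""
    return build_nulls(db, (type,), n_pairs, seed)[type]


def empirical_p(null: NullDistribution, observed: float) -> float:
    """Add-one-smoothed right-tail probability of ``observed`` under the null.

    Ties count in the tail ("equal or greater").  Bounded in
    [1/(n+1), 1]; non-increasing in ``observed``.
    """
    r = null.n - int(np.searchsorted(null.sample, observed, side="left"))
    return (r + 1) / (null.n + 1)


@dataclass(frozen=True)
class TypeScore:
    ssmc: float | None
    p_value: float


@dataclass(frozen=True)
class PairScore:
    """Per-type SSMC and p-values for a gene pair, plus their minimum
    (the cp-value) and the type attaining it."""

    gene_pair: tuple[str, str]
    per_type: dict[SSMType, TypeScore]
    cp_value: float
    best_type: SSMType


def _score_from_results(
    gene_pair: tuple[str, str],
    results: Mapping[SSMType, "object"],
    nulls: Mapping[SSMType, NullDistribution],
    grid: Sequence[SSMType],
) -> PairScore:
    per_type: dict[SSMType, TypeScore] = {}
    for t in grid:
        if t not in nulls:
            raise ValueError(f"missing null distribution for type {t!r}")
        ssmc = results[t].ssmc
        p = 1.0 if ssmc is None else empirical_p(nulls[t], ssmc)
        per_type[t] = TypeScore(ssmc=ssmc, p_value=p)
    best_type = min(sorted(grid), key=lambda t: per_type[t].p_value)
    return PairScore(
        gene_pair=gene_pair,
        per_type=per_type,
        cp_value=per_type[best_type].p_value,
        best_type=best_type,
    )


def score_pair(
    g1: GeneMotifSet,
    g2: GeneMotifSet,
    nulls: Mapping[SSMType, NullDistribution],
    grid: Iterable[SSMType] | None = None,
) -> PairScore:
    """SSMC p-value per grid type and the cp-value (their minimum).

    Types with degenerate SSMC score p = 1 (no evidence)."""
    grid = tuple(grid) if grid is not None else ssm_type_grid()
    db = MotifDatabase([g1] if g1.gene_id == g2.gene_id else [g1, g2])
    engine = SSMEngine(db, grid)
    results = engine.pair_results(g1.gene_id, g2.gene_id)
    return _score_from_results((g1.gene_id, g2.gene_id), results, nulls, grid)


@dataclass(frozen=True)
class CexMember:
    gene_id: str
    cp_value: float
    best_type: SSMType


@dataclass(frozen=True)
class CEXList:
    """Genes whose cp-value against the query falls strictly below ``t``,
    sorted ascending by cp-value (ties broken by gene_id)."""

    query_gene: str
    threshold: float
    members: tuple[CexMember, ...]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(m.gene_id for m in self.members)


def build_cexlist(
    query: str,
    db: MotifDatabase,
    grid: Iterable[SSMType] | None,
    nulls: Mapping[SSMType, NullDistribution],
    t: float,
    engine: SSMEngine | None = None,
) -> CEXList:
    """Score ``query`` against every other gene and keep cp-value < t.

    Pass a shared ``engine`` when building many CEXlists over one
    database so gene window profiles are computed once.
    """
    if query not in db:
        raise KeyError(f"query gene {query!r} not in database")
    if not 0 < t <= 1:
        raise ValueError(f"threshold t must be in (0, 1], got {t}")
    grid = tuple(grid) if grid is not None else ssm_type_grid()
    engine = engine or SSMEngine(db, grid)
    members = []
    for gid in db.gene_ids:
        if gid == query:
            continue
        results = engine.pair_results(query, gid)
        score = _score_from_results((query, gid), results, nulls, grid)
        if score.cp_value < t:
            members.append(CexMember(gid, score.cp_value, score.best_type))
    members.sort(key=lambda m: (m.cp_value, m.gene_id))
    return CEXList(query_gene=query, threshold=t, members=tuple(members))


# ---------------------------------------------------------------------------
# On-disk null cache: one TSV of sorted SSMC values per type plus a JSON
# sidecar recording the database hash, pair count and seed.
# ---------------------------------------------------------------------------


def _null_basename(t: SSMType) -> str:
    return f"null_l{t.l}_d{t.d}"


def null_cache_paths(cache_dir: str | Path, t: SSMType) -> tuple[Path, Path]:
    base = Path(cache_dir) / _null_basename(t)
    return base.with_suffix(".tsv"), base.with_suffix(".json")


def save_nulls(
    nulls: Mapping[SSMType, NullDistribution],
    cache_dir: str | Path,
    *,
    db_hash: str,
    n_pairs: int,
    seed: int,
) -> None:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    for t, null in nulls.items():
        tsv, sidecar = null_cache_paths(cache_dir, t)
        with open(tsv, "w", encoding="utf-8") as fh:
            fh.write("ssmc\n")
            for v in null.sample:
                fh.write(f"{float(v)!r}\n")
        meta = {"db_hash": db_hash, "n_pairs": n_pairs, "seed": seed, "l": t.l, "d": t.d}
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")


def load_nulls(
    cache_dir: str | Path,
    grid: Iterable[SSMType],
    *,
    db_hash: str | None = None,
    n_pairs: int | None = None,
    seed: int | None = None,
) -> dict[SSMType, NullDistribution]:
    """Load cached nulls for every grid type, checking sidecar metadata
    against any expectation supplied (db hash, pair count, seed)."""
    cache_dir = Path(cache_dir)
    out: dict[SSMType, NullDistribution] = {}
    for t in grid:
        tsv, sidecar = null_cache_paths(cache_dir, t)
        if not tsv.exists() or not sidecar.exists():
            raise FileNotFoundError(
                f"no cached null for {t!r} in {cache_dir} "
                f"(expected {tsv.name} and {sidecar.name}); run null sampling first"
            )
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        for key, expected in (("db_hash", db_hash), ("n_pairs", n_pairs), ("seed", seed)):
            if expected is not None and meta.get(key) != expected:
                raise ValueError(
                    f"stale null cache for {t!r}: {key} is {meta.get(key)!r}, "
                    f"expected {expected!r}"
                )
        with open(tsv, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header != "ssmc":
                raise ValueError(f"{tsv}: unexpected header {header!r}")
            sample = np.asarray([float(line) for line in fh], dtype=float)
        out[t] = NullDistribution(type=t, sample=np.sort(sample), n=len(sample))
    return out


def is_cached(cache_dir: str | Path, t: SSMType, *, db_hash: str, n_pairs: int, seed: int) -> bool:
    tsv, sidecar = null_cache_paths(cache_dir, t)
    if not tsv.exists() or not sidecar.exists():
        return False
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return (
        meta.get("db_hash") == db_hash
        and meta.get("n_pairs") == n_pairs
        and meta.get("seed") == seed
    )


def write_cexlist_tsv(cex: CEXList, path: str | Path) -> None:
    """Export: rank, gene_id, cp_value, best (l, d) type."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# query={cex.query_gene}\tt={cex.threshold!r}\n")
        fh.write("rank\tgene_id\tcp_value\tbest_l\tbest_d\n")
        for rank, m in enumerate(cex.members, start=1):
            fh.write(
                f"{rank}\t{m.gene_id}\t{m.cp_value!r}\t{m.best_type.l}\t{m.best_type.d}\n"
            )


def read_cexlist_tsv(path: str | Path) -> CEXList:
    with open(path, encoding="utf-8") as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# query="):
            raise ValueError(f"{path}: missing CEXlist metadata line")
        query_part, t_part = meta[2:].split("\t")
        query = query_part.split("=", 1)[1]
        threshold = float(t_part.split("=", 1)[1])
        header = fh.readline().strip()
        if header != "rank\tgene_id\tcp_value\tbest_l\tbest_d":
            raise ValueError(f"{path}: unexpected header {header!r}")
        members = []
        for line in fh:
            _, gid, cp, l, d = line.rstrip("\n").split("\t")
            members.append(CexMember(gid, float(cp), SSMType(int(l), int(d))))
    return CEXList(query_gene=query, threshold=threshold, members=tuple(members))
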