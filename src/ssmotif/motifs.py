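"""Data model and I/O for motif databases.

A motif database maps gene identifiers to sets of *atomic motifs*: short
conserved promoter sequences (phylogenetic footprints) that are the raw
material of the shared-motif analysis.  Two plain-text encodings are
supported:

* TSV dialect: header line ``gene_id<TAB>motif_id<TAB>sequence``, one
  motif per row, ``#`` comment lines ignored, UTF-8.
* FASTA dialect: header ``>GENEID|MOTIFID`` with the sequence on the
  following line(s); standard wrapping is accepted.

Sequences are normalised to uppercase on ingestion.  Residues outside
{A, C, G, T} are rejected (``strict`` policy, default) or the offending
motif is dropped with a warning (``drop`` policy): Hamming distances and
complementation are undefined for ambiguity codes.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .extended import DNA_ALPHABET

__all__ = [
    "AtomicMotif",
    "GeneMotifSet",
    "MotifDatabase",
    "MotifFormatError",
    "MotifValidationError",
    "DbSummary",
    "read_motif_db",
    "write_motif_db",
    "db_summary",
]


class MotifFormatError(ValueError):
    """Malformed input file (bad header, wrong field count, bad record id)."""


class MotifValidationError(ValueError):
    """Structurally valid input that violates database invariants."""


@dataclass(frozen=True, slots=True)
class AtomicMotif:
    """One conserved promoter sequence of a gene.

    ``motif_id`` is unique within its gene; ``sequence`` is an uppercase
    DNA word over {A, C, G, T}.
    """

    motif_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.motif_id:
            raise MotifValidationError("motif_id must be non-empty")
        if not self.sequence:
            raise MotifValidationError(f"motif {self.motif_id!r}: empty sequence")
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise MotifValidationError(
                f"motif {self.motif_id!r}: non-ACGT residue(s) {bad!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneMotifSet:
    """A gene and its ordered list of atomic motifs (possibly empty)."""

    gene_id: str
    motifs: tuple[AtomicMotif, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise MotifValidationError("gene_id must be non-empty")
        object.__setattr__(self, "motifs", tuple(self.motifs))
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MotifValidationError(
                f"gene {self.gene_id!r}: duplicate motif id(s) {dup!r}"
            )

    def __len__(self) -> int:
        return len(self.motifs)

    def motif_lengths(self) -> tuple[int, ...]:
        return tuple(m.length for m in self.motifs)


class MotifDatabase:
    """Mapping gene_id -> GeneMotifSet with deterministic (sorted) iteration."""

    def __init__(self, genes: Iterable[GeneMotifSet] = ()) -> None:
        self._genes: dict[str, GeneMotifSet] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise MotifValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneMotifSet:
        return self._genes[gene_id]

    def __iter__(self) -> Iterator[GeneMotifSet]:
        for gid in self.gene_ids:
            yield self._genes[gid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifDatabase):
            return NotImplemented
        return dict(sorted(self._genes.items())) == dict(sorted(other._genes.items()))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._genes))

    @property
    def n_motifs(self) -> int:
        return sum(len(g) for g in self._genes.values())

    def content_hash(self) -> str:
        """SHA-256 of the canonical serialisation (keys sorted); used to tag
        on-disk null caches so stale caches are detected."""
        h = hashlib.sha256()
        for gid in self.gene_ids:
            for m in self._genes[gid].motifs:
                h.update(f"{gid}\t{m.motif_id}\t{m.sequence}\n".encode())
        return h.hexdigest()


_TSV_HEADER = ("gene_id", "motif_id", "sequence")


def _ingest(
    records: Iterable[tuple[str, str, str, str]], policy: str
) -> MotifDatabase:
    """Common ingestion/validation path.

    ``records`` yields (gene_id, motif_id, raw_sequence, location) tuples;
    ``location`` names the source line/record for error messages.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown alphabet policy {policy!r}")
    per_gene: dict[str, list[AtomicMotif]] = {}
    seen: set[tuple[str, str]] = set()
    for gene_id, motif_id, raw, loc in records:
        if not gene_id or not motif_id:
            raise MotifFormatError(f"{loc}: empty gene_id or motif_id")
        seq = raw.strip().upper()
        if (gene_id, motif_id) in seen:
            raise MotifValidationError(
                f"{loc}: duplicate (gene_id, motif_id) = ({gene_id!r}, {motif_id!r})"
            )
        seen.add((gene_id, motif_id))
        if not seq or not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            msg = f"{loc}: motif {gene_id!r}/{motif_id!r} has non-ACGT residue(s) {bad!r}"
            if policy == "strict":
                raise MotifValidationError(msg)
            warnings.warn(f"dropping motif: {msg}", stacklevel=3)
            per_gene.setdefault(gene_id, [])
            continue
        per_gene.setdefault(gene_id, []).append(AtomicMotif(motif_id, seq))
    return MotifDatabase(
        GeneMotifSet(gid, tuple(motifs)) for gid, motifs in per_gene.items()
    )


def _read_tsv_records(path: Path) -> Iterator[tuple[str, str, str, str]]:
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _TSV_HEADER:
                    raise MotifFormatError(
                        f"line {ln}: expected header {_TSV_HEADER}, got {tuple(fields)}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise MotifFormatError(
                    f"line {ln}: expected 3 tab-separated fields, got {len(fields)}"
                )
            yield fields[0], fields[1], fields[2], f"line {ln}"
        if not header_seen:
            raise MotifFormatError("missing header line")


def _read_fasta_records(path: Path) -> Iterator[tuple[str, str, str, str]]:
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if "|" not in rec.id:
            raise MotifFormatError(
                f"record {i} ({rec.id!r}): FASTA id must be 'GENEID|MOTIFID'"
            )
        gene_id, motif_id = rec.id.split("|", 1)
        yield gene_id, motif_id, str(rec.seq), f"record {i} ({rec.id!r})"


def read_motif_db(path: str | Path, format: str = "tsv", policy: str = "strict") -> MotifDatabase:
    """Read a motif database from ``path``.

    Parameters
    ----------
    format : {"tsv", "fasta"}
    policy : {"strict", "drop"}
        How to treat motifs with residues outside {A,C,G,T} after
        uppercasing: raise (strict) or drop with a warning.
    """
    path = Path(path)
    if format == "tsv":
        return _ingest(_read_tsv_records(path), policy)
    if format == "fasta":
        return _ingest(_read_fasta_records(path), policy)
    raise ValueError(f"unknown format {format!r}")


def write_motif_db(db: MotifDatabase, path: str | Path, format: str = "tsv") -> None:
    """Write ``db`` so that ``read_motif_db`` round-trips it exactly."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for gene in db:
                for m in gene.motifs:
                    fh.write(f"{gene.gene_id}\t{m.motif_id}\t{m.sequence}\n")
    elif format == "fasta":
        records = [
            SeqRecord(Seq(m.sequence), id=f"{gene.gene_id}|{m.motif_id}", description="")
            for gene in db
            for m in gene.motifs
        ]
        with open(path, "w", encoding="utf-8") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        raise ValueError(f"unknown format {format!r}")


@dataclass(frozen=True)
class DbSummary:
    """Database-level statistics; fields are None when undefined
    (empty database, or fewer than two observations for a standard
    deviation) rather than zero."""

    n_genes: int
    n_motifs: int
    motifs_per_gene_mean: float | None
    motifs_per_gene_sd: float | None
    motif_length_mean: float | None
    motif_length_sd: float | None


def _mean_sd(values: list[int]) -> tuple[float | None, float | None]:
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def db_summary(db: MotifDatabase) -> DbSummary:
    """Gene count, motifs-per-gene and motif-length moments (sample sd)."""
    counts = [len(g) for g in db]
    lengths = [m.length for g in db for m in g.motifs]
    cm, cs = _mean_sd(counts)
    lm, ls = _mean_sd(lengths)
    return DbSummary(len(db), len(lengths), cm, cs, lm, ls)
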