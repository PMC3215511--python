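"""Extended sequences: strand/orientation closure of DNA words.

A DNA word ``w`` is treated as equivalent to its base-wise complement
``w_c``, its reversal ``w_r`` and its reverse complement ``w_rc``.  The
four transforms form a Klein four-group acting on words, so the closure
``{w, w_c, w_r, w_rc}`` is an orbit: any member generates the same set.
Orbits have size 1, 2 or 4 (palindromic structure collapses members).

Distances between extended sequences are the minimum Hamming distance
over all cross pairs of members; because the orbit is a group orbit the
distance is 0 exactly when the two orbits coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_dna(w: str) -> None:
    if not w:
        raise ValueError("empty sequence")
    if not set(w) <= DNA_ALPHABET:
        bad = sorted(set(w) - DNA_ALPHABET)
        raise ValueError(f"sequence contains non-ACGT residue(s): {bad!r}")


def complement(w: str) -> str:
    """Base-wise complement (A<->T, C<->G), same orientation."""
    return w.translate(_COMPLEMENT)


def reverse(w: str) -> str:
    """Reversal of the word without complementation."""
    return w[::-1]


def reverse_complement(w: str) -> str:
    return w[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class ExtendedSequence:
    """The orbit {w, w_c, w_r, w_rc} of a DNA word.

    The canonical key (lexicographically smallest member) identifies the
    orbit and is used for all deterministic orderings downstream.
    """

    members: frozenset[str]

    @property
    def canonical(self) -> str:
        return min(self.members)

    @property
    def length(self) -> int:
        return len(next(iter(self.members)))

    def __contains__(self, w: str) -> bool:
        return w in self.members


def extended_members(w: str) -> tuple[str, ...]:
    """Sorted distinct members of the orbit of ``w`` (no validation)."""
    rev = w[::-1]
    comp = w.translate(_COMPLEMENT)
    return tuple(sorted({w, comp, rev, rev.translate(_COMPLEMENT)}))


@lru_cache(maxsize=1 << 18)
def canonical_key(w: str) -> str:
    """Lexicographically smallest member of the orbit of ``w``."""
    rev = w[::-1]
    comp = w.translate(_COMPLEMENT)
    return min(w, comp, rev, rev.translate(_COMPLEMENT))


def build_extended(w: str) -> ExtendedSequence:
    """Build the extended sequence (orbit) of a validated DNA word."""
    _check_dna(w)
    return ExtendedSequence(frozenset(extended_members(w)))


def hamming(a: str, b: str) -> int:
    """Standard Hamming distance between equal-length words."""
    if len(a) != len(b):
        raise ValueError(f"Hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def extended_distance(w1: ExtendedSequence, w2: ExtendedSequence) -> int:
    """min Hamming distance over all member pairs of two orbits.

    Symmetric; zero exactly when the orbits coincide (share a member).
    """
    l1, l2 = w1.length, w2.length
    if l1 != l2:
        raise ValueError(f"extended distance undefined for lengths {l1} != {l2}")
    return min(hamming(a, b) for a in w1.members for b in w2.members)
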