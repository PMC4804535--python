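"""Minimal absent word (MAW) enumeration.

A word is *absent* from a sequence when it occurs in no segment as a
factor (substring). An absent word is *minimal* when every proper factor
of it does occur. MAWs form a compact fingerprint of a sequence: the full
(infinite) set of absent words is exactly the set of words containing a
MAW, so the MAW set carries all of the absence information.

Enumeration here uses the two-sided extension characterisation: a word
``y`` with ``|y| >= 2`` is a MAW iff ``y`` is absent while both ``y[:-1]``
and ``y[1:]`` are present — every proper factor of ``y`` is a factor of
one of those two maximal ones. Single-character MAWs are the alphabet
symbols that never occur. Scanning the present factor sets length by
length gives an O(n^2 * |Σ|) procedure, ample for the gene-scale inputs
this package targets; `brute_force_maws` is the literal-definition oracle
used to validate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .sequences import Alphabet, SeqRecord, Setting, ValidationError

__all__ = ["WordSet", "enumerate_maws", "brute_force_maws", "write_words"]

BRUTE_FORCE_GUARD = 2000  # total residues; the oracle is for test scale only


@dataclass(frozen=True)
class WordSet:
    """A finite set of words over an alphabet, with provenance.

    ``kind`` records what the set is (MAW set, minimal relative absent
    word set, or plain k-mer set); ``source_ids`` is the record id
    (MAW/KMER) or the ordered (target, reference) pair (RAW).
    """

    alphabet: Alphabet
    words: frozenset[str]
    kind: Literal["MAW", "RAW", "KMER"]
    source_ids: tuple[str, ...]
    setting: Setting = "noRC"

    def __post_init__(self) -> None:
        ok = set(self.alphabet.symbols)
        for w in self.words:
            if not w or set(w) - ok:
                raise ValidationError(f"word {w!r} is not over the alphabet")

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __contains__(self, w: str) -> bool:
        return w in self.words

    def sorted(self) -> list[str]:
        """Words ordered by length then lexicographically."""
        return sorted(self.words, key=lambda w: (len(w), w))


def _factor_sets(segments: tuple[str, ...], max_len: int) -> list[set[str]]:
    """factors[k] = set of distinct length-k factors of any segment, k <= max_len."""
    factors: list[set[str]] = [set() for _ in range(max_len + 1)]
    for seg in segments:
        n = len(seg)
        for k in range(1, min(max_len, n) + 1):
            fk = factors[k]
            for i in range(n - k + 1):
                fk.add(seg[i : i + k])
    return factors


def enumerate_maws(r: SeqRecord, max_len: int | None = None) -> WordSet:
    """Enumerate the minimal absent words of a record.

    Presence means presence in at least one segment. Every MAW of a record
    whose longest segment has length ``n`` has length at most ``n + 1``,
    so ``max_len=None`` (the default) is effectively unbounded; pass a cap
    to truncate the enumeration for long inputs.
    """
    natural_bound = max(len(s) for s in r.segments) + 1
    bound = natural_bound if max_len is None else min(max_len, natural_bound)
    if bound < 1:
        raise ValidationError("max_len must be >= 1")
    factors = _factor_sets(r.segments, bound)
    maws: set[str] = set()
    # length 1: symbols that never occur anywhere
    maws.update(a for a in r.alphabet.symbols if a not in factors[1])
    symbols = r.alphabet.symbols
    for k in range(2, bound + 1):
        present_prev = factors[k - 1]
        present_k = factors[k]
        for v in present_prev:
            for a in symbols:
                cand = a + v
                if cand not in present_k and cand[:-1] in present_prev:
                    maws.add(cand)
    return WordSet(r.alphabet, frozenset(maws), "MAW", (r.id,), r.setting)


def _is_factor(word: str, segments: tuple[str, ...]) -> bool:
    return any(word in seg for seg in segments)


def brute_force_maws(r: SeqRecord, max_len: int) -> WordSet:
    """Literal-definition MAW oracle.

    Walks the word tree up to ``max_len``; for every candidate, absence is
    tested by substring search over every segment and *all* proper factors
    are tested for presence the same way. The only shortcut is forced by
    the definition itself: a word extending an absent word contains it as
    a proper factor and so can never be minimal, hence only present words
    are extended. Guarded to test-scale inputs.
    """
    if sum(len(s) for s in r.segments) > BRUTE_FORCE_GUARD:
        raise ValidationError(
            f"brute force infeasible: more than {BRUTE_FORCE_GUARD} residues"
        )
    maws: set[str] = set()
    present: list[str] = [""]
    for _ in range(max_len):
        frontier: list[str] = []
        for w in present:
            for a in r.alphabet.symbols:
                y = w + a
                if _is_factor(y, r.segments):
                    frontier.append(y)
                    continue
                proper = {y[i:j] for i in range(len(y)) for j in range(i + 1, len(y) + 1)}
                proper.discard(y)
                if all(_is_factor(f, r.segments) for f in proper):
                    maws.add(y)
        present = frontier
    return WordSet(r.alphabet, frozenset(maws), "MAW", (r.id,), r.setting)


def write_words(ws: WordSet, path) -> None:
    """Plain-text export: one word per line, lexicographic order."""
    with open(path, "w") as fh:
        for w in sorted(ws.words):
            fh.write(w + "\n")
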