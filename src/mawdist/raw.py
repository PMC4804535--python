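"""Relative absent words (RAWs).

A relative absent word of a *target* sequence with respect to a
*reference* is a word present in the target but absent from the
reference. The k-th relative set is

    R_k(target, reference) = W_k(target) \\ W_k(reference)

where W_k denotes the set of distinct length-k factors. The *minimal*
relative absent words are filtered iteratively: M_1 = R_1, and a word of
R_k survives into M_k only if no proper factor of it is already minimal
at a smaller length — a minimal word cannot contain a shorter minimal
word. (Checking only the length-(k-1) factors against M_{k-1} is not
enough: a level can be empty while shorter minimal words still occur
inside longer relative words, e.g. ACG vs the reference AAAA contains
the minimal word C although no length-2 relative word is minimal.)
The union of the M_k is the minimal RAW set — the directed dissimilarity
fingerprint used by the RAW-based distance indices.
"""

from __future__ import annotations

from .maw import WordSet
from .sequences import SeqRecord, ValidationError

__all__ = ["kmer_words", "relative_words", "minimal_relative_words", "DEFAULT_K_MAX"]

#: Default upper bound on RAW length. Length-weighted terms decay as 1/k^2,
#: so words beyond this length contribute negligibly.
DEFAULT_K_MAX = 24


def _kmers(segments: tuple[str, ...], k: int) -> set[str]:
    out: set[str] = set()
    for seg in segments:
        for i in range(len(seg) - k + 1):
            out.add(seg[i : i + k])
    return out


def kmer_words(r: SeqRecord, k: int) -> WordSet:
    """The set of distinct length-k factors of any segment of *r*.

    Empty when every segment is shorter than k; k-mers never span
    segment boundaries.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    return WordSet(r.alphabet, frozenset(_kmers(r.segments, k)), "KMER", (r.id,), r.setting)


def _check_pair(target: SeqRecord, reference: SeqRecord) -> None:
    if target.alphabet.symbols != reference.alphabet.symbols:
        raise ValidationError(
            f"alphabet mismatch between {target.id!r} and {reference.id!r}"
        )


def relative_words(target: SeqRecord, reference: SeqRecord, k: int) -> WordSet:
    """R_k: length-k factors of the target that the reference lacks."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    _check_pair(target, reference)
    rk = _kmers(target.segments, k) - _kmers(reference.segments, k)
    return WordSet(
        target.alphabet, frozenset(rk), "RAW", (target.id, reference.id), target.setting
    )


def minimal_relative_words(
    target: SeqRecord, reference: SeqRecord, k_max: int = DEFAULT_K_MAX
) -> WordSet:
    """Minimal relative absent words of *target* w.r.t. *reference*.

    Iterates k = 1..k_max, keeping at each level the relative words that
    contain no already-minimal shorter word as a factor; returns the
    union over k. Stops early once the target has no k-mers at all.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    _check_pair(target, reference)

    def contains_minimal(w: str, minimal: set[str], lengths: set[int]) -> bool:
        for j in lengths:
            for i in range(len(w) - j + 1):
                if w[i : i + j] in minimal:
                    return True
        return False

    minimal: set[str] = set()
    seen_lengths: set[int] = set()
    for k in range(1, k_max + 1):
        target_k = _kmers(target.segments, k)
        if not target_k:
            break
        rk = target_k - _kmers(reference.segments, k)
        level = {w for w in rk if not contains_minimal(w, minimal, seen_lengths)}
        minimal |= level
        if level:
            seen_lengths.add(k)
    return WordSet(
        target.alphabet,
        frozenset(minimal),
        "RAW",
        (target.id, reference.id),
        target.setting,
    )
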