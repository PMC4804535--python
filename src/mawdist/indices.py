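"""(Dis)similarity indices over absent-word sets.

Given the MAW sets of two sequences (or the two directed minimal RAW
sets of an ordered pair), these indices condense them into a single
number. Five operate on MAW sets:

* ``lwi_symmetric_difference`` — length-weighted index sum(1/|u|^2) over
  the symmetric difference; weights short (more surprising) absent words
  more heavily.
* ``lwi_intersection`` — negated length-weighted index of the
  intersection: shared absent words indicate similarity, hence <= 0.
* ``jaccard_distance`` — 1 - |intersection| / |union|.
* ``tvd`` — total variation distance between the normalized word-length
  histograms of the two sets.
* ``gcc_symmetric_difference`` / ``gcc_intersection`` — compositional
  (G+C) bias of the symmetric difference / intersection.

Two operate on directed RAW sets, averaging the two directions:
``raw_lwi_distance`` and ``raw_gcc_distance``.

Empty-set conventions (chosen for continuity with the identical-sequence
limit on difference-type measures, and maximal dissimilarity on
intersection-type measures): Jaccard(∅,∅)=0; GC of an empty symmetric
difference is 0; GC-intersection of an empty intersection is 1; an empty
RAW set contributes 0 GC. TVD of an empty word set is an error — there is
no distribution to normalize.
"""

from __future__ import annotations

from collections import Counter

from .maw import WordSet
from .sequences import ValidationError

__all__ = [
    "MAW_MEASURES",
    "RAW_MEASURES",
    "MEASURES",
    "lwi",
    "lwi_symmetric_difference",
    "lwi_intersection",
    "jaccard_distance",
    "tvd",
    "gcc_symmetric_difference",
    "gcc_intersection",
    "raw_lwi_distance",
    "raw_gcc_distance",
    "length_histogram",
    "gc_fraction",
]

MAW_MEASURES = ("lwi_sym", "lwi_int", "jaccard", "tvd", "gcc_sym", "gcc_int")
RAW_MEASURES = ("raw_lwi", "raw_gcc")
MEASURES = MAW_MEASURES + RAW_MEASURES


def _check_compatible(mx: WordSet, my: WordSet) -> None:
    if mx.alphabet.symbols != my.alphabet.symbols:
        raise ValidationError("word sets are over different alphabets")
    if mx.setting != my.setting:
        raise ValidationError(
            f"word sets from different settings: {mx.setting} vs {my.setting}"
        )


def _check_dna(ws: WordSet) -> None:
    if not ws.alphabet.is_dna:
        raise ValidationError("GC-content measures require the DNA alphabet")


def lwi(words: WordSet | frozenset[str] | set[str]) -> float:
    """Length-weighted index: sum of 1/|u|^2 over the words; 0 for an empty set."""
    it = words.words if isinstance(words, WordSet) else words
    return sum(1.0 / len(u) ** 2 for u in it)


def lwi_symmetric_difference(mx: WordSet, my: WordSet) -> float:
    """Length-weighted index of the symmetric difference of two word sets."""
    _check_compatible(mx, my)
    return lwi(mx.words ^ my.words)


def lwi_intersection(mx: WordSet, my: WordSet) -> float:
    """Negated length-weighted index of the intersection (a similarity, hence <= 0)."""
    _check_compatible(mx, my)
    return -lwi(mx.words & my.words)


def jaccard_distance(mx: WordSet, my: WordSet) -> float:
    """1 - intersection-over-union; two empty sets compare as identical (0)."""
    _check_compatible(mx, my)
    union = mx.words | my.words
    if not union:
        return 0.0
    return 1.0 - len(mx.words & my.words) / len(union)


def length_histogram(words: frozenset[str] | set[str]) -> Counter[int]:
    """Counts of words per length."""
    return Counter(len(w) for w in words)


def tvd(mx: WordSet, my: WordSet) -> float:
    """Total variation distance between normalized word-length histograms.

    Both sets must be non-empty: an empty set has no length distribution.
    """
    _check_compatible(mx, my)
    if not mx.words or not my.words:
        raise ValidationError("TVD is undefined for an empty word set")
    p = length_histogram(mx.words)
    q = length_histogram(my.words)
    np_, nq = len(mx.words), len(my.words)
    lengths = set(p) | set(q)
    return 0.5 * sum(abs(p[i] / np_ - q[i] / nq) for i in lengths)


def gc_fraction(words: frozenset[str] | set[str]) -> float:
    """(G+C) characters over all characters, pooled across the set's members.

    Returns 0.0 for an empty set (no characters to count).
    """
    total = sum(len(w) for w in words)
    if total == 0:
        return 0.0
    gc = sum(w.count("G") + w.count("C") for w in words)
    return gc / total


def gcc_symmetric_difference(mx: WordSet, my: WordSet) -> float:
    """GC fraction of the symmetric difference; 0 when the difference is empty."""
    _check_compatible(mx, my)
    _check_dna(mx)
    return gc_fraction(mx.words ^ my.words)


def gcc_intersection(mx: WordSet, my: WordSet) -> float:
    """1 - GC fraction of the intersection; 1 when nothing is shared."""
    _check_compatible(mx, my)
    _check_dna(mx)
    inter = mx.words & my.words
    if not inter:
        return 1.0
    return 1.0 - gc_fraction(inter)


def _check_raw_pair(ri: WordSet, rj: WordSet) -> None:
    if ri.kind != "RAW" or rj.kind != "RAW":
        raise ValidationError("RAW distance requires RAW word sets")
    if len(ri.source_ids) != 2 or ri.source_ids != rj.source_ids[::-1]:
        raise ValidationError(
            f"RAW sets are not the two directions of one pair: "
            f"{ri.source_ids} vs {rj.source_ids}"
        )
    _check_compatible(ri, rj)


def raw_lwi_distance(ri: WordSet, rj: WordSet) -> float:
    """Mean of the length-weighted indices of the two directed RAW sets."""
    _check_raw_pair(ri, rj)
    return 0.5 * (lwi(ri) + lwi(rj))


def raw_gcc_distance(ri: WordSet, rj: WordSet) -> float:
    """Mean of the GC fractions of the two directed RAW sets (empty set -> 0)."""
    _check_raw_pair(ri, rj)
    _check_dna(ri)
    return 0.5 * (gc_fraction(ri.words) + gc_fraction(rj.words))
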