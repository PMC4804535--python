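"""Sequence containers and FASTA input.

Sequences are stored as ordered lists of *segments*: maximal runs of
characters drawn from the alphabet. Segment boundaries are hard breaks —
no factor (substring) ever spans two segments. This is how both of the
following are modelled without polluting the alphabet with sentinels:

* ambiguous bases (``N`` runs) split a record into clean pieces, and
* the reverse-complement (RC) setting appends the reverse complement of
  a sequence as additional segments, so that artificial words straddling
  the junction between the forward strand and its reverse complement are
  never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

__all__ = [
    "Alphabet",
    "DNA",
    "SeqRecord",
    "ValidationError",
    "read_fasta",
    "reverse_complement",
    "make_rc_setting",
]

Setting = Literal["noRC", "RC"]


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""


@dataclass(frozen=True)
class Alphabet:
    """A finite ordered alphabet with an optional complement involution."""

    symbols: tuple[str, ...]
    complement: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError("alphabet must have at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("alphabet symbols must be distinct")
        if any(len(s) != 1 for s in self.symbols):
            raise ValidationError("alphabet symbols must be single characters")
        if self.complement is not None:
            cm = self.complement
            if set(cm) != set(self.symbols) or set(cm.values()) != set(self.symbols):
                raise ValidationError("complement map must be a bijection on the alphabet")
            for a, b in cm.items():
                if cm[b] != a:
                    raise ValidationError(f"complement map is not self-inverse at {a!r}")

    @property
    def is_dna(self) -> bool:
        return set(self.symbols) == {"A", "C", "G", "T"}

    def __contains__(self, ch: str) -> bool:
        return ch in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


#: The standard DNA alphabet with Watson–Crick complementation.
DNA = Alphabet(("A", "C", "G", "T"), {"A": "T", "T": "A", "C": "G", "G": "C"})

#: Two-letter alphabet used by small worked examples; no complement.
AB = Alphabet(("a", "b"))


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence held as sentinel-free segments over an alphabet."""

    id: str
    segments: tuple[str, ...]
    alphabet: Alphabet = DNA
    setting: Setting = "noRC"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.segments or any(not s for s in self.segments):
            raise ValidationError(f"record {self.id!r}: segments must be non-empty strings")
        ok = set(self.alphabet.symbols)
        for seg in self.segments:
            bad = set(seg) - ok
            if bad:
                raise ValidationError(
                    f"record {self.id!r}: characters {sorted(bad)} outside alphabet"
                )

    @property
    def length(self) -> int:
        """Total residue count across segments."""
        return sum(len(s) for s in self.segments)

    def __repr__(self) -> str:  # compact: segments can be long
        return (
            f"SeqRecord(id={self.id!r}, n={self.length}, "
            f"segments={len(self.segments)}, setting={self.setting!r})"
        )


def _split_on_foreign(seq: str, alphabet: Alphabet) -> list[str]:
    """Split *seq* into maximal runs of alphabet characters."""
    ok = set(alphabet.symbols)
    segments: list[str] = []
    current: list[str] = []
    for ch in seq:
        if ch in ok:
            current.append(ch)
        elif current:
            segments.append("".join(current))
            current = []
    if current:
        segments.append("".join(current))
    return segments


def read_fasta(
    path: str | Path,
    alphabet: Alphabet = DNA,
    ambiguity_policy: Literal["split", "reject"] = "split",
) -> list[SeqRecord]:
    """Read a multi-record FASTA file into validated :class:`SeqRecord` objects.

    Input is uppercased (soft-masked FASTA is common). Characters outside
    the alphabet either split the record into segments (``split``, the
    default — suitable for ``N`` runs) or raise (``reject``).
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first.startswith(">"):
            raise ValidationError(f"{path}: line 1: not a FASTA file (missing '>' header)")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        if not raw:
            raise ValidationError(f"{path}: record {rec.id!r} is empty")
        if ambiguity_policy == "reject":
            ok = set(alphabet.symbols)
            for pos, ch in enumerate(raw):
                if ch not in ok:
                    raise ValidationError(
                        f"{path}: record {rec.id!r}: non-alphabet character "
                        f"{ch!r} at position {pos}"
                    )
            segments = [raw]
        else:
            segments = _split_on_foreign(raw, alphabet)
            if not segments:
                raise ValidationError(
                    f"{path}: record {rec.id!r} has no alphabet characters"
                )
        records.append(SeqRecord(rec.id, tuple(segments), alphabet, "noRC"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def reverse_complement(s: str, alphabet: Alphabet = DNA) -> str:
    """Reverse complement of *s*; involutive. Requires a complementable alphabet."""
    if alphabet.complement is None:
        raise ValidationError("alphabet has no complement map; cannot reverse-complement")
    cm = alphabet.complement
    return "".join(cm[ch] for ch in reversed(s))


def make_rc_setting(r: SeqRecord) -> SeqRecord:
    """Return the RC-setting version of a record.

    The reverse complements of the segments are appended, in reverse segment
    order, as *new* segments. Because factors never span segment boundaries,
    no word straddling the forward/reverse-complement junction is counted.
    """
    if r.setting != "noRC":
        raise ValidationError(f"record {r.id!r} is already in the RC setting")
    rc_segments = tuple(reverse_complement(s, r.alphabet) for s in reversed(r.segments))
    return replace(r, segments=r.segments + rc_segments, setting="RC")
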