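"""Pairwise distance matrices, neighbor rankings and relation checks.

`build_distance_matrix` runs the full word-set machinery for a list of
sequences: MAW sets are computed once per record (directed minimal RAW
sets once per ordered pair), the chosen index fills the upper triangle,
and the result is mirrored with a zero diagonal. `ranked_neighbors` sorts
every species' companions by ascending distance, and `evaluate_relations`
scores a matrix of the 11-species β-globin benchmark against six expected
biological relations (see :func:`evaluate_relations`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import indices as ix
from .maw import WordSet, enumerate_maws
from .raw import DEFAULT_K_MAX, minimal_relative_words
from .sequences import SeqRecord, Setting, ValidationError, make_rc_setting

__all__ = [
    "DistanceMatrix",
    "NeighborRanking",
    "RelationReport",
    "BENCHMARK_SPECIES",
    "build_distance_matrix",
    "ranked_neighbors",
    "evaluate_relations",
    "write_matrix",
    "read_matrix_csv",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise index values with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    measure: str = ""
    setting: Setting = "noRC"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("labels must be unique")
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValidationError("matrix entries must be finite")
        if not np.allclose(v, v.T):
            raise ValidationError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def min_offdiagonal(self) -> float:
        mask = ~np.eye(self.n, dtype=bool)
        return float(self.values[mask].min())

    def shifted_nonnegative(self) -> tuple["DistanceMatrix", float]:
        """Subtract the global off-diagonal minimum if negative; diagonal stays 0.

        Returns the (possibly unchanged) matrix and the shift applied.
        Needed before tree building for measures that can go negative
        (the intersection length-weighted index).
        """
        lo = self.min_offdiagonal()
        if lo >= 0:
            return self, 0.0
        shifted = self.values - lo
        np.fill_diagonal(shifted, 0.0)
        return (
            DistanceMatrix(self.labels, shifted, self.measure, self.setting),
            -lo,
        )


@dataclass(frozen=True)
class NeighborRanking:
    """The other species sorted by ascending distance from a focal species."""

    focal: str
    ordered: tuple[str, ...]


@dataclass(frozen=True)
class RelationReport:
    """Outcome of the six expected-relation checks (REL1..REL6)."""

    satisfied: dict[str, bool]
    details: dict[str, str]

    @property
    def n_satisfied(self) -> int:
        return sum(self.satisfied.values())


def _maw_sets(records: list[SeqRecord], max_len: int | None) -> list[WordSet]:
    return [enumerate_maws(r, max_len) for r in records]


def build_distance_matrix(
    records: list[SeqRecord],
    measure: str,
    setting: Setting = "noRC",
    *,
    k_max: int = DEFAULT_K_MAX,
    max_maw_len: int | None = None,
) -> DistanceMatrix:
    """Compute the full pairwise matrix for one index under one strand setting.

    Records must be in the noRC setting; when ``setting="RC"`` each one is
    first extended with its reverse-complement segments. MAW sets are
    computed once per record; RAW measures compute the two directed
    minimal RAW sets per pair (bounded by ``k_max``).
    """
    if measure not in ix.MEASURES:
        raise ValidationError(f"unknown measure {measure!r}; choose from {ix.MEASURES}")
    if len(records) < 2:
        raise ValidationError("need at least 2 records for a distance matrix")
    labels = tuple(r.id for r in records)
    if len(set(labels)) != len(labels):
        raise ValidationError("record ids must be unique")
    if setting == "RC":
        records = [make_rc_setting(r) for r in records]
    n = len(records)
    values = np.zeros((n, n))

    if measure in ix.RAW_MEASURES:
        fn = ix.raw_lwi_distance if measure == "raw_lwi" else ix.raw_gcc_distance
        for i in range(n):
            for j in range(i + 1, n):
                rij = minimal_relative_words(records[i], records[j], k_max)
                rji = minimal_relative_words(records[j], records[i], k_max)
                values[i, j] = values[j, i] = fn(rij, rji)
    else:
        maws = _maw_sets(records, max_maw_len)
        fn = {
            "lwi_sym": ix.lwi_symmetric_difference,
            "lwi_int": ix.lwi_intersection,
            "jaccard": ix.jaccard_distance,
            "tvd": ix.tvd,
            "gcc_sym": ix.gcc_symmetric_difference,
            "gcc_int": ix.gcc_intersection,
        }[measure]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = fn(maws[i], maws[j])
    return DistanceMatrix(labels, values, measure, setting)


def ranked_neighbors(m: DistanceMatrix) -> list[NeighborRanking]:
    """Per-species neighbor lists, ascending distance, lexicographic tie-break."""
    out = []
    for i, focal in enumerate(m.labels):
        others = [lab for lab in m.labels if lab != focal]
        others.sort(key=lambda lab: (m[focal, lab], lab))
        out.append(NeighborRanking(focal, tuple(others)))
    return out


#: Canonical names of the 11 species in the β-globin first-exon benchmark.
BENCHMARK_SPECIES = (
    "Human",
    "Goat",
    "Opossum",
    "Gallus",
    "Lemur",
    "Mouse",
    "Rabbit",
    "Rat",
    "Gorilla",
    "Bovine",
    "Chimp",
)

_ALIASES = {"chimpanzee": "Chimp", "chimp": "Chimp"}


def _canonical(label: str) -> str | None:
    low = label.strip().lower()
    if low in _ALIASES:
        return _ALIASES[low]
    for sp in BENCHMARK_SPECIES:
        if low == sp.lower():
            return sp
    return None


def evaluate_relations(m: DistanceMatrix) -> RelationReport:
    """Check the six expected biological relations on a benchmark matrix.

    The matrix labels must include (case-insensitively; "Chimpanzee" is
    accepted for "Chimp") the 11 benchmark species. The relations, as
    nearest-neighbor criteria:

    * REL1 — Gorilla and Chimp are Human's two nearest neighbors.
    * REL2 — Goat and Bovine are mutual nearest neighbors.
    * REL3 — Mouse is Rat's nearest neighbor.
    * REL4 — Gallus (the only non-mammal) is in no other species' top 3.
    * REL5 — Opossum (the only marsupial) is in no other species' top 3.
    * REL6 — Lemur's mean rank over the other species' lists falls in the
      bottom half (mean position > (n-1)/2).
    """
    mapping: dict[str, str] = {}
    for lab in m.labels:
        canon = _canonical(lab)
        if canon is not None:
            mapping[canon] = lab
    missing = [sp for sp in BENCHMARK_SPECIES if sp not in mapping]
    if missing:
        raise ValidationError(f"matrix lacks benchmark species: {missing}")

    rankings = {r.focal: r.ordered for r in ranked_neighbors(m)}

    def nearest(species: str, k: int = 1) -> tuple[str, ...]:
        return rankings[mapping[species]][:k]

    satisfied: dict[str, bool] = {}
    details: dict[str, str] = {}

    top2 = nearest("Human", 2)
    satisfied["REL1"] = set(top2) == {mapping["Gorilla"], mapping["Chimp"]}
    details["REL1"] = f"Human's two nearest: {top2}"

    goat_nn = nearest("Goat")[0]
    bov_nn = nearest("Bovine")[0]
    satisfied["REL2"] = goat_nn == mapping["Bovine"] and bov_nn == mapping["Goat"]
    details["REL2"] = f"Goat's nearest: {goat_nn}; Bovine's nearest: {bov_nn}"

    rat_nn = nearest("Rat")[0]
    satisfied["REL3"] = rat_nn == mapping["Mouse"]
    details["REL3"] = f"Rat's nearest: {rat_nn}"

    for rel, outlier in (("REL4", "Gallus"), ("REL5", "Opossum")):
        offenders = [
            sp
            for sp in BENCHMARK_SPECIES
            if sp != outlier and mapping[outlier] in nearest(sp, 3)
        ]
        satisfied[rel] = not offenders
        details[rel] = (
            f"{outlier} in top-3 of: {offenders}" if offenders else f"{outlier} in no top-3"
        )

    n = m.n
    lemur = mapping["Lemur"]
    positions = [
        rankings[mapping[sp]].index(lemur) + 1
        for sp in BENCHMARK_SPECIES
        if sp != "Lemur"
    ]
    mean_rank = sum(positions) / len(positions)
    satisfied["REL6"] = mean_rank > (n - 1) / 2
    details["REL6"] = f"Lemur mean rank {mean_rank:.2f} of {n - 1}"

    return RelationReport(satisfied, details)


def write_matrix(
    m: DistanceMatrix, format: Literal["csv", "phylip"], path: str | Path
) -> None:
    """Serialize a matrix: labeled CSV at full precision, or square PHYLIP."""
    path = Path(path)
    if format == "csv":
        m.to_dataframe().to_csv(path, float_format="%.17g")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{m.n}\n")
            for i, lab in enumerate(m.labels):
                row = " ".join(f"{v:.10f}" for v in m.values[i])
                fh.write(f"{lab} {row}\n")
    else:
        raise ValidationError(f"unknown matrix format {format!r}")


def read_matrix_csv(path: str | Path, measure: str = "", setting: Setting = "noRC") -> DistanceMatrix:
    """Read back a matrix written by :func:`write_matrix` in CSV format."""
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float), measure, setting)
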