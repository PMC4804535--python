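"""Published reference matrices for the 11-species β-globin benchmark.

The first exon of the β-globin gene from 11 species (Human, Goat,
Opossum, Gallus, Lemur, Mouse, Rabbit, Rat, Gorilla, Bovine, Chimpanzee)
is a classic test set for alignment-free comparison methods: the expected
biological relations among these species (primates cluster, Goat/Bovine
and Rat/Mouse pair up, Gallus and Opossum are outliers) are well
established, so a distance measure can be judged by whether it recovers
them.

This module ships two published pairwise distance matrices for that
benchmark — the length-weighted index on minimal relative absent word
sets and the Jaccard distance on minimal absent word sets, both under the
reverse-complement setting, printed at 2-decimal precision. They serve as
ground-truth fixtures for the ranking and relation analysis: the
underlying sequences themselves are distributed separately and are not
required to use these matrices.
"""

from __future__ import annotations

import numpy as np

from .matrix import BENCHMARK_SPECIES, DistanceMatrix

__all__ = [
    "BENCHMARK_SPECIES",
    "raw_lwi_rc_reference_matrix",
    "jaccard_rc_reference_matrix",
]

# Upper triangles, row by row, species order as in BENCHMARK_SPECIES:
# Human, Goat, Opossum, Gallus, Lemur, Mouse, Rabbit, Rat, Gorilla, Bovine, Chimp.
_RAW_LWI_RC_UPPER = [
    [23.39, 26.94, 28.34, 27.82, 23.49, 19.31, 27.88, 4.77, 21.60, 7.26],
    [28.71, 24.16, 25.89, 25.52, 24.33, 27.43, 21.77, 8.73, 24.26],
    [29.55, 31.23, 29.21, 26.69, 30.52, 26.90, 28.16, 28.44],
    [28.66, 30.22, 26.27, 30.89, 28.25, 26.21, 30.51],
    [30.21, 27.63, 30.96, 27.77, 25.91, 30.27],
    [24.09, 26.43, 20.98, 23.17, 23.29],
    [29.19, 19.02, 22.28, 21.50],
    [28.37, 27.95, 30.21],
    [19.48, 9.62],
    [21.97],
]

_JACCARD_RC_UPPER = [
    [0.70, 0.82, 0.80, 0.76, 0.70, 0.61, 0.80, 0.15, 0.69, 0.26],
    [0.84, 0.74, 0.74, 0.77, 0.77, 0.79, 0.69, 0.36, 0.71],
    [0.85, 0.87, 0.91, 0.84, 0.90, 0.82, 0.85, 0.82],
    [0.81, 0.82, 0.79, 0.85, 0.80, 0.81, 0.80],
    [0.83, 0.81, 0.81, 0.76, 0.72, 0.77],
    [0.78, 0.78, 0.64, 0.74, 0.68],
    [0.81, 0.63, 0.75, 0.65],
    [0.80, 0.82, 0.82],
    [0.67, 0.15],
    [0.69],
]


def _from_upper(upper: list[list[float]], measure: str) -> DistanceMatrix:
    n = len(BENCHMARK_SPECIES)
    values = np.zeros((n, n))
    for i, row in enumerate(upper):
        for off, v in enumerate(row):
            j = i + 1 + off
            values[i, j] = values[j, i] = v
    return DistanceMatrix(BENCHMARK_SPECIES, values, measure, "RC")


def raw_lwi_rc_reference_matrix() -> DistanceMatrix:
    """Published RAW length-weighted-index matrix (RC setting) for the benchmark."""
    return _from_upper(_RAW_LWI_RC_UPPER, "raw_lwi")


def jaccard_rc_reference_matrix() -> DistanceMatrix:
    """Published Jaccard-distance matrix on MAW sets (RC setting) for the benchmark."""
    return _from_upper(_JACCARD_RC_UPPER, "jaccard")
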