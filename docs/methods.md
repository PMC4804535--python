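# Methods

## Model and assumptions

`mawdist` treats a DNA sequence as a bag of *present factors* and
compares sequences through what is missing rather than what is shared.
The central objects are:

* the **minimal absent word (MAW) set** of a sequence — absent words all
  of whose proper factors are present. Because every absent word
  contains a MAW, the MAW set generates the whole absent-word language;
  it is typically small (linear-size in practice) and is computed
  exactly, with no sampling or heuristics.
* the **minimal relative absent word (RAW) set** of an ordered (target,
  reference) pair — words present in the target, absent from the
  reference, and containing no shorter such minimal word.

Eight indices condense these sets into pairwise dissimilarities (see the
README for formulas). The implicit modelling assumptions are the usual
ones for alignment-free comparison: homology signal survives in
factor-composition statistics, sequences are long enough that their
absent-word sets are informative (for very short sequences most short
words are absent and every index saturates), and evolutionary distance
grows with fingerprint divergence. No substitution model is assumed and
no rate calibration is attempted: the indices are dissimilarities, not
evolutionary time estimates.

## Sequences, segments and the RC setting

A record is an ordered list of *segments*; factors never span segment
boundaries. Two things are encoded this way:

* Ambiguous IUPAC characters (`N` runs) split a record into segments
  (policy `split`, the default) because absent-word logic is undefined
  for degenerate symbols; a `reject` policy is available since datasets
  free of ambiguity may prefer a hard error. Lowercase (soft-masked)
  input is uppercased rather than rejected.
* The **RC setting** appends the reverse-complemented segments (in
  reverse order) as new segments of the same record. Words spanning the
  junction between the forward strand and its reverse complement are
  artefacts of concatenation; the segment representation excludes them
  by construction rather than by post-filtering, which makes the
  exclusion directly testable (the k-mer multiset of an RC record equals
  the forward k-mers plus their reverse complements, exactly).

## MAW enumeration

A word `y` with `|y| ≥ 2` is a MAW iff `y` is absent while `y[:-1]` and
`y[1:]` are both present; single-symbol MAWs are alphabet symbols that
never occur. The enumerator scans present-factor sets length by length
and applies this two-sided test, which is O(n²·|Σ|) overall — ample for
gene-scale inputs, which is the intended regime (whole-genome
engineering, external-memory indexes and compressed suffix structures
are out of scope). Symbols of the declared alphabet that never occur in
the sequence are reported as length-1 MAWs, a strict reading of the
definition; tools that hard-code the observed alphabet may differ on
such degenerate inputs.

The independent oracle `brute_force_maws` walks the word tree and tests,
for every candidate, absence and the presence of *every* proper factor
literally by substring search. Extensions of absent words are not
walked: a superstring of an absent word contains it as a proper factor
and so can never be minimal. This pruning is forced by the definition
and keeps the oracle exact while making length-15 comparisons on DNA
feasible; the oracle is guarded to inputs of at most 2000 residues.

## RAW minimality

The level sets are built iteratively: `M_1 = R_1`, and a word of `R_k`
is minimal iff none of its proper factors lies in any earlier `M_j`.
Checking only the two length-(k−1) factors against `M_{k−1}` is *not*
sufficient: levels can be empty while shorter minimal words still occur
inside longer relative words (target `ACGT` against reference `AAAA`
gives `M_1 = {C,G,T}`, `M_2 = ∅`, yet `ACG ∈ R_3` contains `C`). The
implementation therefore checks all accumulated minimal words, which
guarantees the defining invariant — no reported word contains another —
verified by a property test on random inputs.

`k_max` defaults to 24 (configurable; iteration stops early when the
target has no k-mers left). The length-weighted terms decay as `1/k²`,
so longer words contribute little to RAW-LWI; reproductions of published
RAW-based values are nonetheless mildly sensitive to this cutoff, which
upstream tooling does not document.

## Indices: conventions and edge cases

Degenerate inputs force conventions the definitions leave open; they are
chosen for continuity with the identical-sequence limit on
difference-type measures and maximal dissimilarity on intersection-type
measures:

* `Jaccard(∅, ∅) = 0`; GC of an empty symmetric difference is 0;
  GC-intersection of an empty intersection is 1; an empty RAW set
  contributes GC 0 to the pair average.
* TVD on an empty word set is an **error**, not 0 — no probability
  distribution exists, and surfacing that is safer than a silent value.
* GC counting pools characters across all members of a set (not a
  per-word average), and the RAW-GCC pair value averages the two
  directed sets' fractions rather than pooling their counts.
* TVD histograms live on the union of observed lengths; unobserved
  lengths contribute probability 0.

Matrix diagonals are forced to zero for all measures, including those
without a zero identity (GC-intersection) or with negative range
(LWI-intersection).

## Trees

UPGMA (average linkage, rooted ultrametric output) and neighbor joining
(Saitou–Nei Q-criterion, unrooted output with a trifurcating root) are
implemented in-package so that merge ties break deterministically by the
lexicographically earliest label pair — reruns are bit-identical, and
tied toy matrices have one canonical tree. Consistency is tested rather
than assumed: NJ reproduces random additive matrices and UPGMA random
ultrametric matrices to < 1e-9 path-length error, and both are
cross-checked against scikit-bio's NJ and scipy's average linkage.

Two numerical conventions: matrices with negative entries (possible for
LWI-intersection) are shifted by their global off-diagonal minimum
before tree building, with the shift recorded in the run manifest; and
negative NJ branch-length estimates are clamped to zero with the raw
estimate kept on the node (`preclamp_length`).

## Relation checks

The six expected relations among the 11 β-globin benchmark species are
qualitative folklore; this package operationalizes them as the weakest
nearest-neighbor criteria consistent with published verdicts: REL1 —
{Gorilla, Chimp} are Human's two nearest (either order); REL2 — Goat and
Bovine are mutual nearest neighbors; REL3 — Mouse is Rat's nearest;
REL4/REL5 — Gallus (resp. Opossum) appears in no other species' top
three; REL6 — Lemur's mean position across the other species' rankings
exceeds (n−1)/2. Neighbor rankings break distance ties
lexicographically, so rankings recomputed from matrices printed at
2-decimal precision are compared per tie block.

## Synthetic data

Property tests run on uniform i.i.d. random DNA. Real sequences are not
i.i.d. — codon structure, GC bias and repeats shape which words are
absent — but the algorithms under test are exact combinatorial
procedures whose correctness does not depend on the input distribution,
so uniform strings exercise them fully; what uniform tests do *not*
show is how discriminative the indices are on real data. Tree-builder
tests draw random edge-weighted binary trees (edges uniform on
[0.1, 1]) and random clock-like agglomerations, i.e. exactly additive
and exactly ultrametric matrices, the regimes in which NJ and UPGMA are
provably consistent. Problem sizes — strings up to length ~25, 100
matrices of 4–12 leaves, an 11 × 92 bp pipeline run — keep the whole
suite at desk scale (seconds) while covering every code path.

## Known limitations

* The indices are not metrics in general (TVD and Jaccard are bounded
  semimetrics on the fingerprints; LWI-intersection is not even
  non-negative), and none is calibrated to substitutions per site.
* Very short or low-complexity sequences give saturated, uninformative
  MAW sets.
* The 11-species benchmark *sequences* are not bundled (only the
  published reference matrices are); the external reproduction test
  requires supplying them as `data/beta_globin_exon1.fasta`.
* The CLI is DNA-only; other alphabets (e.g. the two-letter examples)
  are available through the library API, where complement-dependent
  operations raise cleanly.
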