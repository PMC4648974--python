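# Methods

This document records the model implemented by `profsearch`, the default
parameters and where they come from, the synthetic activity-class
generator, and the numerical design decisions.

## 1. Similarity model

Compounds are represented by binary fingerprints (Morgan/circular,
radius 2, 1024 bits by default, via the optional RDKit dependency; any
binary fingerprint table works). Two similarity forms are used:

* **Binary Tanimoto** for fingerprint–fingerprint comparison:
  `Tc(A, B) = c / (a + b − c)` with `a`, `b` the popcounts and `c` the
  intersection popcount.
* **Continuous Tanimoto** for profile–fingerprint comparison:
  `Tc(A, B) = Σ aᵢbᵢ / Σ (aᵢ² + bᵢ² − aᵢbᵢ)`.

On binary inputs the two coincide exactly: the popcount of a 0/1 vector
is its sum of squares and the intersection popcount is the dot product,
so both forms perform the same float division. Two all-zero vectors score
0 by convention.

A **profile** is the element-wise arithmetic mean (AVE) of a set of member
fingerprints. A one-member profile is numerically identical to its
fingerprint — this makes the engine degeneracy chain (section 3) exact.

## 2. Pipeline

For a query `q` with a set of labeled references:

1. **Neighbor list.** Every reference with `Tc(q, ref)` *strictly greater*
   than the neighbor cutoff (default **0.3**) enters the neighbor list,
   split by label. The query itself is always included among the active
   units, so an empty reference set degenerates to conventional search.
2. **Unit construction.**
   * Fingerprint engines (`css`, `iss`, `isc`) use the raw fingerprints
     of query + neighbors as units.
   * `pbss` builds a single profile over query + active neighbors.
   * `pbiss`/`pbisc` cluster the neighbor list (query included) with
     Taylor–Butina at the cluster cutoff (default **0.4**) and replace
     each cluster by per-label profiles: a label-pure cluster becomes one
     profile; a mixed cluster becomes one active and one inactive profile.
   The **compression ratio** is (number of fingerprints entering unit
   construction) / (number of units) and is always ≥ 1.
3. **Scoring.** MAX group fusion: each database compound's score is its
   best similarity over the active units.
4. **Rejection** (`isc`, `pbisc` only). A database compound is kept only
   if its best active-unit similarity strictly exceeds its best
   inactive-unit similarity; ties are rejected. Rejected compounds are
   excluded from the hit list and scored as −∞ in ROC analysis.
5. **Hit list.** The top `floor(0.01 · |db|)` compounds (at least one),
   sorted by descending score with ties broken by ascending compound id.
   The query and all references are excluded from the database before
   ranking.

## 3. Degeneracy chain

These identities hold bit-for-bit and are enforced by the acceptance
tests:

* With an empty reference set, every engine equals `css`.
* When Taylor–Butina produces only singleton clusters, `pbiss` equals
  `iss` and `pbisc` equals `isc` (one-member profiles are fingerprints).
* On binary inputs, continuous Tanimoto equals binary Tanimoto.

## 4. Clustering and diversity

Taylor–Butina sphere exclusion, classic static form: compute all pairwise
similarities; each compound's neighbor count is the number of compounds
with similarity ≥ cutoff (inclusive); repeatedly take the unassigned
compound with the most neighbors (ties: lowest index) as a centroid and
assign it plus its unassigned neighbors to a new cluster. Neighbor counts
are not recomputed after assignments, so "false singletons" (compounds
whose neighbors were all claimed earlier) remain singletons.

The **diversity index** of a clustering is the Shannon entropy (base 2)
of its cluster-size distribution: 0 for one cluster, log₂ k for k
equal-size clusters.

## 5. Activity-class curation and splitting

End points are labeled by measured concentration: **active** strictly
below 10 μM, **inactive** strictly above 30 μM, undetermined in between
(explicit labels pass through). Per class:

* Compounds with conflicting end points are counted; a class with more
  than 5% of its end points in conflict is dropped as noisy, otherwise
  the conflicting compounds are removed.
* A retained class needs more than 70 actives **and** more than 70
  inactives.

Splitting a class: Taylor–Butina cluster the actives at the diversity
cutoff; the cluster centroids become the **query set**; remaining actives
are split roughly in half (seeded shuffle) into reference and test sets;
inactives likewise, except that classes with more than 20,000 inactives
cap the inactive reference set at one quarter of the inactives (the rest
go to the test set). A class whose actives are all centroids cannot be
split (no non-centroid actives to learn from) and raises an error.

## 6. Evaluation

Per query: recall (fraction of test actives in the hit list), precision
(active fraction among *labeled* hits; unknown background compounds are
excluded from both sides), rank-based ROC AUC over the full database
(ties contribute ½; rejected compounds enter at −∞; unknown compounds
excluded), and enrichment factor (hit-list active rate over database
active prevalence). Metrics whose denominator is empty are NaN and are
excluded from class averages, with the count reported. Engine pairs are
compared per class (ΔAUC, Δaverage-recall, Δaverage-precision) with a
two-sided Mann–Whitney U test on per-query recall.

## 7. Synthetic activity-class generator

The generator emulates the *structure* that gives the enhanced engines
their advantage, not chemistry:

* Each class has `n_scaffolds` random prototype fingerprints
  (Bernoulli bits at `bit_density`).
* Each scaffold spawns `n_subfamilies` sub-family prototypes by flipping
  a fraction `sub_flip_rate` of bit positions — multi-modal active series
  whose siblings are reachable from a query only through reference
  neighbors. This is the mechanism MAX fusion exploits.
* Actives are drawn around sub-family prototypes with per-compound flip
  rates `flip_rate · (1 ± flip_spread)`.
* Each scaffold also spawns activity-cliff prototypes at `near_flip_rate`
  from the scaffold prototype; near-inactives are drawn around these, so
  coherent inactive series sit adjacent to the active series. This is the
  mechanism rejection exploits. (Drawing near-inactives by independent
  flips instead would scatter them, and rejection would never fire.)
* Far inactives and the unlabeled background are fully random at
  `bit_density`.

Defaults (4 scaffolds × 36 actives, 1200 near + 600 far inactives,
10,000 background, 1024 bits) put the benchmark in the regime where the
labeled pool exceeds the 1% hit budget while test actives stay below it,
so recall and precision differences between engines are expressible.
What the generator does **not** emulate: real fingerprint bit
correlations, scaffold-size imbalance, assay noise, or any particular
target family. All headline numbers in `results/` come from this
generator and should be read as properties of the implementation, not as
chemical claims.

Per-class seeds are derived with `numpy.random.SeedSequence([seed, i])`
reduced modulo 2³¹.

## 8. Numerical design decisions

* **Exact rational scoring.** Every engine score is a ratio of integers.
  Fingerprint scores divide exact integer popcounts. Profile scores use a
  scaled-integer form: a profile stores its integer member-bit counts
  `s` and member count `n`, and the score against a binary row `b` is
  `n·(s·b) / (Σs² + n²·Σb² − n·(s·b))` — all operands exact integers in
  float64 (bounded by n²·M ≪ 2⁵³), so the single division is correctly
  rounded. The float score therefore depends only on the exact rational
  value: equal rationals give bitwise-equal floats and ranking tie-breaks
  are deterministic. The test suite verifies all six engines against a
  brute-force reimplementation in `fractions.Fraction` arithmetic with
  exact ranked-list equality.
* **AUC** is computed from midranks (`scipy.stats.rankdata`) rather than
  trapezoidal integration, which handles ties and −∞ scores exactly.
* **Determinism.** All randomness flows through seeded
  `numpy.random.Generator` instances; benchmark runs with the same config
  are byte-identical.
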