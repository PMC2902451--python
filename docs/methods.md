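# Methods

## Model

An RNA chain is reduced to the polygonal space curve through its phosphorus
atoms, one per nucleotide, taken in file order within the chain. All shape
information used downstream comes from this curve; bases, sugars, and
base-pairing are deliberately ignored, which is what makes the method
global, alignment-free and fast, and also what it cannot see (two chains
with similar backbones but different base-pairing are similar by
construction).

For two line segments the kernel quantity `w(i, j)` is the average over all
projection directions of the signed crossing indicator of the projected
segments (right-hand-rule sign). It is computed in closed form as the area
of the spherical quadrilateral spanned by the four endpoint directions: with
`r13, r14, r23, r24` the vectors between endpoints of the two segments, the
four unit normals of consecutive cross products give the quadrilateral's
area through the Gram–dot arcsin sum, and the sign is the sign of
`((b1−b0) × (a1−a0)) · r13`. The arcsin sum covers one hemisphere of
directions while opposite directions show the same crossing, so the area is
divided by 2π, not 4π; the tests validate the kernel against a literal
Monte-Carlo projection experiment, which also fixes the overall sign
convention. `|w| ≤ 1`, coplanar and endpoint-sharing pairs give exactly 0.

An order-k Gauss integral is the sum over strictly increasing 2k-tuples of
segment indices of a product of k factors `w(i_a, i_b)` arranged by a chord
pattern (a perfect matching of the 2k ordered positions); any chord may
enter as `|w|`, making that factor achiral. The descriptor enumeration is

* order 1: `(1,2)` plain and absolute — 2 invariants;
* order 2: matchings `(1,2)(3,4)`, `(1,3)(2,4)`, `(1,4)(2,3)`, each with
  all 4 absolute-value combinations — 12;
* order 3: all 15 matchings of six positions, plain — 15;

29 in total, prefixed by the backbone length measure for a 30-component
vector. This is the only decomposition of 29 into whole orders ≤ 3; the
enumeration order (order, matching lexicographically, flag combination) is
frozen under the version tag `order123-lex-1`, which every database header
and report embeds so vectors from different enumerations are never
compared. The length measure defaults to the residue count N (a
unit-unambiguous choice, and the reason the component survives uniform
scaling); arc length in Å is available behind a keyword but off by
default. No length normalization is applied to the invariants; a larger
molecule legitimately has larger integrals, and the Euclidean distance
therefore mixes size and shape exactly as the raw definition prescribes.

## Fast evaluation

Literal enumeration of an order-3 invariant costs O(n⁶). The implementation
instead sums explicitly over the *even-position* indices of the tuple
(e₂, e₄, e₆). Each odd-position index is then confined to an interval
between its explicit neighbours, and because every tuple position belongs
to exactly one chord, the product factorizes per chord: a chord with one
odd endpoint collapses to a 1-D prefix-sum difference of the writhe matrix,
a chord with two odd endpoints to a 2-D prefix-sum rectangle (the two
intervals are disjoint and ordered, so the increasing-tuple constraint is
automatic), and an even–even chord is a plain matrix lookup. The triple
explicit sum gives O(n³) time and O(n²) memory for all 29 invariants
together; empty intervals vanish through the prefix differences, so no
boundary cases are special-cased. Equality with the brute-force enumeration
at relative 1e−9 is an acceptance property of the build (observed agreement
is at machine precision, ~1e−13).

## Numerical choices

* Degeneracy threshold 1e−12, applied scale-relatively: a cross-product
  norm below 1e−12 times the product of its factors' norms (collinear
  endpoints, shared endpoints), or a triple product below 1e−12 times its
  scale (coplanar segments), returns w = 0. Arcsin arguments are clamped to
  [−1, 1].
* Backbone curves reject zero-length segments (consecutive P atoms closer
  than 1e−6 Å) as data errors.
* The writhe matrix is computed vectorized over all non-adjacent segment
  pairs, chunked at 2·10⁶ pairs to bound memory on long chains.
* Survival fractions use strict inequality (fraction of background
  distances strictly greater than D), so a distance above the maximum has
  significance exactly 0 and a zero distance against a positive background
  exactly 1.
* Scan ties at equal distance break lexicographically by entry id;
  thresholds of the ROC utility default to midpoints between consecutive
  sorted unique pair distances (the exact empirical curve), AUC by the
  trapezoid rule.

## Structure input

Selection on PDB files: first model, first chain containing a P atom,
overridable per call. Altlocs other than blank or 'A' are dropped; modified
nucleotides (HETATM with a P atom inside the chain) are part of the
backbone; waters, free phosphate and similar non-backbone residues are
excluded by a small name blacklist. A nucleotide without a P atom is
skipped and its neighbours joined by a straight segment — the Gauss
integrals need one connected curve, and a single bridging segment perturbs
the shape far less than truncating the chain; this gap rule is a design
choice of this package, as is treating chains only individually (each chain
of a multi-chain assembly is a separate curve). Chains with ≤ 7 nucleotides
are rejected: the order-3 integrals superpose six segments, so at least 8
points are required.

## Database and significance

A database maps entry ids to descriptors and stores the distance
distribution over all unordered pairs of distinct entries. The file is a
single JSON document with a header (enumeration version, creation time);
writes are atomic (write-temp-then-rename). The background is the full
sorted sample up to 10⁶ distances; beyond that it degrades to a 10⁴-bin
histogram over [0, D_max], whose survival query counts whole bins above D
(resolution 10⁻⁴ of the range) and whose incremental update clips new
values into the existing bin range. Incremental update adds only new entry
ids and extends the background with the new-versus-all distances, which the
tests verify to be multiset-identical to a full rebuild. Default scan
parameters are cut-off 0.5 and 10 reported hits.

## Synthetic curves and what the tests show

The generator produces planar zigzags (exact null descriptor), right-handed
helices at A-form-like dimensions (radius 9.4 Å, rise 2.81 Å, 11 points per
turn), seeded fixed-step random walks (step 6 Å, a typical P–P spacing),
mirror pairs, and Gaussian-jittered copies (default σ = 0.3 Å, the scale of
coordinate differences between independent determinations of the same
fold). The random walk is not self-avoiding; near-self-intersections are
tolerated by the degeneracy threshold. These fixtures have known topology,
which is what the tests exercise: exactness of the evaluation scheme,
symmetry structure, validity rules, database semantics, cost scaling
(log–log slope of descriptor time over n = 50–400, measured ≈ 2.6–2.8,
bounded in the tests by 3.3), and perfect ROC separation of jittered-helix
versus random-walk clusters with chance-level AUC under label shuffling.
What they do not show: agreement with any particular deposited structure's
published distance values, which depends on matching the exact enumeration
and scaling conventions of other Gauss-integral implementations, and
robustness to real-data pathologies (large disordered gaps, alternate
conformations beyond altloc A, chain breaks spanning many residues) beyond
the bridging rule above. The worked-example test on deposited tRNA and 23S
rRNA chains runs only when local copies of those PDB entries are provided.

## Known limitations

* Descriptor magnitudes grow with chain length (sums over up to C(n−1, 6)
  tuples); distances between chains of very different lengths are dominated
  by size. This matches the raw definition; the optional arc-length measure
  and any rescaling are left to the caller.
* The histogram fallback of the background makes significance approximate
  (bin resolution) and its incremental update approximate at the range
  edges.
* mmCIF input is not supported; convert to PDB first.
* Single chains only; assemblies must be processed per chain.
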