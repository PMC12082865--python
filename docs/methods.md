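# Methods

## The construction

Given DNA sequences S₁,…,Sₙ and an odd k, `kpang` builds the singular
bidirected variation graph that is

- **k-complete** — every pair of equal k-mer occurrences, on either strand,
  is represented by the same oriented vertex path, and
- **k-faithful** — two positions share a vertex only when a chain of shared,
  reflected k-mers forces them together (k-extendability).

These two properties determine the graph uniquely up to isomorphism: it is
the quotient of the generic representation (one vertex per sequence
position, edges between neighbours) by the equivalence closure of the
relation that matches, offset by offset, every pair of equal k-length
windows across both strands.  Orientations follow the strands: two matched
occurrences on the same strand keep equal vertex orientations, opposite
strands flip them.  Because k is odd, no window equals its own reverse
complement, so the orientation of every merge is well defined and the
closure can never demand both signs at once.

The quotient is computed without alignment in four passes:

1. **Concatenation.** The inputs become one text `s` with a `$` separator
   after every sequence (`sequence_io`).  All coordinates are 1-based.
2. **Indexing** (`kmer_index`).  One scan assigns every valid window a
   signed canonical k-mer ID — `K[i] = ±j`, negative when the window is the
   reverse complement of canonical k-mer j; windows that touch a separator,
   a masked character or the text end get 0.  IDs are numbered by first
   occurrence, which makes every downstream artifact deterministic.  The
   inverted index `R[j]` lists the start positions of k-mer j.
3. **Quotient BFS** (`quotient`).  Positions and k-mers form an implicit
   bipartite graph: position p connects to k-mer j with *color* c when p is
   the c-th character of an occurrence of j (forward occurrence starting at
   a: p = a+c−1; reverse occurrence: p = a+k−c).  A BFS that may switch
   colors at positions but must keep the color when passing through a k-mer
   node visits exactly one equivalence class per run; the signed vector
   F[p] records the class (vertex) and orientation of every position.
   Queue growth is bounded by the canonical-member rule: per (k-mer, color)
   pair only the lowest-position member may fan out to the others; any
   other member enqueues just that canonical member.
4. **Graph assembly and compression** (`graph`).  Vertices take the label
   of their +1-oriented occurrences; per-sequence paths and side-to-side
   edges follow directly from F.  Unbranched chains are then contracted:
   a classification pass assigns every vertex its left/right neighbour
   characters (normalized to the vertex's +1 orientation, `$` at sequence
   ends) and marks a side as branching on any disagreement or immediate
   inversion; an edge is contracted only when both endpoints' sides carry a
   single, agreeing, non-`$` context.  Chains that close into boundary-less
   cycles are broken at their lowest-ID vertex (such components cannot
   arise from path-covered inputs, but the walker handles them).  The
   result is the unique maximal contraction; `split_to_singular` inverts it
   up to isomorphism.

Output is GFA 1.0 (S/L/P lines, `0M` overlaps); a step ⟨v,−1⟩ serializes
as `v-`, and a bidirected edge {(v,o),(w,o′)} as `L v o w −o′ 0M`.

### A note on side degrees

It is tempting to expect, by analogy with de Bruijn graphs, that each side
of a vertex in the singular k-complete graph meets at most four neighbours
with pairwise distinct oriented labels.  That holds for neighbours reached
through *directly* shared windows — a (k−1)-overlap plus an equal flanking
character forms an equal k-window and forces the neighbours to merge — but
not across transitive merge chains: two occurrences of one vertex may
extend by equal characters into vertices that share no k-window and hence
stay distinct.  Randomized tests in this package routinely produce such
vertices (and side degrees well above four).  The compression pass
therefore never relies on label uniqueness: it contracts a side only when
that side carries exactly one edge.

## Verification oracles

`metrics.oracle_partition` recomputes the ground truth by brute force:
enumerate all pairs of equal canonical k-mer occurrences, union the k
offset-matched position pairs in an orientation-carrying union-find, and
raise if any class is forced into both orientations (impossible for odd
k).  It is quadratic in per-k-mer occurrence counts and intended for small
inputs (the CLI guards it at 20 kb).  `verify_k_faithful` checks that F
induces exactly the oracle partition with consistent orientations up to a
global per-class flip; `verify_k_complete` checks reflection of every
shared k-mer directly on the graph paths and reports the violating
position pairs.  The two verifiers are independent of the BFS code path:
the flagship test asserts their agreement on hundreds of randomized
collections including inversion- and duplication-bearing ones.

## Graph comparison

An *aligned pair* is two distinct genome positions represented by the same
offset of the same vertex label; μ(G) is the set of all such pairs, each
flagged same- or opposite-strand.  Pair identity deliberately ignores
orientation (the flag records it), so inversion-related pairs are counted;
μ is computed exactly, hence intended for small graphs.  Graph similarity
is the Jaccard index |μ(G₁)∩μ(G₂)| / |μ(G₁)∪μ(G₂)|, defined as 1.0 when
both sets are empty.  Coverage statistics report node/edge counts, total
label length, the maximum node coverage (path steps per node), and the
private fraction — base-weighted by default (label length in coverage-1
nodes over total sequence length), with a node-count-weighted variant.

## Choosing k

`select_k` implements the rare-k-mer rule: pick the smallest odd k whose
fraction of canonical k-mers occurring exactly once reaches a target
(default 0.05).  The fraction is distinct-k-mer-based (unique k-mers / M);
an occurrence-based variant is exposed as an option.  Because the fraction
grows approximately monotonically with k, a coarse grid is evaluated first
and the bracketing interval scanned linearly; if nothing reaches the
target the maximum k is returned with a warning flag.  Too small a k
merges non-homologous sequence (at saturation the graph degenerates toward
one vertex per strand-equivalent base class); too large a k misses real
homology.

## Synthetic collections

`synthetic.generate_collection` emulates a collection of related
haplotypes: an ancestral i.i.d. sequence (`gc_content`, default 0.5) and,
per haplotype, substitutions and short indels per base, then tandem
duplications and segmental inversions drawn as Poisson event counts.
Defaults model closely related bacterial strains: substitution rate 0.01
per base, indel rate 0.001 (lengths 1–3), inversion and duplication rates
0 by default (tests enable them explicitly; inversions 30–100 bp,
duplications 10–50 bp).  Inversions are placed without overlap and applied
last, so their logged coordinates address the final sequence; duplication
coordinates are valid at application time.  Every edit is logged, and the
generator is deterministic given its seed.

What the generator does *not* model: recombination, coalescent structure,
realistic repeat families, sequencing error, or chromosome-scale lengths.
Passing tests therefore demonstrate correctness of the construction on
collections with substitution/indel/inversion/duplication structure at
desk scale, not performance or topology claims on real assemblies.

## Numerical and design choices

- **Canonical k-mer** = lexicographic minimum of window and reverse
  complement; k must be odd (rejected otherwise).
- **Ambiguity characters** (`N`, IUPAC codes): policy `mask` keeps them in
  the text, excludes every window containing one from the index (each
  masked base becomes a singleton vertex whose label passes through
  verbatim); `strict` rejects the input.
- **Determinism**: seed scan in ascending position order, first seed of a
  class oriented +1, IDs by first occurrence — identical input bytes and k
  give byte-identical GFA.  Any other traversal yields an isomorphic
  graph.
- **Compressed label orientation**: a chain is read with its lowest-ID
  endpoint oriented +1; any consistent choice is isomorphic.
- **Isomorphism in tests** is equality of canonically relabeled graphs
  (first-occurrence order along name-sorted paths, each vertex flipped so
  its first occurrence is +1) — sound for path-covered graphs with shared
  path names.
- **Orientation conflicts** in the BFS raise immediately; for odd k on
  valid input they cannot occur, so any occurrence signals a bug rather
  than something to resolve silently.
- **Problem sizes**: randomized correctness tests use n ≤ 8 haplotypes of
  ≤ 200 bp with k ∈ {3,5,7,9} (the closure oracle is quadratic); the
  scaling check runs the pipeline at 10⁴ and 10⁶ bases with k = 7 and
  asserts the runtime ratio stays ≲ 150×, consistent with O(kN) growth.
  Constant-factor engineering for large inputs: a byte table flags
  positions covered by any repeated k-mer so the BFS crosses unique
  regions at byte-lookup cost; occurrence lists carry strand-signed
  starts; canonical members are cached only for occurrence lists longer
  than 8 (shorter lists are cheaper to rescan); graph assembly and the
  compression classification pass are vectorized over F.

## Known limitations

- The closure oracle and μ(G) are exact but quadratic; both are for
  verification at small scale, not production comparison of full-genome
  graphs.
- GFA input must be blunt (`0M` overlaps); overlapping-segment graphs are
  out of scope.
- The 20 kb verification guard and the CLI defaults suit desk-scale use;
  the library itself handles megabase inputs in seconds to tens of
  seconds, but remains a single-threaded reference implementation in
  Python, not a competitor to optimized native builders.
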