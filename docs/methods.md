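# Methods

## Model and procedure

`offscan` treats guide specificity screening as bounded approximate string
matching over the candidate set rather than over the genome.

1. **Candidate scan.** Both strands of every input sequence are scanned for
   an IUPAC PAM; each match with a full-length, N-free spacer adjacent on
   the configured side yields one candidate site. This is a plain linear
   scan (no index): the genome is traversed exactly once. Minus-strand
   sites are stored guide-oriented (reverse complemented), so spacers are
   directly comparable across strands; coordinates are 0-based, half-open,
   on the forward reference (BED-compatible).
2. **Candidate index.** All spacers (length *k*) are concatenated, each
   followed by the sentinel `$`, and one FM-index is built over the
   resulting string of length N·(k+1). `$` sorts before every base. Because
   queries are sentinel-free and all segments have equal length, an
   alignment of length *k* can never span a sentinel; any hit must start at
   offset ≡ 0 (mod k+1). This is asserted as a hard integrity check, never
   silently filtered.
3. **Bounded search.** For a guide *Q* the backward-search tree is
   traversed level-synchronously from the 3′ end of the spacer: at each
   position all four bases are tried (mismatches counted), and a state is
   discarded when `mismatches + LB > m`, where LB lower-bounds the
   mismatches any alignment must still spend on the unconsumed prefix.
   With `use_lower_bounds=False` only the LB pruning is disabled — the
   budget itself always applies — which the tests use to show pruning
   changes node counts but never hit sets.

### Lower bound

`LB` is a greedy partition bound computed once per query in the direction
opposite to the search: walk the query left to right, extending a maximal
segment that occurs exactly (sentinel-free) in the indexed text; every
forced break implies ≥ 1 mismatch against *any* equal-length substring.
`lb[i]` records the breaks accumulated in `Q[0..i]`. The bound is valid
(never exceeds the true minimum Hamming distance of the prefix to any
substring of the text — property-tested against brute force) and monotone.
Occurrence tests use the same index (O(k) per test, O(k²) per query, k≈20).

### Distance model

Hamming distance only: substitutions, no bulges/indels, uniform budget
across the spacer (no seed/non-seed split). Off-target *scoring* (CFD/MIT)
is out of scope; the output is the exact mismatch count and positions.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pam` | `NGG`, 3′ side | SpCas9 motif; any IUPAC string, alternatives may be listed (`NAG`…), 5′ side for Cpf1-class |
| `spacer_len` (k) | 20 nt | guide-matching length; ≤ 63 in the bounded search (positions are bit-packed) |
| `max_mismatches` (m) | 3 | Hamming budget; any 0 ≤ m ≤ k is supported |
| `exclude_self` | true | drop a K-member query's own 0-mismatch hit (an exact duplicate at another locus is kept) |
| `occ_block` | 128 | Occ checkpoint spacing for large texts |
| `dense_occ_threshold` | 4·10⁶ | below this text length a dense cumulative rank matrix gives O(1) Occ and vectorized batch extension |

## Synthetic benchmark generator

`SimulationSpec` defaults: 50 kb single chromosome, GC 0.41
(vertebrate-like), 5 planted pairs at Hamming distance 2, spacer 20, PAM
NGG. Each pair is a random spacer plus a copy mutated at exactly
`planted_distance` positions, both written with a concrete PAM into
non-overlapping grid slots on the plus strand; a TSV truth table records
both members.

**Clean-background guarantee.** A 50 kb random genome carries ~4–6 k NGG
candidates, and the expected number of *accidental* spacer pairs within 3
mismatches is ≈ 0.5 — enough to confound a planted-pair benchmark on a
large fraction of seeds. The generator therefore verifies, by exhaustive
pairwise Hamming comparison of all scanned candidates, that no non-planted
pair lies within `background_min_distance − 1` (default 3) mismatches;
offending draws are rejected and redrawn from the same RNG stream. The
truth table is thus the *complete* truth for any budget below
`background_min_distance`, and a fixed seed still yields byte-identical
output.

What the generator does **not** emulate: repeats and segmental
duplications, N-gaps, chromatin context, real base composition structure.
Passing the planted-pair benchmark shows the search is complete and the
pipeline plumbing is correct; it says nothing about off-target *activity*
in real genomes, where near-duplicate density is far higher.

## Numerical and design choices

- **Suffix array construction** (method not dictated by the data
  structure): numpy prefix doubling, O(n log² n); correctness-first and
  adequate at desk scale. The naive full-suffix sort exists only as a test
  oracle. The full SA is stored for locating (no sampling).
- **Alphabet order** fixed `$ < A < C < G < T`; input uppercased before
  indexing. `Occ[a, −1] = 0` so the interval recurrences need no special
  case at `sp = 0`.
- **Internal sentinels**: the concatenation uses the single symbol `$`;
  suffix comparison runs past internal sentinels (total order is
  well-defined since all suffixes differ in length). Correct because
  queries are sentinel-free.
- **Determinism**: hits are sorted (mismatches, site_id); candidate sites
  by (chrom, start, strand) with consecutive ids; a fixed seed reproduces
  every output byte-for-byte.
- **Degenerate inputs**: empty genome → empty candidate list; `m = 0`
  degenerates to exact search (tested identical); single-sentinel text
  `"$"` is a valid index.
- **N handling**: candidates whose spacer window overlaps an N are dropped;
  an N base never satisfies a PAM position (even code `N`, which expands to
  A/C/G/T only).
- **Problem sizes in tests**: randomized oracle-equivalence runs 500
  instances at n_sites ≤ 500, k ∈ {8, 20}, m ≤ 4; the pipeline benchmark
  uses the 50 kb default. These sizes keep the full suite under ~20 s while
  the chromosome-scale path is the same vectorized code.

## Known limitations

- Candidate sets of hundreds of millions of sites (mammalian genome scale)
  exceed the dense-Occ threshold; the checkpointed Occ path is exact but
  unvectorized there, and indexing at that scale is untested on this
  hardware class.
- No indel (DNA/RNA bulge) support; no activity scoring; no paired-guide
  mode.
- The spacer-length cap of 63 nt comes from bit-packing mismatch positions.
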