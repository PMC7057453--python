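# offscan

CRISPR sgRNA candidate scanning and FM-index-based off-target detection.

## The problem

CRISPR/Cas9 cleaves wherever its guide RNA's ~20-nt spacer base-pairs next
to a protospacer-adjacent motif (PAM, 5′-NGG-3′ for SpCas9) — *including*
genomic sites that differ from the intended target by a few mismatches.
Designing a specific guide therefore means (1) enumerating every
PAM-adjacent candidate site *K* in a genome and (2) finding, for each
guide, all candidates within a mismatch budget *m*.

Running an aligner per guide rescans the whole genome each time and returns
hits that are not PAM-adjacent. `offscan` instead searches **within the
candidate set itself**: every PAM-adjacent site is already in *K*, so the
candidate spacers are joined with sentinels into a single string

    spacer_0 $ spacer_1 $ … spacer_{N−1} $

and one FM-index (suffix array *SA*, Burrows–Wheeler transform *B*, *C*
array and *Occ* ranks) is built over the concatenation. The suffix-array
interval [*sp*, *ep*] of a pattern *Q* shrinks by one backward-extension per
character:

    sp(aQ) = C[a] + Occ[a, sp(Q) − 1]
    ep(aQ) = C[a] + Occ[a, ep(Q)] − 1

so exact search costs O(|Q|). Mismatched search is a bounded traversal of
the backward-search tree: all four bases are tried at every position, and a
branch is pruned as soon as its accumulated mismatches plus a greedy
lower-bound *LB* on the still-unconsumed query prefix exceed *m*. Because
queries never contain the sentinel and all k-mers have equal length, every
hit necessarily aligns to a spacer boundary — PAM adjacency is guaranteed
by construction, with no post-filtering. The search is complete (no hit
within *m* is missed) and is verified against brute-force Hamming
enumeration in the test suite.

## Worked example

```sh
$ python examples/01_fm_index_basics.py
text          : banana$
suffix array  : [6, 5, 3, 1, 0, 4, 2]
BWT           : annb$aa
C array       : {'$': 0, 'a': 1, 'b': 4, 'n': 5}
interval of 'ana' : [2, 3]  (2 occurrences)
text positions    : [1, 3]
```

The suffix array rows 2–3 are exactly the suffixes starting with `ana`;
locating them gives text offsets 1 and 3, the two occurrences in `banana`.

The full pipeline on a simulated benchmark genome:

```sh
$ python examples/04_simulated_pipeline.py
candidate sites found: 4187
specific guides:      4177
non-specific guides:  10  (expected: 10 planted)
```

A 50 kb genome with 5 planted spacer pairs at Hamming distance 2 yields
4187 NGG candidates; at a 3-mismatch budget exactly the 10 planted sites
are flagged non-specific, each with one off-target at 2 mismatches — its
planted twin.

## Command line

```sh
offscan simulate  --length 50000 --pairs 5 --distance 2 --seed 7 \
                  --out-fasta g.fa --out-truth truth.tsv
offscan pamscan   --fasta g.fa --pam NGG --spacer-len 20 --out sites.tsv
offscan index     --sites sites.tsv --out K.idx
offscan offtarget --index K.idx --sites sites.tsv --max-mismatches 3 \
                  --out hits.tsv --report specificity.tsv
```

`hits.tsv` lists every within-K hit with mismatch count and 0-based
mismatch positions (position 0 = PAM-distal end); `specificity.tsv` has
per-site off-target counts by mismatch level and a `specific` flag.
Alternative PAMs (`--pam NGG --pam NAG`) and 5′-PAM nucleases
(`--pam-side 5prime`) are supported.

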