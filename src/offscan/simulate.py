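"""Synthetic genomes with planted near-duplicate PAM-adjacent sites.

Generates a random A/C/G/T genome at a configurable GC content and plants
pairs of PAM-adjacent spacers at a known Hamming distance: each pair is one
"guide target" plus one deliberate near-copy, so a complete off-target
search must flag both members as non-specific.  The truth table written
alongside the FASTA is the oracle for end-to-end recovery tests.

The generator emulates only base composition; it has no repeats, gene
structure or N-gaps unless planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pam_scan import GenomeSequence, PamPattern, parse_pam, scan_candidates

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_ATTEMPTS = 64


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic genome.

    Defaults give a 50 kb chromosome at vertebrate-like 41% GC with five
    planted pairs two substitutions apart — small enough to scan in well
    under a second yet large enough that background near-duplicates among
    20-mers are vanishingly unlikely.
    """

    genome_length: int = 50_000
    gc_content: float = 0.41
    n_planted_pairs: int = 5
    planted_distance: int = 2
    pam: PamPattern = field(default_factory=lambda: parse_pam("NGG"))
    spacer_len: int = 20
    seed: int = 0
    background_min_distance: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.planted_distance > self.spacer_len:
            raise ValueError("planted_distance exceeds spacer_len")
        cassette = self.spacer_len + len(self.pam)
        if self.genome_length < self.n_planted_pairs * 2 * cassette:
            raise ValueError("genome too short for the requested planted pairs")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _concrete_pam(rng: np.random.Generator, pam: PamPattern) -> str:
    """Sample one concrete base string matching the IUPAC pattern."""
    return "".join(sorted(allow)[rng.integers(len(allow))] for allow in pam.allowed)


def _mutate(rng: np.random.Generator, spacer: str, d: int) -> str:
    """Exactly ``d`` substitutions at distinct random positions."""
    out = list(spacer)
    for pos in rng.choice(len(spacer), size=d, replace=False):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


def generate(spec: SimulationSpec) -> tuple[str, pd.DataFrame]:
    """Build the genome string and the planted-pair truth table.

    Planted cassettes (spacer + concrete PAM, plus-strand, 3'-PAM geometry)
    are written into non-overlapping slots chosen on a regular grid, so two
    cassettes can never merge.  The background is guaranteed clean: apart
    from the planted pairs, no two candidate spacers in the genome lie
    within ``background_min_distance - 1`` substitutions of each other, so
    the truth table is the *complete* truth for any mismatch budget below
    ``background_min_distance``.  Draws violating this (a random genome of
    this size produces an accidental near-pair with appreciable
    probability) are rejected and redrawn from the same stream, so the same
    seed always yields the same bytes.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(_MAX_ATTEMPTS):
        seq, truth = _generate_once(rng, spec)
        if _background_is_clean(seq, truth, spec):
            return seq, truth
    raise RuntimeError(
        "could not draw a genome with a clean background; "
        "lower background_min_distance or genome_length"
    )


def _generate_once(
    rng: np.random.Generator, spec: SimulationSpec
) -> tuple[str, pd.DataFrame]:
    genome = _random_bases(rng, spec.genome_length, spec.gc_content)
    if spec.pam.side != "three_prime":
        raise NotImplementedError("planting currently assumes a 3' PAM")
    cassette_len = spec.spacer_len + len(spec.pam)
    n_members = spec.n_planted_pairs * 2
    n_slots = spec.genome_length // cassette_len
    slot_ids = rng.choice(n_slots, size=n_members, replace=False)
    rows = []
    for pair in range(spec.n_planted_pairs):
        spacer = "".join(map(chr, _random_bases(rng, spec.spacer_len, spec.gc_content)))
        mutant = _mutate(rng, spacer, spec.planted_distance)
        for member, seq in enumerate((spacer, mutant)):
            start = int(slot_ids[pair * 2 + member]) * cassette_len
            pam_seq = _concrete_pam(rng, spec.pam)
            cassette = np.frombuffer((seq + pam_seq).encode("ascii"), dtype=np.uint8)
            genome[start : start + cassette_len] = cassette
            rows.append(
                {
                    "pair_id": pair,
                    "member": member,
                    "chrom": "sim1",
                    "start": start,
                    "strand": "+",
                    "spacer": seq,
                    "pam": pam_seq,
                    "distance": spec.planted_distance,
                }
            )
    truth = pd.DataFrame(rows).sort_values(["pair_id", "member"]).reset_index(drop=True)
    return genome.tobytes().decode("ascii"), truth


def _background_is_clean(seq: str, truth: pd.DataFrame, spec: SimulationSpec) -> bool:
    """True iff the only near-pairs among all candidate spacers are planted.

    Checks every pair of candidate sites (both strands) for Hamming distance
    below ``background_min_distance``; a close pair is acceptable only when
    both members are plus-strand planted cassettes of the same pair.
    """
    sites = scan_candidates(
        [GenomeSequence("sim1", seq)], spec.pam, spec.spacer_len
    )
    n = len(sites)
    if n < 2:
        return True
    k = spec.spacer_len
    mat = np.frombuffer(
        "".join(s.spacer for s in sites).encode("ascii"), dtype=np.uint8
    ).reshape(n, k)
    planted_pair_of = {
        int(r.start): int(r.pair_id) for r in truth.itertuples(index=False)
    }
    thr = spec.background_min_distance
    block = 256
    for i0 in range(0, n, block):
        dists = (mat[i0 : i0 + block, None, :] != mat[None, :, :]).sum(axis=2)
        for bi, j in np.argwhere(dists < thr):
            i = i0 + int(bi)
            j = int(j)
            if i == j:
                continue
            si, sj = sites[i], sites[j]
            pi = planted_pair_of.get(si.start) if si.strand == "+" else None
            pj = planted_pair_of.get(sj.start) if sj.strand == "+" else None
            if pi is not None and pj is not None and pi == pj:
                continue
            return False
    return True


def simulate_genome(spec: SimulationSpec, fasta_path, truth_path) -> None:
    """Write the FASTA (single record ``sim1``) and the truth TSV."""
    seq, truth = generate(spec)
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">sim1 seed={spec.seed} length={spec.genome_length}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    truth.to_csv(truth_path, sep="\t", index=False)
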