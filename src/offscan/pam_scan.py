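"""Genome scan for PAM-adjacent candidate sgRNA sites.

Both strands of every input sequence are scanned for a user-defined IUPAC
PAM (default ``NGG``, the SpCas9 motif); each match with a full-length,
N-free spacer adjacent on the configured side yields one candidate site.
This step is a plain linear scan — the FM-index only enters downstream when
off-targets are searched within the candidate set.

Minus-strand sites are stored guide-oriented (spacer and PAM reverse
complemented) so that spacer sequences are directly comparable across
strands; coordinates always refer to the forward reference.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PamSide = Literal["three_prime", "five_prime"]


@dataclass(frozen=True)
class PamPattern:
    """A validated IUPAC PAM with its position relative to the spacer."""

    pattern: str
    side: PamSide = "three_prime"
    allowed: tuple[frozenset[str], ...] = ()

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, seq: str) -> bool:
        """Positionwise IUPAC match; an ``N`` base in the genome never matches."""
        if len(seq) != len(self.pattern):
            return False
        return all(b in allow for b, allow in zip(seq, self.allowed))


def parse_pam(pattern: str, side: PamSide = "three_prime") -> PamPattern:
    """Validate an IUPAC PAM string and expand each code to its base set."""
    if not pattern:
        raise ValueError("PAM pattern must be non-empty")
    pattern = pattern.upper()
    try:
        allowed = tuple(IUPAC_CODES[c] for c in pattern)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol in PAM: {exc.args[0]!r}") from None
    if side not in ("three_prime", "five_prime"):
        raise ValueError(f"invalid PAM side: {side!r}")
    return PamPattern(pattern=pattern, side=side, allowed=allowed)


@dataclass(frozen=True)
class GenomeSequence:
    """One FASTA record, uppercased, over ``A,C,G,T,N``."""

    name: str
    seq: str


@dataclass(frozen=True)
class CandidateSite:
    """A PAM-adjacent spacer: one member of the candidate set K.

    ``start`` is the 0-based forward-reference start of the spacer; on the
    minus strand, ``spacer`` and ``pam_seq`` are guide-oriented (reverse
    complemented).
    """

    site_id: int
    chrom: str
    start: int
    strand: str
    spacer: str
    pam_seq: str

    @property
    def end(self) -> int:
        """0-based half-open end of the spacer interval."""
        return self.start + len(self.spacer)


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``A,C,G,T,N`` (N maps to N)."""
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide symbols: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file (plain or gzipped) into uppercased records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"{path}: sequence data before any FASTA header")
        fh.seek(0)
        records = [
            GenomeSequence(name=rec.id, seq=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def _pam_match_positions(codes: np.ndarray, pam: PamPattern) -> np.ndarray:
    """Start positions where the PAM matches (vectorized per PAM column)."""
    L = len(codes)
    p = len(pam)
    if L < p:
        return np.zeros(0, dtype=np.int64)
    ok = np.ones(L - p + 1, dtype=bool)
    for j, allow in enumerate(pam.allowed):
        lut = np.zeros(256, dtype=bool)
        for b in allow:
            lut[ord(b)] = True
        ok &= lut[codes[j : L - p + 1 + j]]
    return np.nonzero(ok)[0].astype(np.int64)


def _scan_one_strand(
    seq: str, pam: PamPattern, spacer_len: int
) -> list[tuple[int, str, str]]:
    """Scan a single oriented sequence; returns (spacer_start, spacer, pam_seq).

    Coordinates are within the oriented sequence; the caller maps minus-strand
    hits back to forward coordinates.
    """
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    L = len(codes)
    k = spacer_len
    p = len(pam)
    pam_starts = _pam_match_positions(codes, pam)
    # spacer must be N-free: prefix sums of ACGT flags give window checks
    lut_acgt = np.zeros(256, dtype=np.int64)
    for b in "ACGT":
        lut_acgt[ord(b)] = 1
    cs = np.concatenate(([0], np.cumsum(lut_acgt[codes])))
    out: list[tuple[int, str, str]] = []
    if pam.side == "three_prime":
        spacer_starts = pam_starts - k
        valid = spacer_starts >= 0
    else:
        spacer_starts = pam_starts + p
        valid = spacer_starts + k <= L
    pam_starts = pam_starts[valid]
    spacer_starts = spacer_starts[valid]
    nfree = cs[spacer_starts + k] - cs[spacer_starts] == k
    for s, t in zip(spacer_starts[nfree], pam_starts[nfree]):
        out.append((int(s), seq[s : s + k], seq[t : t + p]))
    return out


def scan_candidates(
    genome: Sequence[GenomeSequence],
    pam: PamPattern | Sequence[PamPattern],
    spacer_len: int = 20,
) -> list[CandidateSite]:
    """Find every PAM-adjacent spacer on both strands of every sequence.

    Multiple alternative PAMs (e.g. NGG plus NAG) may be given; a position
    matching several patterns is emitted once, deduplicated by
    ``(chrom, start, strand)``.  Sites are sorted by ``(chrom, start,
    strand)`` and numbered consecutively from 0.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    pams = [pam] if isinstance(pam, PamPattern) else list(pam)
    sides = {p.side for p in pams}
    if len(sides) > 1:
        raise ValueError("all PAM patterns must share the same side")
    seen: dict[tuple[str, int, str], tuple[str, str]] = {}
    for record in genome:
        L = len(record.seq)
        rc = reverse_complement(record.seq)
        for p in pams:
            for s, spacer, pam_seq in _scan_one_strand(record.seq, p, spacer_len):
                seen.setdefault((record.name, s, "+"), (spacer, pam_seq))
            for s, spacer, pam_seq in _scan_one_strand(rc, p, spacer_len):
                fwd_start = L - (s + spacer_len)
                seen.setdefault((record.name, fwd_start, "-"), (spacer, pam_seq))
    ordered = sorted(seen.items(), key=lambda kv: kv[0])
    return [
        CandidateSite(
            site_id=i, chrom=chrom, start=start, strand=strand,
            spacer=spacer, pam_seq=pam_seq,
        )
        for i, ((chrom, start, strand), (spacer, pam_seq)) in enumerate(ordered)
    ]


_TSV_COLUMNS = ["site_id", "chrom", "start", "end", "strand", "spacer", "pam"]


def write_candidates(sites: Iterable[CandidateSite], path) -> None:
    """Write sites as TSV (0-based half-open spacer coordinates)."""
    rows = [
        (s.site_id, s.chrom, s.start, s.end, s.strand, s.spacer, s.pam_seq)
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[CandidateSite]:
    """Read back a TSV written by :func:`write_candidates`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "spacer": str, "pam": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CandidateSite(
            site_id=int(r.site_id), chrom=str(r.chrom), start=int(r.start),
            strand=str(r.strand), spacer=str(r.spacer), pam_seq=str(r.pam),
        )
        for r in df.itertuples(index=False)
    ]


def write_bed(sites: Iterable[CandidateSite], path) -> None:
    """BED6 export of the spacer intervals (name = site_id, score = 0)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t0\t{s.strand}\n")
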