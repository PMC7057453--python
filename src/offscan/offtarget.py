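"""Bounded off-target search within the candidate set K.

Instead of rescanning the genome for every guide, all candidate spacers are
joined into one sentinel-separated string (``spacer_0 $ spacer_1 $ ...``) and
a single FM-index is built over it.  A guide's off-targets are then found by
a depth-first bounded backward search over that index: at each query position
all four bases are tried, mismatches are accumulated, and branches whose
accumulated mismatches plus a precomputed lower bound on the remaining
(not-yet-consumed) query prefix exceed the budget are pruned.

Because queries are sentinel-free and every k-mer between sentinels has the
same length, any full-length match necessarily starts at a spacer boundary —
enforced here as a hard integrity assertion, not a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fm_index import (
    SENTINEL,
    AlphabetError,
    FmIndex,
    SaInterval,
    Text,
    build_fm_index,
)
from .pam_scan import CandidateSite


class IntegrityError(RuntimeError):
    """A structural guarantee of the sentinel-concatenation was violated."""


@dataclass(frozen=True)
class Query:
    """A guide sequence to search against the candidate index."""

    query_id: str
    seq: str
    source: Literal["from_K", "user_supplied"] = "user_supplied"
    site_id: int | None = None  # populated when source == "from_K"

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise AlphabetError(f"query contains invalid symbols: {sorted(bad)}")


@dataclass(frozen=True)
class SearchParams:
    """Mismatch budget and self-hit handling for an off-target run."""

    max_mismatches: int = 3
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate within the mismatch budget of a query guide."""

    query_id: str
    site_id: int
    chrom: str
    start: int
    end: int
    strand: str
    spacer: str
    mismatches: int
    mismatch_positions: tuple[int, ...]


def concat_candidates(
    sites: Sequence[CandidateSite],
) -> tuple[Text, "OffsetMap"]:
    """Join all spacers as ``spacer_0 $ spacer_1 $ ... $`` with an offset map."""
    if not sites:
        raise ValueError("candidate set is empty")
    k = len(sites[0].spacer)
    if any(len(s.spacer) != k for s in sites):
        raise ValueError("heterogeneous spacer lengths in candidate set")
    symbols = SENTINEL.join(s.spacer for s in sites) + SENTINEL
    text = Text(symbols, allow_internal_sentinels=True)
    return text, OffsetMap(spacer_len=k, n_sites=len(sites))


@dataclass(frozen=True)
class OffsetMap:
    """Inverts the concatenation layout: offset -> (site index, within-spacer)."""

    spacer_len: int
    n_sites: int

    def __call__(self, offset: int) -> tuple[int, int]:
        site, within = divmod(offset, self.spacer_len + 1)
        if site >= self.n_sites:
            raise IndexError(f"offset {offset} beyond concatenation")
        return site, within


@dataclass
class CandidateIndex:
    """FM-index over the sentinel-joined candidate spacers."""

    fm: FmIndex
    spacer_len: int
    n_sites: int
    offset_map: OffsetMap = field(init=False)

    def __post_init__(self) -> None:
        expected = self.n_sites * (self.spacer_len + 1)
        if self.fm.n != expected:
            raise ValueError(
                f"index text length {self.fm.n} != n_sites*(k+1) = {expected}"
            )
        self.offset_map = OffsetMap(self.spacer_len, self.n_sites)

    def save(self, path) -> None:
        self.fm.save(path)

    @classmethod
    def load(cls, path) -> "CandidateIndex":
        fm = FmIndex.load(path)
        # layout: n = n_sites * (k+1); k recovered from the first sentinel
        k = fm.text.symbols.index(SENTINEL)
        return cls(fm=fm, spacer_len=k, n_sites=fm.n // (k + 1))


def build_candidate_index(sites: Sequence[CandidateSite]) -> CandidateIndex:
    """Build the one shared FM-index over the whole candidate set."""
    text, omap = concat_candidates(sites)
    fm = build_fm_index(text)
    return CandidateIndex(fm=fm, spacer_len=omap.spacer_len, n_sites=omap.n_sites)


@dataclass(frozen=True)
class LowerBoundArray:
    """Per-position lower bounds used to prune the bounded backward search.

    ``lb[i]`` bounds from below the mismatches any alignment must spend on
    the query prefix ``Q[0..i]`` — the portion the backward search has not
    yet consumed when it is about to process position ``i``.
    """

    lb: np.ndarray

    def bound_before(self, i: int) -> int:
        """Bound on the portion strictly left of position ``i``."""
        return int(self.lb[i - 1]) if i > 0 else 0


def compute_lower_bounds(q: Query | str, idx: CandidateIndex) -> LowerBoundArray:
    """Greedy-partition mismatch lower bounds for each query prefix.

    Walking the query left to right (opposite to the backward search), a
    maximal segment that occurs exactly in the indexed text is extended;
    every forced break costs at least one mismatch against any equal-length
    substring, so the running break count is a valid lower bound.
    """
    seq = q.seq if isinstance(q, Query) else q
    k = idx.spacer_len
    if len(seq) != k:
        raise ValueError(f"query length {len(seq)} != index spacer length {k}")
    lb = np.zeros(k, dtype=np.int64)
    z = 0
    j = 0
    for i in range(k):
        if idx.fm.exact_search(seq[j : i + 1]).is_empty:
            z += 1
            j = i + 1
        lb[i] = z
    return LowerBoundArray(lb=lb)


def bounded_search(
    idx: CandidateIndex,
    q: Query | str,
    params: SearchParams,
    use_lower_bounds: bool = True,
    stats: dict | None = None,
) -> list[tuple[int, tuple[int, ...]]]:
    """All concatenation offsets within ``max_mismatches`` of the query.

    Traverses the backward-search tree level by level: positions are
    consumed from the spacer's 3' end to its 5' end, trying all four bases
    at every position (never the sentinel).  A branch is abandoned as soon
    as its accumulated mismatches plus the lower bound for the unconsumed
    prefix exceed the budget.  Complete (no hit missed) and sound (no hit
    beyond the budget) by construction; ``use_lower_bounds=False`` disables
    only the lower-bound pruning, never the budget itself.

    Returns ``(offset, mismatch_positions)`` pairs; ``stats``, if given, is
    filled with the number of visited search-tree nodes (root plus every
    surviving extension).
    """
    query = q if isinstance(q, Query) else Query(query_id="q", seq=q)
    k = idx.spacer_len
    m = params.max_mismatches
    if m > k:
        raise ValueError(f"max_mismatches {m} exceeds spacer length {k}")
    if len(query.seq) != k:
        raise ValueError(f"query length {len(query.seq)} != spacer length {k}")
    if k > 63:
        raise ValueError("spacer length beyond 63 not supported")
    fm = idx.fm
    alpha = fm.alphabet  # ($, A, C, G, T)
    qcodes = [alpha.index(c) for c in query.seq]
    lb = compute_lower_bounds(query, idx) if use_lower_bounds else None

    # level-synchronous traversal of the backward-search tree: the frontier
    # holds one row per live search state (interval, mismatch count,
    # bitmask of mismatch positions); each level consumes one query
    # position, from the 3' end to the 5' end
    sp = np.array([0], dtype=np.int64)
    ep = np.array([fm.n - 1], dtype=np.int64)
    mm = np.array([0], dtype=np.int64)
    mask = np.array([0], dtype=np.int64)
    nodes = 1  # root
    for i in range(k - 1, -1, -1):
        bound = lb.bound_before(i) if lb is not None else 0
        parts = []
        for code in range(1, len(alpha)):
            sp2, ep2 = fm._extend_codes_batch(sp, ep, code)
            mm2 = mm + (code != qcodes[i])
            keep = (sp2 <= ep2) & (mm2 + bound <= m)
            if not keep.any():
                continue
            mask2 = mask[keep]
            if code != qcodes[i]:
                mask2 = mask2 | (1 << i)
            parts.append((sp2[keep], ep2[keep], mm2[keep], mask2))
        if not parts:
            sp = np.empty(0, dtype=np.int64)
            break
        sp = np.concatenate([p[0] for p in parts])
        ep = np.concatenate([p[1] for p in parts])
        mm = np.concatenate([p[2] for p in parts])
        mask = np.concatenate([p[3] for p in parts])
        nodes += len(sp)

    hits: list[tuple[int, tuple[int, ...]]] = []
    for j in range(len(sp)):
        positions = tuple(
            pos for pos in range(k) if (int(mask[j]) >> pos) & 1
        )
        for row in range(int(sp[j]), int(ep[j]) + 1):
            hits.append((int(fm.sa[row]), positions))
    if stats is not None:
        stats["nodes_visited"] = nodes
    hits.sort()
    return hits


def resolve_hits(
    raw_hits: Sequence[tuple[int, tuple[int, ...]]],
    idx: CandidateIndex,
    sites: Sequence[CandidateSite],
    query: Query,
    params: SearchParams,
) -> list[OffTargetHit]:
    """Map concatenation offsets to candidate sites and apply self-exclusion.

    Any alignment not starting at a spacer boundary would mean a match ran
    across a sentinel — impossible by construction — and raises
    :class:`IntegrityError`.
    """
    out: list[OffTargetHit] = []
    for offset, positions in raw_hits:
        site_idx, within = idx.offset_map(offset)
        if within != 0:
            raise IntegrityError(
                f"hit offset {offset} not at a spacer boundary (within={within})"
            )
        site = sites[site_idx]
        if (
            params.exclude_self
            and query.source == "from_K"
            and site.site_id == query.site_id
            and len(positions) == 0
        ):
            continue
        out.append(
            OffTargetHit(
                query_id=query.query_id,
                site_id=site.site_id,
                chrom=site.chrom,
                start=site.start,
                end=site.end,
                strand=site.strand,
                spacer=site.spacer,
                mismatches=len(positions),
                mismatch_positions=positions,
            )
        )
    out.sort(key=lambda h: (h.mismatches, h.site_id))
    return out


def find_offtargets(
    idx: CandidateIndex,
    sites: Sequence[CandidateSite],
    query: Query,
    params: SearchParams,
    use_lower_bounds: bool = True,
) -> list[OffTargetHit]:
    """Bounded search plus hit resolution for one query."""
    raw = bounded_search(idx, query, params, use_lower_bounds=use_lower_bounds)
    return resolve_hits(raw, idx, sites, query, params)


def brute_force_offtargets(
    q: Query | str,
    sites: Sequence[CandidateSite],
    m: int,
    exclude_self: bool = False,
) -> list[OffTargetHit]:
    """Definitional oracle: direct Hamming comparison against every spacer."""
    query = q if isinstance(q, Query) else Query(query_id="q", seq=q)
    out: list[OffTargetHit] = []
    for site in sites:
        positions = tuple(
            i for i, (a, b) in enumerate(zip(query.seq, site.spacer)) if a != b
        )
        if len(positions) > m:
            continue
        if (
            exclude_self
            and query.source == "from_K"
            and site.site_id == query.site_id
            and not positions
        ):
            continue
        out.append(
            OffTargetHit(
                query_id=query.query_id,
                site_id=site.site_id,
                chrom=site.chrom,
                start=site.start,
                end=site.end,
                strand=site.strand,
                spacer=site.spacer,
                mismatches=len(positions),
                mismatch_positions=positions,
            )
        )
    out.sort(key=lambda h: (h.mismatches, h.site_id))
    return out


def scan_all_vs_all(
    idx: CandidateIndex,
    sites: Sequence[CandidateSite],
    params: SearchParams,
) -> tuple[list[OffTargetHit], pd.DataFrame]:
    """Query every member of K against the shared index, one pass.

    Returns all hits plus the per-site specificity report: one off-target
    count column per mismatch level 0..m and a ``specific`` flag, true iff
    the site has no within-K off-target inside the budget.
    """
    m = params.max_mismatches
    all_hits: list[OffTargetHit] = []
    rows = []
    for site in sites:
        query = Query(
            query_id=str(site.site_id), seq=site.spacer,
            source="from_K", site_id=site.site_id,
        )
        hits = find_offtargets(idx, sites, query, params)
        all_hits.extend(hits)
        counts = [0] * (m + 1)
        for h in hits:
            counts[h.mismatches] += 1
        rows.append([site.site_id, *counts, not hits])
    report = pd.DataFrame(
        rows,
        columns=["site_id", *[f"n_offtargets_mm{d}" for d in range(m + 1)], "specific"],
    )
    return all_hits, report


def filter_specific(
    sites: Sequence[CandidateSite],
    params: SearchParams,
    idx: CandidateIndex | None = None,
) -> tuple[list[CandidateSite], pd.DataFrame]:
    """Flag each candidate by its within-K off-target profile.

    Every site's spacer is searched against the shared index with its own
    exact self-hit excluded.  Returns the sites with no off-target within
    the budget, plus the per-site report (see :func:`scan_all_vs_all`).
    """
    if idx is None:
        idx = build_candidate_index(sites)
    self_params = SearchParams(
        max_mismatches=params.max_mismatches, exclude_self=True
    )
    _, report = scan_all_vs_all(idx, sites, self_params)
    specific_ids = set(report.loc[report["specific"], "site_id"])
    specific = [s for s in sites if s.site_id in specific_ids]
    return specific, report


_HITS_COLUMNS = [
    "query_id", "site_id", "chrom", "start", "end", "strand",
    "spacer", "mismatches", "mismatch_positions",
]


def write_hits(hits: Sequence[OffTargetHit], path) -> None:
    """Write hits as TSV; mismatch positions comma-joined."""
    rows = [
        (
            h.query_id, h.site_id, h.chrom, h.start, h.end, h.strand,
            h.spacer, h.mismatches, ",".join(map(str, h.mismatch_positions)),
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HITS_COLUMNS).to_csv(path, sep="\t", index=False)
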