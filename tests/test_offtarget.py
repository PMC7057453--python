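"""Bounded off-target search: oracle equivalence, pruning safety, hit logic."""

import numpy as np
import pytest

from conftest import make_sites
from offscan.fm_index import SENTINEL, AlphabetError
from offscan.offtarget import (
    CandidateIndex,
    IntegrityError,
    Query,
    SearchParams,
    bounded_search,
    brute_force_offtargets,
    build_candidate_index,
    compute_lower_bounds,
    concat_candidates,
    filter_specific,
    find_offtargets,
    resolve_hits,
    scan_all_vs_all,
)
from offscan.pam_scan import CandidateSite


def site(i, spacer, start=None):
    return CandidateSite(
        site_id=i, chrom="chr1", start=start if start is not None else i * 30,
        strand="+", spacer=spacer, pam_seq="TGG",
    )


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


# ------------------------------------------------------------ concatenation


def test_concat_layout():
    text, omap = concat_candidates([site(0, "ACG"), site(1, "TTT")])
    assert text.symbols == "ACG$TTT$"
    assert omap(4) == (1, 0)
    assert omap(2) == (0, 2)
    single, _ = concat_candidates([site(0, "ACG")])
    assert single.symbols == "ACG$"


def test_concat_length_arithmetic(rng):
    sites = make_sites(rng, 17, 20)
    text, _ = concat_candidates(sites)
    assert text.n == 17 * 21
    assert all(text.symbols[i] == SENTINEL for i in range(20, text.n, 21))


def test_concat_rejects_bad_input():
    with pytest.raises(ValueError):
        concat_candidates([])
    with pytest.raises(ValueError):
        concat_candidates([site(0, "ACG"), site(1, "ACGT")])


def test_index_self_match_and_query_validation(rng):
    sites = make_sites(rng, 5, 8)
    idx = build_candidate_index(sites)
    assert idx.fm.n == 5 * 9
    iv = idx.fm.exact_search(sites[2].spacer)
    assert any(p % 9 == 0 for p in idx.fm.locate(iv))
    with pytest.raises(AlphabetError):
        idx.fm.exact_search("AC$T")


def test_index_serialization_round_trip(tmp_path, rng):
    sites = make_sites(rng, 30, 20)
    idx = build_candidate_index(sites)
    path = tmp_path / "K.idx"
    idx.save(path)
    idx2 = CandidateIndex.load(path)
    assert (idx2.spacer_len, idx2.n_sites) == (20, 30)
    q = Query("q", sites[7].spacer)
    p = SearchParams(max_mismatches=2, exclude_self=False)
    assert bounded_search(idx, q, p) == bounded_search(idx2, q, p)


# ------------------------------------------------------------- lower bounds


def test_lower_bounds_examples():
    idx1 = build_candidate_index([site(0, "AAA")])
    assert list(compute_lower_bounds("AAA", idx1).lb) == [0, 0, 0]
    # every single C is absent from AAA$: each position forces a break
    assert list(compute_lower_bounds("CCC", idx1).lb) == [1, 2, 3]
    idx2 = build_candidate_index([site(0, "ACG")])
    assert list(compute_lower_bounds("ACT", idx2).lb) == [0, 0, 1]


def test_lower_bound_validity(rng):
    """Each lb[i] never exceeds the true minimum Hamming distance between
    Q[0..i] and any equal-length sentinel-free substring of the text."""
    for _ in range(30):
        sites = make_sites(rng, rng.integers(1, 20), 10)
        idx = build_candidate_index(sites)
        q = "".join(rng.choice(list("ACGT"), size=10))
        lb = compute_lower_bounds(q, idx).lb
        substrings = {
            s.spacer[a : a + L]
            for s in sites
            for L in range(1, 11)
            for a in range(11 - L)
        }
        for i in range(10):
            seg = q[: i + 1]
            true_min = min(
                (hamming(seg, t) for t in substrings if len(t) == len(seg)),
            )
            assert lb[i] <= true_min
        assert all(x <= y for x, y in zip(lb, lb[1:]))  # monotone


def test_lower_bounds_rejects_wrong_length(rng):
    idx = build_candidate_index(make_sites(rng, 3, 10))
    with pytest.raises(ValueError):
        compute_lower_bounds("ACGT", idx)


# ------------------------------------------------------------ bounded search


def test_bounded_search_triplet_example():
    sites = [site(0, "ACGT"), site(1, "ACCT"), site(2, "TTTT")]
    idx = build_candidate_index(sites)
    hits = find_offtargets(
        idx, sites, Query("q", "ACGT"), SearchParams(1, exclude_self=False)
    )
    assert [(h.site_id, h.mismatches, h.mismatch_positions) for h in hits] == [
        (0, 0, ()),
        (1, 1, (2,)),
    ]


def test_self_match_toy():
    sites = [site(0, "ANA".replace("N", "C"))]  # "ACA"
    idx = build_candidate_index(sites)
    hits = bounded_search(idx, "ACA", SearchParams(1, exclude_self=False))
    assert (0, ()) in hits


def test_oracle_equivalence_randomized(rng):
    """Bounded search equals brute-force Hamming enumeration exactly."""
    for _ in range(60):
        k = int(rng.choice([8, 20]))
        sites = make_sites(rng, int(rng.integers(1, 120)), k)
        m = int(rng.integers(0, 5))
        base = sites[rng.integers(len(sites))].spacer
        q = list(base)
        for pos in rng.choice(k, size=rng.integers(0, min(4, k)), replace=False):
            q[pos] = rng.choice([b for b in "ACGT" if b != q[pos]])
        q = "".join(q)
        idx = build_candidate_index(sites)
        params = SearchParams(m, exclude_self=False)
        got = find_offtargets(idx, sites, Query("q", q), params)
        expected = brute_force_offtargets(q, sites, m)
        assert got == expected


def test_pruning_never_changes_hits_and_reduces_nodes(rng):
    for _ in range(20):
        sites = make_sites(rng, int(rng.integers(5, 80)), 12)
        idx = build_candidate_index(sites)
        q = "".join(rng.choice(list("ACGT"), size=12))
        params = SearchParams(int(rng.integers(0, 4)), exclude_self=False)
        s_on, s_off = {}, {}
        hits_on = bounded_search(idx, q, params, use_lower_bounds=True, stats=s_on)
        hits_off = bounded_search(idx, q, params, use_lower_bounds=False, stats=s_off)
        assert hits_on == hits_off
        assert s_on["nodes_visited"] <= s_off["nodes_visited"]


def test_budget_monotonicity(rng):
    sites = make_sites(rng, 60, 8)
    idx = build_candidate_index(sites)
    q = "".join(rng.choice(list("ACGT"), size=8))
    prev: set = set()
    for m in range(5):
        hits = {
            (h.site_id, h.mismatch_positions)
            for h in find_offtargets(
                idx, sites, Query("q", q), SearchParams(m, exclude_self=False)
            )
        }
        assert prev <= hits
        prev = hits


def test_zero_budget_equals_exact_search(rng):
    sites = make_sites(rng, 100, 10)
    idx = build_candidate_index(sites)
    for _ in range(20):
        q = sites[rng.integers(len(sites))].spacer
        raw = bounded_search(idx, q, SearchParams(0, exclude_self=False))
        iv = idx.fm.exact_search(q)
        assert [off for off, _ in raw] == idx.fm.locate(iv)
        assert all(pos == () for _, pos in raw)


def test_sentinel_never_in_alignment(rng):
    sites = make_sites(rng, 50, 8)
    idx = build_candidate_index(sites)
    for _ in range(10):
        q = "".join(rng.choice(list("ACGT"), size=8))
        for off, _ in bounded_search(idx, q, SearchParams(3, exclude_self=False)):
            site_i, within = idx.offset_map(off)
            assert within == 0
            assert SENTINEL not in idx.fm.text.symbols[off : off + 8]


def test_search_rejects_overlong_budget(rng):
    idx = build_candidate_index(make_sites(rng, 3, 8))
    with pytest.raises(ValueError):
        bounded_search(idx, "ACGTACGT", SearchParams(9, exclude_self=False))


# ------------------------------------------------------------- hit resolution


def test_resolve_rejects_offset_inside_spacer(rng):
    sites = make_sites(rng, 4, 8)
    idx = build_candidate_index(sites)
    q = Query("q", sites[0].spacer)
    with pytest.raises(IntegrityError):
        resolve_hits([(3, ())], idx, sites, q, SearchParams(1, exclude_self=False))


def test_self_hit_exclusion():
    sites = [site(0, "ACGT"), site(1, "ACGT"), site(2, "GGGG")]
    idx = build_candidate_index(sites)
    q = Query("0", "ACGT", source="from_K", site_id=0)
    with_self = find_offtargets(idx, sites, q, SearchParams(0, exclude_self=False))
    assert {h.site_id for h in with_self} == {0, 1}
    without = find_offtargets(idx, sites, q, SearchParams(0, exclude_self=True))
    assert {h.site_id for h in without} == {1}  # duplicate twin retained
    user_q = Query("u", "ACGT", source="user_supplied")
    as_user = find_offtargets(idx, sites, user_q, SearchParams(0, exclude_self=True))
    assert {h.site_id for h in as_user} == {0, 1}  # exclusion only for K members


# ---------------------------------------------------------- specificity filter


def test_filter_specific_distinct_and_duplicates(rng):
    distinct = [site(0, "AAAAAAAA"), site(1, "CCCCCCCC"), site(2, "GGGGGGGG")]
    specific, report = filter_specific(distinct, SearchParams(2))
    assert [s.site_id for s in specific] == [0, 1, 2]
    assert report["specific"].all()

    dup = [site(0, "ACGTACGT"), site(1, "ACGTACGT"), site(2, "TTTTTTTT")]
    specific, report = filter_specific(dup, SearchParams(0))
    assert [s.site_id for s in specific] == [2]
    assert list(report["n_offtargets_mm0"]) == [1, 1, 0]


def test_filter_specific_planted_distance_threshold():
    a = "ACGTACGTACGTACGTACGT"
    b = "ACGTACGTACGTACGTACCA"  # Hamming distance 2 from a
    assert hamming(a, b) == 2
    far = "TGCATGCATGCATGCATGCA"
    sites = [site(0, a), site(1, b), site(2, far)]
    specific_m2, _ = filter_specific(sites, SearchParams(2))
    assert [s.site_id for s in specific_m2] == [2]
    specific_m1, _ = filter_specific(sites, SearchParams(1))
    assert [s.site_id for s in specific_m1] == [0, 1, 2]


def test_scan_all_vs_all_matches_per_site_runs(rng):
    sites = make_sites(rng, 40, 8)
    idx = build_candidate_index(sites)
    params = SearchParams(2, exclude_self=True)
    hits, report = scan_all_vs_all(idx, sites, params)
    for s in sites:
        q = Query(str(s.site_id), s.spacer, source="from_K", site_id=s.site_id)
        expected = brute_force_offtargets(q, sites, 2, exclude_self=True)
        got = [h for h in hits if h.query_id == str(s.site_id)]
        assert got == expected
    assert report["specific"].tolist() == [
        not brute_force_offtargets(
            Query(str(s.site_id), s.spacer, source="from_K", site_id=s.site_id),
            sites, 2, exclude_self=True,
        )
        for s in sites
    ]


def test_every_member_finds_itself(rng):
    sites = make_sites(rng, 80, 8)
    idx = build_candidate_index(sites)
    for s in sites:
        hits = find_offtargets(
            idx, sites, Query(str(s.site_id), s.spacer),
            SearchParams(0, exclude_self=False),
        )
        assert s.site_id in {h.site_id for h in hits}
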