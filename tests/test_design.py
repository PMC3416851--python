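"""Candidate enumeration, composition filters, and greedy lexicode design."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tagkit.core import edit_distance
from tagkit.design import (
    DesignSpec,
    build_set,
    design,
    enumerate_candidates,
    extract_subset,
    passes_filters,
    reduce_keys,
    summarize_key,
)
from tagkit.validate import validate

DEFAULTS = DesignSpec(length=4, min_distance=3)


class TestEnumeration:
    def test_dimers(self):
        cands = enumerate_candidates(2)
        assert len(cands) == 16
        assert cands[0] == "AA" and cands[-1] == "TT"

    def test_monomers(self):
        assert enumerate_candidates(1) == ["A", "C", "G", "T"]

    def test_lexicographic_order(self):
        cands = enumerate_candidates(3)
        assert cands == sorted(cands)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_candidates(0)


class TestFilters:
    @pytest.mark.parametrize(
        "seq,expected,why",
        [
            ("AAAT", False, "homopolymer run of 3"),
            ("ACGT", False, "perfect self-complement"),
            ("AACC", True, "GC 50%, runs of 2, revcomp GGTT"),
            ("AATT", False, "GC 0%"),
            ("GGCC", False, "GC 100%"),
            ("AACG", True, "GC 50%"),
        ],
    )
    def test_default_filters(self, seq, expected, why):
        assert passes_filters(seq, DEFAULTS) is expected, why

    def test_gc_bounds_inclusive(self):
        # a 5-mer with 2 GC bases sits exactly on the 40% bound and passes
        spec = DesignSpec(length=5, min_distance=3)
        assert passes_filters("AAGCA", spec)
        assert passes_filters("AGCGA", spec)  # 60%

    def test_no_filters_passes_everything(self):
        spec = DesignSpec(length=4, min_distance=3, apply_filters=False)
        assert passes_filters("AAAA", spec)


class TestSummaryVectors:
    def test_dimer_histogram_matches_brute_force(self):
        dimers = enumerate_candidates(2)
        vec = summarize_key("AA", dimers)
        brute = [0, 0, 0]
        for c in dimers:
            brute[edit_distance("AA", c)] += 1
        assert list(vec.counts) == brute == [1, 6, 9]

    def test_singleton_pool(self):
        vec = summarize_key("ACGT", ["ACGT"])
        assert vec.counts == (1,)

    @given(st.lists(st.text(alphabet="ACGT", min_size=3, max_size=3),
                    min_size=1, max_size=20))
    def test_counts_sum_to_pool_size(self, pool):
        vec = summarize_key(pool[0], pool)
        assert sum(vec.counts) == len(pool)
        assert vec.counts[0] >= 1

    def test_reduce_keeps_argmax_in_order(self):
        dimers = enumerate_candidates(2)
        vectors = [summarize_key(k, dimers) for k in dimers]
        reduced = reduce_keys(vectors, 2)
        top = max(v.count_at(2) for v in vectors)
        assert reduced == [v.key for v in vectors if v.count_at(2) == top]
        assert summarize_key("AA", dimers).count_at(2) == 9

    def test_reduce_treats_missing_entry_as_zero(self):
        vectors = [summarize_key("ACGT", ["ACGT"])]  # counts == (1,)
        assert reduce_keys(vectors, 3) == ["ACGT"]  # all tie at zero


class TestBuildSet:
    def test_distance_one_keeps_everything(self):
        dimers = enumerate_candidates(2)
        assert len(build_set("AA", dimers, 1)) == 16

    def test_unreachable_distance_leaves_key_alone(self):
        dimers = enumerate_candidates(2)
        for key in dimers:
            assert build_set(key, dimers, 3) == [key]

    def test_every_pair_at_distance(self):
        cands = enumerate_candidates(4)
        members = build_set("AACC", cands, 3)
        assert all(
            edit_distance(a, b) >= 3 for a, b in itertools.combinations(members, 2)
        )

    def test_scalar_and_vectorized_paths_agree(self):
        cands = enumerate_candidates(3)  # 64 candidates -> vectorized path
        vec = build_set("AAC", cands, 2)
        scalar_check = ["AAC"]
        for c in cands:
            if c != "AAC" and all(edit_distance(m, c) >= 2 for m in scalar_check):
                scalar_check.append(c)
        assert vec == scalar_check


class TestDesign:
    def test_no_filters_distance_one_is_whole_space(self):
        ts = design(DesignSpec(length=3, min_distance=1, apply_filters=False))
        assert len(ts) == 64

    def test_designed_set_validates_clean(self, design_d3_len5):
        report = validate(design_d3_len5)
        assert report.conforms
        assert report.observed_min_distance >= 3

    def test_members_pass_filters(self, design_d3_len5):
        spec = DesignSpec(length=5, min_distance=3)
        assert all(passes_filters(t.sequence, spec) for t in design_d3_len5)

    def test_maximality_no_candidate_can_be_added(self, design_d3_len4):
        spec = DesignSpec(length=4, min_distance=3)
        members = design_d3_len4.sequences
        pool = [c for c in enumerate_candidates(4) if passes_filters(c, spec)]
        for cand in pool:
            if cand in members:
                continue
            assert any(edit_distance(cand, m) < 3 for m in members), (
                f"{cand} could extend the designed set"
            )

    def test_greedy_size_bounded_by_exact_maximum(self):
        # with filters off at tiny n the greedy result must sit between the
        # plain lexicode baseline and the exact maximum (bitmask enumeration
        # over all 2^16 subsets of the dimer space)
        spec = DesignSpec(length=2, min_distance=2, apply_filters=False)
        ts = design(spec)
        pool = enumerate_candidates(2)
        lexicode = []
        for c in pool:
            if all(edit_distance(c, m) >= 2 for m in lexicode):
                lexicode.append(c)
        conflict = [
            sum(1 << j for j in range(16)
                if j != i and edit_distance(pool[i], pool[j]) < 2)
            for i in range(16)
        ]
        best = 0
        for mask in range(1 << 16):
            m, size, ok = mask, 0, True
            while m:
                i = (m & -m).bit_length() - 1
                if conflict[i] & mask:
                    ok = False
                    break
                size += 1
                m &= m - 1
            if ok and size > best:
                best = size
        assert len(lexicode) <= len(ts) <= best

    def test_empty_design_errors(self):
        # GC window that nothing satisfies
        spec = DesignSpec(length=4, min_distance=2, gc_min=10, gc_max=12)
        with pytest.raises(ValueError, match="no length-4 candidate"):
            design(spec)

    def test_deterministic_across_workers_and_batching(self):
        base = design(DesignSpec(length=4, min_distance=3))
        parallel = design(DesignSpec(length=4, min_distance=3, workers=2,
                                     filter_batch_size=7, row_batch_size=3))
        assert base.sequences == parallel.sequences
        assert base.names == parallel.names


class TestExtractSubset:
    def test_identity_at_same_distance(self, design_d3_len4):
        sub = extract_subset(design_d3_len4, 3)
        assert sub.sequences == design_d3_len4.sequences

    def test_higher_distance_subset_validates(self, design_d3_len5):
        sub = extract_subset(design_d3_len5, 4)
        assert 1 <= len(sub) <= len(design_d3_len5)
        if len(sub) >= 2:
            report = validate(sub)
            assert report.conforms
            assert report.observed_min_distance >= 4

    def test_lower_distance_rejected(self, design_d3_len4):
        with pytest.raises(ValueError):
            extract_subset(design_d3_len4, 2)
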