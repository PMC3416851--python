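"""Distance metrics, encodings, and capacity arithmetic."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tagkit.core import (
    InvalidAlphabetError,
    Tag,
    TagSet,
    binary_encode,
    binary_hamming_distance,
    correction_capacity,
    edit_distance,
    hamming_distance,
    normalize_sequence,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=12)
short_dna = st.text(alphabet="ACGT", min_size=0, max_size=5)


def brute_force_edit(a: str, b: str) -> int:
    """Exponential recursion oracle for the Levenshtein distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[0] == b[0] else 1
    return min(
        brute_force_edit(a[1:], b[1:]) + cost,   # match / substitute
        brute_force_edit(a[1:], b) + 1,          # delete from a
        brute_force_edit(a, b[1:]) + 1,          # insert into a
    )


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("", "ACG", 3),
            ("ACG", "", 3),
            ("", "", 0),
            # equal-length pair with Hamming distance 8 but edit distance 2:
            # a single base shifted across the tag is two edits, not eight
            ("ACGTACGT", "GACGTACG", 2),
            ("AAAA", "AAAT", 1),
            ("AAAA", "TTTT", 4),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert edit_distance(a, b) == expected

    def test_rejects_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            edit_distance("ACGN", "ACGT")

    @given(short_dna, short_dna)
    def test_matches_brute_force_recursion(self, a, b):
        assert edit_distance(a, b) == brute_force_edit(a, b)

    @given(dna, dna)
    def test_matches_edlib(self, a, b):
        edlib = pytest.importorskip("edlib")
        if not a or not b:  # edlib requires non-empty queries
            assert edit_distance(a, b) == max(len(a), len(b))
        else:
            assert edit_distance(a, b) == edlib.align(a, b, task="distance")["editDistance"]

    @given(dna, dna, dna)
    def test_metric_axioms(self, a, b, c):
        dab = edit_distance(a, b)
        assert dab >= 0
        assert (dab == 0) == (a == b)
        assert dab == edit_distance(b, a)
        assert dab <= edit_distance(a, c) + edit_distance(c, b)
        assert dab <= max(len(a), len(b))


class TestHammingAndBinary:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("AAAA", "TTTT", 4), ("ACGTACGT", "GACGTACG", 8)],
    )
    def test_hamming(self, a, b, expected):
        assert hamming_distance(a, b) == expected

    def test_hamming_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            hamming_distance("ACG", "ACGT")

    @pytest.mark.parametrize(
        "seq,bits", [("T", "00"), ("G", "01"), ("C", "10"), ("A", "11"), ("AT", "1100")]
    )
    def test_binary_encode_default_mapping(self, seq, bits):
        assert binary_encode(seq) == bits

    @pytest.mark.parametrize(
        "a,b,expected", [("A", "T", 2), ("A", "G", 1), ("ACGT", "ACGT", 0)]
    )
    def test_binary_hamming(self, a, b, expected):
        assert binary_hamming_distance(a, b) == expected

    def test_complement_swaps_cost_two_bits_others_one(self):
        # exactly the A<->T and C<->G substitutions land on the encoding
        # diagonal and cost two bits; the other four pairs cost one
        costs = {
            frozenset(p): binary_hamming_distance(*p)
            for p in itertools.combinations("ACGT", 2)
        }
        doubles = {pair for pair, c in costs.items() if c == 2}
        assert doubles == {frozenset("AT"), frozenset("CG")}
        assert all(c == 1 for pair, c in costs.items() if pair not in doubles)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=12).flatmap(
        lambda a: st.tuples(st.just(a), st.text(alphabet="ACGT",
                                                min_size=len(a), max_size=len(a)))))
    def test_equal_length_metric_ordering(self, pair):
        a, b = pair
        assert (
            edit_distance(a, b)
            <= hamming_distance(a, b)
            <= binary_hamming_distance(a, b)
        )


class TestCorrectionCapacity:
    @pytest.mark.parametrize(
        "d,detectable,correctable", [(5, 4, 2), (3, 2, 1), (1, 0, 0), (2, 1, 0), (4, 3, 1)]
    )
    def test_capacity(self, d, detectable, correctable):
        cap = correction_capacity(d)
        assert (cap.detectable, cap.correctable) == (detectable, correctable)
        assert 0 <= cap.correctable <= cap.detectable < d

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            correction_capacity(0)


class TestDomainTypes:
    def test_tag_normalizes_case(self):
        assert Tag("t", "acgt").sequence == "ACGT"

    @pytest.mark.parametrize("bad", ["", "ACGN", "ACG-T", "ACGU"])
    def test_tag_rejects_bad_sequences(self, bad):
        with pytest.raises((ValueError, InvalidAlphabetError)):
            Tag("t", bad)

    def test_tagset_rejects_duplicate_names(self):
        with pytest.raises(ValueError, match="duplicate"):
            TagSet("s", [Tag("t1", "ACGT"), Tag("t1", "TTTT")])

    def test_hamming_tagset_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal-length"):
            TagSet("s", [Tag("t1", "ACGT"), Tag("t2", "ACG")], metric="hamming")

    @given(dna)
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_normalize_rejects_iupac(self):
        with pytest.raises(InvalidAlphabetError):
            normalize_sequence("ACGTN")
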