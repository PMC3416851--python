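"""Domain types, distance metrics, encodings, and error-correction capacity.

Everything downstream (validation, design, integration, error modelling) is
built on the functions here. The edit (Levenshtein) distance is global,
unit-cost, and computed by dynamic programming; Hamming distance is the
positionwise mismatch count of equal-length strings; the binary Hamming
distance measures the bit-level separation of two sequences under a fixed
two-bits-per-base encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ALPHABET",
    "DEFAULT_BINARY_ENCODING",
    "Tag",
    "TagSet",
    "CorrectionCapacity",
    "InvalidAlphabetError",
    "normalize_sequence",
    "reverse_complement",
    "gc_percent",
    "max_homopolymer_run",
    "edit_distance",
    "hamming_distance",
    "binary_encode",
    "binary_hamming_distance",
    "correction_capacity",
]

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Two bits per base. The mapping is arbitrary but must be systematic; this
#: default (T=00, G=01, C=10, A=11) pairs complements across the diagonal so
#: that A<->T and C<->G substitutions cost two bits.
DEFAULT_BINARY_ENCODING = {"T": "00", "G": "01", "C": "10", "A": "11"}


class InvalidAlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T} after normalization."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase ``sequence`` and reject anything outside the DNA alphabet.

    IUPAC ambiguity codes are rejected: tags are fully specified synthetic
    oligos. Empty strings are allowed (distances to the empty string are
    well defined); callers that require non-empty sequences enforce that
    themselves.
    """
    seq = sequence.upper()
    for ch in seq:
        if ch not in ALPHABET:
            raise InvalidAlphabetError(
                f"invalid character {ch!r} in sequence {sequence!r}; "
                f"only A/C/G/T are allowed"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_percent(sequence: str) -> float:
    """GC content as a percentage of sequence length."""
    if not sequence:
        raise ValueError("GC content of an empty sequence is undefined")
    gc = sum(1 for ch in sequence if ch in "GC")
    return 100.0 * gc / len(sequence)


def max_homopolymer_run(sequence: str) -> int:
    """Length of the longest run of a single repeated base."""
    best = run = 0
    prev = None
    for ch in sequence:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best


@dataclass(frozen=True)
class Tag:
    """A named nucleotide sequence over {A, C, G, T}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if not seq:
            raise ValueError(f"tag {self.name!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


VALID_METRICS = ("edit", "hamming", "binary_hamming")


@dataclass
class TagSet:
    """An ordered collection of tags with a declared metric and minimum distance.

    ``expected_min_distance`` is the design claim the set carries (``d``); the
    validator checks observed pairwise distances against it. For the Hamming
    metrics all sequences must be the same length.
    """

    name: str
    tags: list[Tag] = field(default_factory=list)
    metric: str = "edit"
    expected_min_distance: int = 1

    def __post_init__(self) -> None:
        if self.metric not in VALID_METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; expected one of {VALID_METRICS}"
            )
        if self.expected_min_distance < 1:
            raise ValueError("expected_min_distance must be >= 1")
        names = [t.name for t in self.tags]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tag names in set {self.name!r}: {dupes}")
        if self.metric in ("hamming", "binary_hamming") and self.tags:
            lengths = {len(t) for t in self.tags}
            if len(lengths) > 1:
                raise ValueError(
                    f"metric {self.metric!r} requires equal-length tags; "
                    f"found lengths {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    @property
    def sequences(self) -> list[str]:
        return [t.sequence for t in self.tags]

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tags]

    @classmethod
    def from_sequences(
        cls,
        sequences,
        name: str = "tagset",
        metric: str = "edit",
        expected_min_distance: int = 1,
        prefix: str = "Tag",
    ) -> "TagSet":
        """Build a set from bare sequences, auto-naming ``Tag1..TagN`` in order."""
        tags = [Tag(f"{prefix}{i}", s) for i, s in enumerate(sequences, start=1)]
        return cls(name=name, tags=tags, metric=metric,
                   expected_min_distance=expected_min_distance)


def edit_distance(a: str, b: str) -> int:
    """Global unit-cost Levenshtein distance between two nucleotide strings.

    Insertions, deletions, and substitutions each cost one. Computed with the
    standard two-row dynamic program in O(len(a) * len(b)). Inputs must
    already be normalized (use :func:`normalize_sequence`); empty strings are
    allowed.
    """
    for s in (a, b):
        for ch in s:
            if ch not in ALPHABET:
                raise InvalidAlphabetError(f"invalid character {ch!r} in {s!r}")
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    # keep the inner loop over the shorter string
    if lb > la:
        a, b, la, lb = b, a, lb, la
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[lb]


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(
            f"Hamming distance is undefined for unequal lengths "
            f"({len(a)} vs {len(b)})"
        )
    return sum(1 for x, y in zip(a, b) if x != y)


def binary_encode(sequence: str, encoding: dict[str, str] | None = None) -> str:
    """Concatenated two-bit codes for each base.

    The default mapping is T=00, G=01, C=10, A=11. Any systematic two-bit
    mapping may be supplied instead; it must cover all four bases.
    """
    enc = DEFAULT_BINARY_ENCODING if encoding is None else encoding
    try:
        return "".join(enc[ch] for ch in sequence)
    except KeyError as exc:
        raise InvalidAlphabetError(
            f"base {exc.args[0]!r} missing from binary encoding"
        ) from None


def binary_hamming_distance(
    a: str, b: str, encoding: dict[str, str] | None = None
) -> int:
    """Hamming distance between the binary encodings of two sequences.

    Each base position contributes 0, 1, or 2 bit differences; substitutions
    between complementary bases under the default encoding (A<->T, C<->G)
    contribute 2, which is what makes one third of single-nucleotide
    substitutions uncorrectable for binary-encoded Hamming codes.
    """
    if len(a) != len(b):
        raise ValueError(
            f"binary Hamming distance is undefined for unequal lengths "
            f"({len(a)} vs {len(b)})"
        )
    return hamming_distance(binary_encode(a, encoding), binary_encode(b, encoding))


@dataclass(frozen=True)
class CorrectionCapacity:
    """Error detection/correction capacity of a code with minimum distance ``d``."""

    distance: int
    detectable: int
    correctable: int


def correction_capacity(d: int) -> CorrectionCapacity:
    """Capacity of a minimum-distance-``d`` code: detect ``d - 1``, correct ``floor((d - 1) / 2)``.

    A set with minimum edit distance five therefore corrects up to two errors
    per tag; distance three corrects one.
    """
    if d < 1:
        raise ValueError(f"minimum distance must be >= 1, got {d}")
    detectable = d - 1
    return CorrectionCapacity(distance=d, detectable=detectable,
                              correctable=detectable // 2)


def distance_function(metric: str):
    """Return the pairwise distance callable for a metric name."""
    if metric == "edit":
        return edit_distance
    if metric == "hamming":
        return hamming_distance
    if metric == "binary_hamming":
        return binary_hamming_distance
    raise ValueError(f"unknown metric {metric!r}; expected one of {VALID_METRICS}")
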