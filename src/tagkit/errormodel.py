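"""Error models for sequence tags and a minimal error-correcting assigner.

With a uniform per-base error rate ``p`` and tag length ``L``, the number of
errors in one tag is Binomial(L, p); in a run of ``N`` reads the expected
number of reads carrying at least ``k`` tag errors is ``N * P(X >= k)``. At
p = 1% and L = 8 that is already ~8% of a million-read run — the reason tag
sets need enough minimum distance to absorb errors. A Monte-Carlo twin of the
closed form draws per-read error counts (with a configurable mix of
substitutions, insertions, and deletions) and supports corrupting concrete
sequences for round-trip demultiplexing checks.

``k`` defaults to 1 (reads with *at least one* tag error). The "more than one
error" reading is available as ``min_errors=2``; both are exposed because the
two readings differ by an order of magnitude and neither should be chosen
silently for the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from tagkit.core import (
    ALPHABET,
    DEFAULT_BINARY_ENCODING,
    TagSet,
    binary_encode,
    correction_capacity,
    edit_distance,
    hamming_distance,
)
from tagkit.validate import validate

__all__ = [
    "ErrorModelSpec",
    "expected_error_reads",
    "simulate_error_reads",
    "corrupt_sequence",
    "edit_neighborhood",
    "binary_correctability_fraction",
    "assign_tag",
]


@dataclass(frozen=True)
class ErrorModelSpec:
    """Uniform per-base error model for a tag of length ``L`` in ``N`` reads.

    ``error_mix`` gives the proportions (substitution, insertion, deletion)
    of error events; it only matters when corrupting concrete sequences —
    the count of error events per read is mix-independent.
    """

    per_base_error_rate: float
    tag_length: int
    read_count: int
    min_errors: int = 1
    seed: int | None = None
    error_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1]")
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if self.min_errors < 1:
            raise ValueError("min_errors must be >= 1")
        mix = self.error_mix
        if len(mix) != 3 or any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must be 3 non-negative proportions summing to 1")


def expected_error_reads(spec: ErrorModelSpec) -> float:
    """Closed form: ``N * P(Binomial(L, p) >= min_errors)``."""
    p_affected = stats.binom.sf(spec.min_errors - 1, spec.tag_length,
                                spec.per_base_error_rate)
    return spec.read_count * float(p_affected)


def simulate_error_reads(spec: ErrorModelSpec) -> int:
    """Monte-Carlo twin of :func:`expected_error_reads`.

    Draws the per-base error indicators for every read and counts reads with
    at least ``min_errors`` error events. Reproducible under a fixed seed and
    converges on the closed form as ``read_count`` grows.
    """
    if spec.seed is None:
        raise ValueError("Monte-Carlo simulation requires a seed")
    rng = np.random.default_rng(spec.seed)
    errors_per_read = rng.binomial(
        spec.tag_length, spec.per_base_error_rate, size=spec.read_count
    )
    return int((errors_per_read >= spec.min_errors).sum())


def corrupt_sequence(sequence: str, n_errors: int, rng: np.random.Generator,
                     error_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)) -> str:
    """Apply ``n_errors`` random edit operations of the given mix to a sequence."""
    seq = list(sequence)
    kinds = rng.choice(3, size=n_errors, p=list(error_mix))
    for kind in kinds:
        if kind == 0 and seq:  # substitution
            pos = int(rng.integers(len(seq)))
            choices = [b for b in ALPHABET if b != seq[pos]]
            seq[pos] = choices[int(rng.integers(3))]
        elif kind == 1:  # insertion
            pos = int(rng.integers(len(seq) + 1))
            seq.insert(pos, ALPHABET[int(rng.integers(4))])
        elif seq:  # deletion
            pos = int(rng.integers(len(seq)))
            del seq[pos]
    return "".join(seq)


def edit_neighborhood(sequence: str, radius: int) -> set[str]:
    """All strings reachable from ``sequence`` by at most ``radius`` edits.

    Exhaustive enumeration over substitutions, insertions, and deletions;
    intended for small radii (1-2) and short tags.
    """
    frontier = {sequence}
    seen = {sequence}
    for _ in range(radius):
        nxt = set()
        for s in frontier:
            for i in range(len(s)):
                for b in ALPHABET:  # substitutions (incl. no-ops, harmless)
                    nxt.add(s[:i] + b + s[i + 1:])
                nxt.add(s[:i] + s[i + 1:])  # deletion
            for i in range(len(s) + 1):
                for b in ALPHABET:  # insertion
                    nxt.add(s[:i] + b + s[i:])
        frontier = nxt - seen
        seen |= nxt
    return seen


def binary_correctability_fraction(
    encoding: dict[str, str] | None = None,
) -> tuple[float, float]:
    """Fractions of single-nucleotide substitutions that defeat binary Hamming codes.

    Enumerates all 6 unordered nucleotide pairs under the two-bit encoding and
    returns ``(uncorrectable, correctable)``: the fraction whose encodings
    differ in two bits (detectable but uncorrectable by a single-bit-correcting
    code) and its complement. Under any systematic two-bit encoding exactly
    2 of the 6 pairs differ in both bits, so the split is (2/6, 4/6).
    """
    enc = DEFAULT_BINARY_ENCODING if encoding is None else encoding
    pairs = list(combinations(ALPHABET, 2))
    double = sum(
        1
        for a, b in pairs
        if hamming_distance(binary_encode(a, enc), binary_encode(b, enc)) == 2
    )
    return double / len(pairs), (len(pairs) - double) / len(pairs)


def assign_tag(
    observed: str,
    tagset: TagSet,
    radius: int | None = None,
    _validated: bool = False,
) -> str | None:
    """Assign an observed tag sequence to a member of an edit-metric set.

    An exact match wins immediately; otherwise the unique tag within the
    correction radius ``floor((d - 1) / 2)`` is returned; ties or no tag in
    range give ``None`` (read unassigned). The set is validated against its
    declared minimum distance first — correction within the radius is only
    guaranteed for a conforming set. For bulk assignment pre-validate once
    and pass ``_validated=True``.
    """
    d = tagset.expected_min_distance
    if not _validated:
        report = validate(tagset, metric="edit")
        if not report.conforms:
            raise ValueError(
                f"tag set {tagset.name!r} violates its declared minimum distance "
                f"{d} (observed {report.observed_min_distance}); "
                f"correction radius is undefined"
            )
    r = radius if radius is not None else correction_capacity(d).correctable
    best_tag = None
    best_dist = None
    tied = False
    for tag in tagset:
        dist = edit_distance(observed, tag.sequence)
        if dist == 0:
            return tag.name
        if best_dist is None or dist < best_dist:
            best_tag, best_dist, tied = tag, dist, False
        elif dist == best_dist:
            tied = True
    if best_dist is not None and best_dist <= r and not tied:
        return best_tag.name
    return None
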