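"""Audit tag sets for conformance to a distance metric.

Given a set with a declared metric and expected minimum distance ``d``, the
validator computes every unordered pairwise distance and reports the observed
minimum, the pairs falling below ``d``, the full matrix, and — via the
rescanning helper — how many tags survive culling to a (possibly stricter)
threshold ``D``. Tags embedded in primers or adapters are validated by
passing the slice coordinates of the tag within each oligo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from tagkit.core import Tag, TagSet, distance_function

__all__ = ["DistanceReport", "validate", "rescan_conforming"]


@dataclass
class DistanceReport:
    """Validation output for one tag set.

    ``matrix`` is the symmetric pairwise distance table in tag order (zero
    diagonal); ``pair_violations`` holds exactly the unordered pairs with
    distance below ``expected_min_distance``; ``conforming_counts`` maps a
    threshold ``D`` to the number of tags retained by greedy culling at ``D``.
    """

    metric: str
    expected_min_distance: int
    tag_names: list[str]
    matrix: list[list[int]]
    observed_min_distance: int
    pair_violations: list[tuple[str, str, int]]
    conforming_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_tags(self) -> int:
        return len(self.tag_names)

    @property
    def conforms(self) -> bool:
        return not self.pair_violations


def _extract(tagset: TagSet, slices) -> list[Tag]:
    """Pull the tag slice out of each oligo when coordinates are supplied."""
    if slices is None:
        return list(tagset.tags)
    if isinstance(slices, tuple):
        slices = [slices] * len(tagset)
    if len(slices) != len(tagset):
        raise ValueError("need one (start, end) slice per tag")
    out = []
    for tag, (start, end) in zip(tagset, slices):
        sub = tag.sequence[start:end]
        if not sub:
            raise ValueError(
                f"slice [{start}:{end}) of {tag.name!r} is empty "
                f"(oligo length {len(tag)})"
            )
        out.append(Tag(tag.name, sub))
    return out


def validate(
    tagset: TagSet,
    metric: str | None = None,
    expected_min_distance: int | None = None,
    slices: tuple[int, int] | list[tuple[int, int]] | None = None,
    rescan_at: tuple[int, ...] = (),
) -> DistanceReport:
    """Compute all pairwise distances of a tag set and report conformance.

    ``metric`` and ``expected_min_distance`` default to the set's declared
    values. ``slices`` gives 0-based half-open tag coordinates within each
    sequence for sets of tagged oligos (one pair for all, or one per tag).
    ``rescan_at`` adds greedy-culling retention counts at each threshold to
    ``conforming_counts``. Output verbosity is a serialization concern (see
    :mod:`tagkit.tagio`); the full matrix is always computed.
    """
    metric = metric or tagset.metric
    d_exp = (
        expected_min_distance
        if expected_min_distance is not None
        else tagset.expected_min_distance
    )
    if d_exp < 1:
        raise ValueError("expected minimum distance must be >= 1")
    tags = _extract(tagset, slices)
    if len(tags) < 2:
        raise ValueError(
            f"validation needs at least 2 tags; set {tagset.name!r} has {len(tags)}"
        )
    dist = distance_function(metric)
    if metric in ("hamming", "binary_hamming"):
        lengths = {len(t) for t in tags}
        if len(lengths) > 1:
            raise ValueError(
                f"metric {metric!r} requires equal-length tags; "
                f"found lengths {sorted(lengths)}"
            )

    n = len(tags)
    matrix = [[0] * n for _ in range(n)]
    violations: list[tuple[str, str, int]] = []
    observed_min = None
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(tags[i].sequence, tags[j].sequence)
            matrix[i][j] = matrix[j][i] = d
            if observed_min is None or d < observed_min:
                observed_min = d
            if d < d_exp:
                violations.append((tags[i].name, tags[j].name, d))

    report = DistanceReport(
        metric=metric,
        expected_min_distance=d_exp,
        tag_names=[t.name for t in tags],
        matrix=matrix,
        observed_min_distance=observed_min,
        pair_violations=violations,
    )
    for threshold in rescan_at:
        count, _ = rescan_conforming(tagset, metric=metric, min_distance=threshold,
                                     slices=slices)
        report.conforming_counts[threshold] = count
    return report


def rescan_conforming(
    tagset: TagSet,
    metric: str | None = None,
    min_distance: int | None = None,
    slices: tuple[int, int] | list[tuple[int, int]] | None = None,
) -> tuple[int, list[Tag]]:
    """Greedily cull a set until every remaining pair is at least ``min_distance`` apart.

    The culling rule is deterministic: repeatedly remove the tag participating
    in the most sub-threshold pairs, breaking ties by removing the
    lexicographically larger sequence (then name), until no violating pair
    remains. Returns the retained count and tags in their original order. The
    retained set always passes :func:`validate` at ``min_distance`` — but it is
    a greedy (not provably maximum) conforming subset.
    """
    metric = metric or tagset.metric
    D = min_distance if min_distance is not None else tagset.expected_min_distance
    if D < 1:
        raise ValueError("min_distance must be >= 1")
    tags = _extract(tagset, slices)
    dist = distance_function(metric)
    n = len(tags)
    conflict = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if dist(tags[i].sequence, tags[j].sequence) < D:
                conflict[i][j] = conflict[j][i] = True

    alive = set(range(n))
    while True:
        degree = {
            i: sum(1 for j in alive if j != i and conflict[i][j]) for i in alive
        }
        worst = max(degree.values(), default=0)
        if worst == 0:
            break
        # ties: drop the lexicographically larger sequence, then larger name
        victim = max(
            (i for i, deg in degree.items() if deg == worst),
            key=lambda i: (tags[i].sequence, tags[i].name),
        )
        alive.remove(victim)
    retained = [tags[i] for i in sorted(alive)]
    return len(retained), retained
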