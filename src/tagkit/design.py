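"""Greedy lexicode construction of maximal edit-metric tag sets.

The pipeline mirrors the classic lexicode idea — scan candidates in a fixed
order and keep those far enough from everything already kept — with two
practical modifications that keep long tag lengths tractable on a desktop:

1. **Composition filters** remove candidates with homopolymer runs, skewed GC
   content, or perfect self-complementarity before any distance work.
2. **Summary-vector reduction** computes, for every surviving candidate taken
   as a "key", a histogram of how many candidates sit at each edit distance
   from it, then keeps only the keys with the maximum count at the target
   distance ``d``. Only those keys seed the expensive greedy construction,
   and only histograms (never a full pairwise matrix) are held in memory.

For each surviving key the greedy build drops candidates closer than ``d`` to
the key and then scans the remainder in candidate order, retaining a tag iff
it is at least ``d`` from every previously retained tag. The largest resulting
set wins; ties go to the lexicographically smallest key.

Candidate order is lexicographic with A < C < G < T everywhere. The greedy
outcome (content and size of the final set) depends on this order; any fixed
order yields a valid, maximal set, but published counts from other
implementations may differ by a few tags if their ordering differed.
"""

from __future__ import annotations

import itertools
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace

import numpy as np

from tagkit._batch import encode_pool, levenshtein_to_pool
from tagkit.core import (
    TagSet,
    edit_distance,
    gc_percent,
    max_homopolymer_run,
    normalize_sequence,
    reverse_complement,
)

__all__ = [
    "DesignSpec",
    "SummaryVector",
    "enumerate_candidates",
    "passes_filters",
    "summarize_key",
    "reduce_keys",
    "build_set",
    "design",
    "extract_subset",
]

MAX_LENGTH = 12  # 4^12 ~ 17M candidates; beyond this the pipeline is not desk-scale


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one design run.

    ``length``/``min_distance`` define the code; the filter fields control the
    composition screen (GC bounds are inclusive percentages); the batch sizes
    and ``workers`` are throughput knobs only — results are identical for any
    batching or worker count.
    """

    length: int
    min_distance: int
    max_homopolymer_run: int = 2
    gc_min: float = 40.0
    gc_max: float = 60.0
    reject_self_complement: bool = True
    apply_filters: bool = True
    filter_batch_size: int = 25_000
    row_batch_size: int = 500
    workers: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.length <= MAX_LENGTH:
            raise ValueError(f"length must be in [1, {MAX_LENGTH}], got {self.length}")
        if not 1 <= self.min_distance <= self.length:
            raise ValueError(
                f"min_distance must be in [1, length={self.length}], "
                f"got {self.min_distance}"
            )
        if not 0 <= self.gc_min <= self.gc_max <= 100:
            raise ValueError("need 0 <= gc_min <= gc_max <= 100")
        if self.max_homopolymer_run < 1:
            raise ValueError("max_homopolymer_run must be >= 1")
        if self.filter_batch_size < 1 or self.row_batch_size < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass(frozen=True)
class SummaryVector:
    """Histogram of candidate counts per edit distance from one key.

    ``counts[i]`` is the number of candidates at edit distance exactly ``i``
    from ``key`` (the key itself contributes to ``counts[0]`` when it is in
    the pool). Keeping these histograms instead of a full pairwise matrix is
    what makes long tag lengths feasible in memory.
    """

    key: str
    counts: tuple[int, ...]

    def count_at(self, d: int) -> int:
        return self.counts[d] if d < len(self.counts) else 0


def enumerate_candidates(length: int) -> list[str]:
    """All ``4^length`` sequences in lexicographic order (A < C < G < T)."""
    if not 1 <= length <= MAX_LENGTH:
        raise ValueError(f"length must be in [1, {MAX_LENGTH}], got {length}")
    return ["".join(p) for p in itertools.product("ACGT", repeat=length)]


def passes_filters(sequence: str, spec: DesignSpec) -> bool:
    """Composition screen: homopolymer runs, GC bounds, self-complementarity.

    True iff the sequence has no single-base run longer than
    ``spec.max_homopolymer_run``, GC percentage within
    ``[gc_min, gc_max]`` inclusive, and (when ``reject_self_complement``)
    is not equal to its own reverse complement. With ``apply_filters=False``
    everything passes.
    """
    seq = normalize_sequence(sequence)
    if not spec.apply_filters:
        return True
    if max_homopolymer_run(seq) > spec.max_homopolymer_run:
        return False
    if not spec.gc_min <= gc_percent(seq) <= spec.gc_max:
        return False
    if spec.reject_self_complement and seq == reverse_complement(seq):
        return False
    return True


def summarize_key(key: str, candidates: list[str]) -> SummaryVector:
    """Edit-distance histogram of ``candidates`` around ``key``.

    ``counts[i]`` = number of candidates at distance exactly ``i``; the
    vector spans 0..max observed distance.
    """
    if candidates and len(set(map(len, candidates))) == 1 and len(candidates) > 32:
        pool = encode_pool(candidates)
        dists = levenshtein_to_pool(key, pool)
    else:
        dists = np.array([edit_distance(key, c) for c in candidates], dtype=np.int64)
    counts = np.bincount(dists) if len(dists) else np.zeros(1, dtype=np.int64)
    return SummaryVector(key=key, counts=tuple(int(c) for c in counts))


def reduce_keys(vectors: list[SummaryVector], d: int) -> list[str]:
    """Keys whose count at distance ``d`` equals the maximum, in input order.

    A vector too short to have an entry at ``d`` counts as zero. This is the
    pruning step: only these keys seed greedy construction.
    """
    if not vectors:
        return []
    scores = [v.count_at(d) for v in vectors]
    top = max(scores)
    return [v.key for v, s in zip(vectors, scores) if s == top]


def build_set(key: str, candidates: list[str], d: int) -> list[str]:
    """Greedy lexicode build seeded at ``key``.

    Candidates closer than ``d`` to the key are dropped; the rest are scanned
    in candidate order, each retained iff it is at least ``d`` from every
    previously retained tag. The result (key included) has every pair at
    distance >= ``d`` and is maximal: no dropped candidate can be added.
    """
    if d < 1:
        raise ValueError("min distance must be >= 1")
    equal_len = candidates and len(set(map(len, candidates))) == 1
    if equal_len and len(candidates) > 32:
        pool = encode_pool(candidates)
        alive = levenshtein_to_pool(key, pool) >= d
        alive &= np.array([c != key for c in candidates])
        members = [key]
        idx = np.arange(len(candidates))
        while True:
            live = idx[alive]
            if live.size == 0:
                break
            nxt = int(live[0])
            members.append(candidates[nxt])
            alive[nxt] = False
            still = idx[alive]
            if still.size:
                dists = levenshtein_to_pool(candidates[nxt], pool[still])
                alive[still[dists < d]] = False
        return members
    members = [key]
    for cand in candidates:
        if cand == key:
            continue
        if all(edit_distance(m, cand) >= d for m in members):
            members.append(cand)
    return members


# -- multiprocessing plumbing ------------------------------------------------
# Batches are mapped in order and reassembled in order, so the result is
# byte-identical to the serial computation for any worker count.

_POOL_SEQS: list[str] = []
_POOL_MAT: np.ndarray | None = None
_POOL_D: int = 0


def _init_pool(seqs: list[str], d: int) -> None:
    global _POOL_SEQS, _POOL_MAT, _POOL_D
    _POOL_SEQS = seqs
    _POOL_MAT = encode_pool(seqs)
    _POOL_D = d


def _filter_batch(args) -> list[str]:
    batch, spec = args
    return [s for s in batch if passes_filters(s, spec)]


def _score_batch(key_span: tuple[int, int]) -> np.ndarray:
    """Counts at distance exactly d for each key in [start, stop)."""
    start, stop = key_span
    out = np.empty(stop - start, dtype=np.int64)
    for i in range(start, stop):
        dists = levenshtein_to_pool(_POOL_SEQS[i], _POOL_MAT)
        out[i - start] = int((dists == _POOL_D).sum())
    return out


def _chunks(items, size):
    for i in range(0, len(items), size):
        yield items[i:i + size]


def design(spec: DesignSpec) -> TagSet:
    """Run the full pipeline: enumerate, filter, summarize, reduce, build.

    Returns the largest greedy set over all reduced keys (ties broken by the
    lexicographically smallest key) as a :class:`~tagkit.core.TagSet` with
    tags auto-named ``Tag1..TagN`` in lexicographic sequence order. Every pair
    in the result is at least ``min_distance`` apart, every member passes the
    composition filters, and no filtered candidate outside the set could be
    added without violating the distance.
    """
    candidates = enumerate_candidates(spec.length)

    batches = list(_chunks(candidates, spec.filter_batch_size))
    if spec.workers > 1 and len(batches) > 1:
        with ProcessPoolExecutor(max_workers=spec.workers) as ex:
            filtered_batches = list(ex.map(_filter_batch, [(b, spec) for b in batches]))
    else:
        filtered_batches = [_filter_batch((b, spec)) for b in batches]
    pool = [s for batch in filtered_batches for s in batch]
    if not pool:
        raise ValueError(
            f"no length-{spec.length} candidate survives the composition filters"
        )

    d = spec.min_distance
    spans = [(i, min(i + spec.row_batch_size, len(pool)))
             for i in range(0, len(pool), spec.row_batch_size)]
    if spec.workers > 1 and len(spans) > 1:
        with ProcessPoolExecutor(
            max_workers=spec.workers, initializer=_init_pool, initargs=(pool, d)
        ) as ex:
            score_parts = list(ex.map(_score_batch, spans))
    else:
        _init_pool(pool, d)
        score_parts = [_score_batch(span) for span in spans]
    scores = np.concatenate(score_parts)

    top = scores.max()
    reduced = [pool[i] for i in np.flatnonzero(scores == top)]

    best_members: list[str] | None = None
    best_key: str | None = None
    for key in reduced:  # reduced is in lexicographic order
        members = build_set(key, pool, d)
        if best_members is None or len(members) > len(best_members):
            best_members, best_key = members, key
    assert best_members is not None

    name = f"design_L{spec.length}_D{d}"
    return TagSet.from_sequences(
        sorted(best_members), name=name, metric="edit", expected_min_distance=d
    )


def extract_subset(tagset: TagSet, d_prime: int) -> TagSet:
    """Higher-distance subset shortcut.

    From a designed set with minimum distance ``d``, quickly pull a subset
    whose pairwise distances are all at least ``d_prime >= d``: each member in
    turn is taken as key, members closer than ``d_prime`` to it are dropped,
    and the rest are greedily retained in lexicographic order; the largest
    subset wins (ties to the smallest key). With ``d_prime == d`` the input
    set is returned unchanged. The shortcut does not guarantee the largest
    possible ``d_prime`` code — rerunning the full design at ``d_prime`` may
    yield more tags.
    """
    d = tagset.expected_min_distance
    if d_prime < d:
        raise ValueError(
            f"subset distance {d_prime} is below the set's minimum distance {d}"
        )
    seqs = sorted(t.sequence for t in tagset)
    best: list[str] | None = None
    for key in seqs:
        members = build_set(key, seqs, d_prime)
        if best is None or len(members) > len(best):
            best = members
    assert best is not None
    name = f"{tagset.name}_D{d_prime}"
    return TagSet.from_sequences(
        sorted(best), name=name, metric="edit", expected_min_distance=d_prime
    )
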