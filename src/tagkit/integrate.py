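"""Place sequence tags into PCR primers and sequencing adapters.

Fusion primers carry the tag at the 5' end of both the upper and lower
primer, optionally behind a ``GTTT`` pigtail that promotes non-templated +A
addition for T/A ligation. Where the tag's 3' end duplicates the primer's 5'
end, the overlap can be collapsed once to shorten the synthesis. Tagged
oligos are screened with a string-complementarity heuristic for hairpins and
dimers; an external thermodynamic evaluator can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from tagkit.core import Tag, TagSet, normalize_sequence, reverse_complement

__all__ = [
    "ScreenScores",
    "TaggedPrimerPair",
    "TaggedAdapter",
    "tag_primer",
    "screen_structure",
    "cross_dimer_length",
    "tag_all_primers",
    "tag_adapter",
]

DEFAULT_PIGTAIL = "GTTT"


@dataclass(frozen=True)
class ScreenScores:
    """Structure-screen result for one oligo.

    ``hairpin_stem_len`` is the longest self-folding stem (a substring whose
    reverse complement occurs downstream, past a minimum loop); ``self_dimer_len``
    the longest substring whose reverse complement occurs anywhere else in the
    same oligo; ``flagged`` is true when either reaches the stem threshold.
    """

    hairpin_stem_len: int
    self_dimer_len: int
    min_stem: int
    min_loop: int

    @property
    def flagged(self) -> bool:
        return (
            self.hairpin_stem_len >= self.min_stem
            or self.self_dimer_len >= self.min_stem
        )


@dataclass(frozen=True)
class TaggedPrimerPair:
    """One tag integrated into both primers of a PCR pair."""

    tag: Tag
    upper_primer: str
    lower_primer: str
    pigtail: str
    trim_common: bool
    upper_oligo: str
    lower_oligo: str
    upper_trim: int
    lower_trim: int
    upper_screen: ScreenScores
    lower_screen: ScreenScores
    cross_dimer_len: int

    @property
    def flagged(self) -> bool:
        return self.upper_screen.flagged or self.lower_screen.flagged


@dataclass(frozen=True)
class TaggedAdapter:
    """A tag positioned inside an adapter, with its slice recorded."""

    tag: Tag
    five_prime_part: str
    three_prime_part: str
    full_sequence: str
    tag_slice: tuple[int, int]


def _common_overlap(tag_seq: str, primer: str) -> int:
    """Longest suffix of the tag equal to a prefix of the primer."""
    best = 0
    for k in range(1, min(len(tag_seq), len(primer)) + 1):
        if tag_seq[-k:] == primer[:k]:
            best = k
    return best


def tag_primer(
    tag: Tag,
    primer: str,
    pigtail: str | None = DEFAULT_PIGTAIL,
    trim_common: bool = True,
) -> tuple[str, int]:
    """Prepend a tag (and optional pigtail) to a primer's 5' end.

    When ``trim_common`` the longest suffix of the tag equal to a prefix of
    the primer is collapsed once, so the shared bases are synthesized only
    within the tag. Returns ``(oligo, k)`` where ``k`` is the collapsed
    length. A tag that swallows the entire primer is an error.
    """
    primer = normalize_sequence(primer)
    if not primer:
        raise ValueError("primer sequence is empty")
    pig = normalize_sequence(pigtail) if pigtail else ""
    k = _common_overlap(tag.sequence, primer) if trim_common else 0
    if k == len(primer):
        raise ValueError(
            f"tag {tag.name!r} ({tag.sequence}) swallows the entire primer {primer!r}"
        )
    return pig + tag.sequence + primer[k:], k


def screen_structure(oligo: str, min_stem: int = 4, min_loop: int = 3) -> ScreenScores:
    """String-complementarity screen for hairpins and self-dimers.

    The hairpin stem is the longest ``L`` for which some length-``L``
    substring has its reverse complement occurring downstream in the same
    oligo with at least ``min_loop`` unpaired bases between them. The
    self-dimer length is the longest substring whose reverse complement
    occurs anywhere else (different start position) in the oligo. This is a
    heuristic on strings, not a thermodynamic model: it ranks candidates and
    flags obvious fold-back structure but knows nothing of melting
    temperatures. Pass a different ``screen`` callable to
    :func:`tag_all_primers` to plug in an external evaluator.
    """
    oligo = normalize_sequence(oligo)
    n = len(oligo)
    hairpin = 0
    dimer = 0
    for L in range(1, n // 2 + 1):
        found_hairpin = found_dimer = False
        rc_cache: dict[str, str] = {}
        for i in range(0, n - L + 1):
            sub = oligo[i:i + L]
            rc = rc_cache.get(sub)
            if rc is None:
                rc = reverse_complement(sub)
                rc_cache[sub] = rc
            # hairpin: rc downstream, separated by >= min_loop bases
            j = oligo.find(rc, i + L + min_loop)
            if j != -1:
                found_hairpin = True
            # self-dimer: rc anywhere at a different start
            j = oligo.find(rc)
            while j != -1:
                if j != i:
                    found_dimer = True
                    break
                j = oligo.find(rc, j + 1)
            if found_hairpin and found_dimer:
                break
        if found_hairpin:
            hairpin = L
        if found_dimer:
            dimer = L
        if not found_hairpin and not found_dimer:
            break
    return ScreenScores(hairpin_stem_len=hairpin, self_dimer_len=dimer,
                        min_stem=min_stem, min_loop=min_loop)


def cross_dimer_length(a: str, b: str) -> int:
    """Longest substring of ``a`` whose reverse complement occurs in ``b``."""
    a = normalize_sequence(a)
    b = normalize_sequence(b)
    best = 0
    for L in range(1, min(len(a), len(b)) + 1):
        hit = False
        for i in range(0, len(a) - L + 1):
            if reverse_complement(a[i:i + L]) in b:
                hit = True
                break
        if not hit:
            break
        best = L
    return best


def tag_pair(
    tag: Tag,
    upper_primer: str,
    lower_primer: str,
    pigtail: str | None = DEFAULT_PIGTAIL,
    trim_common: bool = True,
    min_stem: int = 4,
    min_loop: int = 3,
    screen: Callable[[str], ScreenScores] | None = None,
) -> TaggedPrimerPair:
    """Integrate one tag into both primers and screen the resulting oligos."""
    screen_fn = screen or (lambda o: screen_structure(o, min_stem, min_loop))
    upper_oligo, ku = tag_primer(tag, upper_primer, pigtail, trim_common)
    lower_oligo, kl = tag_primer(tag, lower_primer, pigtail, trim_common)
    return TaggedPrimerPair(
        tag=tag,
        upper_primer=normalize_sequence(upper_primer),
        lower_primer=normalize_sequence(lower_primer),
        pigtail=normalize_sequence(pigtail) if pigtail else "",
        trim_common=trim_common,
        upper_oligo=upper_oligo,
        lower_oligo=lower_oligo,
        upper_trim=ku,
        lower_trim=kl,
        upper_screen=screen_fn(upper_oligo),
        lower_screen=screen_fn(lower_oligo),
        cross_dimer_len=cross_dimer_length(upper_oligo, lower_oligo),
    )


def tag_all_primers(
    tagset: TagSet,
    upper_primer: str,
    lower_primer: str,
    pigtail: str | None = DEFAULT_PIGTAIL,
    trim_common: bool = True,
    min_stem: int = 4,
    min_loop: int = 3,
    screen: Callable[[str], ScreenScores] | None = None,
    exclude_flagged: bool = False,
) -> pd.DataFrame:
    """Integrate every tag of a set into a primer pair.

    Returns one row per tag, in tag-set order, with the final oligos, trim
    lengths, screen scores, and a pass/flag column. Per-tag failures are
    recorded in the ``error`` column instead of aborting the batch. With
    ``exclude_flagged`` only structure-clean rows are kept (how a hairpin-free
    subset of tagged primers is selected for synthesis).
    """
    if len(tagset) == 0:
        raise ValueError(f"tag set {tagset.name!r} is empty")
    rows = []
    for tag in tagset:
        try:
            pair = tag_pair(tag, upper_primer, lower_primer, pigtail,
                            trim_common, min_stem, min_loop, screen)
            rows.append({
                "tag_name": tag.name,
                "tag": tag.sequence,
                "upper_oligo": pair.upper_oligo,
                "lower_oligo": pair.lower_oligo,
                "upper_trim": pair.upper_trim,
                "lower_trim": pair.lower_trim,
                "upper_hairpin": pair.upper_screen.hairpin_stem_len,
                "lower_hairpin": pair.lower_screen.hairpin_stem_len,
                "upper_self_dimer": pair.upper_screen.self_dimer_len,
                "lower_self_dimer": pair.lower_screen.self_dimer_len,
                "cross_dimer": pair.cross_dimer_len,
                "flagged": pair.flagged,
                "error": "",
            })
        except ValueError as exc:
            rows.append({
                "tag_name": tag.name, "tag": tag.sequence,
                "upper_oligo": "", "lower_oligo": "",
                "upper_trim": pd.NA, "lower_trim": pd.NA,
                "upper_hairpin": pd.NA, "lower_hairpin": pd.NA,
                "upper_self_dimer": pd.NA, "lower_self_dimer": pd.NA,
                "cross_dimer": pd.NA, "flagged": pd.NA,
                "error": str(exc),
            })
    table = pd.DataFrame(rows)
    if exclude_flagged:
        table = table[(table["error"] == "") & (table["flagged"] == False)]  # noqa: E712
        table = table.reset_index(drop=True)
    return table


def tag_adapter(five_prime_part: str, tag: Tag, three_prime_part: str) -> TaggedAdapter:
    """Insert a tag between the 5' and 3' parts of an adapter.

    Either part may be empty. The tag's 0-based half-open slice within the
    full sequence is recorded so the embedded tag can be extracted and
    re-validated later.
    """
    five = normalize_sequence(five_prime_part)
    three = normalize_sequence(three_prime_part)
    full = five + tag.sequence + three
    return TaggedAdapter(
        tag=tag,
        five_prime_part=five,
        three_prime_part=three,
        full_sequence=full,
        tag_slice=(len(five), len(five) + len(tag.sequence)),
    )
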