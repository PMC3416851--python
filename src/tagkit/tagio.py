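"""Read and write tag sets, and serialize validation reports.

Three on-disk dialects are supported:

``ini``
    One ``[section]`` per tag set with ``name:sequence`` lines; ``#`` starts
    a comment. This is the house format for collecting heterogeneous
    published sets under one roof.
``plain``
    One sequence per line; tags are auto-named ``Tag1..TagN`` in file order.
``fasta``
    Standard FASTA, single-line or wrapped sequences (read via Biopython).

Parsing then serializing then parsing again yields an identical tag set
(names, order, sequences) for every dialect.
"""

from __future__ import annotations

import configparser
import csv
import io
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagkit.core import InvalidAlphabetError, Tag, TagSet, normalize_sequence

if TYPE_CHECKING:  # pragma: no cover
    from tagkit.validate import DistanceReport

__all__ = ["detect_dialect", "read_tagset", "write_tagset", "write_report"]

DIALECTS = ("ini", "plain", "fasta")


def detect_dialect(path: str | Path) -> str:
    """Guess the dialect from the first non-blank, non-comment line.

    Leading ``>`` means FASTA; a ``[section]`` header means INI; anything
    else is treated as plain one-sequence-per-line text.
    """
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith(">"):
                return "fasta"
            if stripped.startswith("["):
                return "ini"
            return "plain"
    raise ValueError(f"empty tag file: {path}")


def _read_ini(path: Path, section: str | None) -> tuple[str, list[Tag]]:
    parser = configparser.ConfigParser(
        delimiters=(":", "="), comment_prefixes=("#", ";"), interpolation=None
    )
    parser.optionxform = str  # preserve tag-name case
    with open(path) as handle:
        parser.read_file(handle)
    sections = parser.sections()
    if not sections:
        raise ValueError(f"no [section] headers in ini tag file: {path}")
    if section is None:
        if len(sections) > 1:
            raise ValueError(
                f"{path} contains multiple sections {sections}; "
                f"pass section= to choose one"
            )
        section = sections[0]
    elif section not in sections:
        raise ValueError(f"section {section!r} not found in {path}; has {sections}")
    tags = []
    for name, seq in parser.items(section):
        try:
            tags.append(Tag(name, seq))
        except InvalidAlphabetError as exc:
            raise InvalidAlphabetError(f"{path} [{section}] {name}: {exc}") from None
    return section, tags


def _read_plain(path: Path) -> list[Tag]:
    tags = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            seq = line.strip()
            if not seq or seq.startswith("#"):
                continue
            try:
                tags.append(Tag(f"Tag{len(tags) + 1}", seq))
            except InvalidAlphabetError as exc:
                raise InvalidAlphabetError(f"{path}, line {lineno}: {exc}") from None
    return tags


def _read_fasta(path: Path) -> list[Tag]:
    tags = []
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            tags.append(Tag(record.id, str(record.seq)))
        except InvalidAlphabetError as exc:
            raise InvalidAlphabetError(f"{path}, record {record.id!r}: {exc}") from None
    return tags


def read_tagset(
    path: str | Path,
    dialect: str | None = None,
    metric: str = "edit",
    expected_min_distance: int = 1,
    section: str | None = None,
) -> TagSet:
    """Read a tag set from ``path``, auto-detecting the dialect if unset.

    Sequences are normalized to uppercase; duplicate names, empty files, and
    non-ACGT characters raise with the offending location named.
    """
    path = Path(path)
    if dialect is None:
        dialect = detect_dialect(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    name = path.stem
    if dialect == "ini":
        name, tags = _read_ini(path, section)
    elif dialect == "plain":
        tags = _read_plain(path)
    else:
        tags = _read_fasta(path)
    if not tags:
        raise ValueError(f"no tags found in {path} (dialect={dialect})")
    return TagSet(name=name, tags=tags, metric=metric,
                  expected_min_distance=expected_min_distance)


def write_tagset(tagset: TagSet, path: str | Path, dialect: str = "ini") -> None:
    """Serialize a tag set in the given dialect.

    Note the plain dialect stores no names: a round trip through it recovers
    the auto-generated ``Tag1..TagN`` names, not custom ones.
    """
    path = Path(path)
    if dialect == "ini":
        lines = [f"[{tagset.name}]"]
        lines += [f"{t.name}:{t.sequence}" for t in tagset]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "plain":
        path.write_text("\n".join(t.sequence for t in tagset) + "\n")
    elif dialect == "fasta":
        records = [
            SeqRecord(Seq(t.sequence), id=t.name, description="") for t in tagset
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def format_report_text(report: "DistanceReport") -> str:
    """Human-readable summary: observed minimum plus any violating pairs."""
    lines = [
        f"metric: {report.metric}",
        f"expected minimum distance: {report.expected_min_distance}",
        f"minimum distance: {report.observed_min_distance}",
        f"pair violations: {len(report.pair_violations)}",
    ]
    for a, b, dist in report.pair_violations:
        lines.append(f"{a},{b},{dist}")
    return "\n".join(lines) + "\n"


def format_report_csv(report: "DistanceReport") -> str:
    """Full pairwise matrix as CSV with tag names on both axes."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([""] + report.tag_names)
    for name, row in zip(report.tag_names, report.matrix):
        writer.writerow([name] + list(row))
    return buf.getvalue()


def write_report(report: "DistanceReport", path: str | Path, format: str = "text") -> None:
    """Write a validation report as ``text`` (min + violations) or ``csv`` (matrix)."""
    if format == "text":
        content = format_report_text(report)
    elif format == "csv":
        content = format_report_csv(report)
    else:
        raise ValueError(f"unknown report format {format!r}; expected 'csv' or 'text'")
    Path(path).write_text(content)
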