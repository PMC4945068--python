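"""Readers and writers for the pipeline's tabular formats.

All files are UTF-8, tab-separated. Every table carries a header row except
the alignment table, which follows the headerless 12-column convention of
tabular homology-search output (query, subject, % identity, alignment length,
mismatches, gap opens, q.start, q.end, s.start, s.end, e-value, bit score).
Because that layout lacks sequence lengths — needed by the catalog coverage
filter — lengths are supplied either through a companion two-column length
table or through an extended 14-column dialect with qlen/slen appended.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlignmentHit",
    "ConsistencyWarning",
    "GenomeRecord",
    "Habitat",
    "LocalizationProfile",
    "OrthologGroupAnnotation",
    "TableFormatError",
    "read_alignment_table",
    "read_alignment_table_lenient",
    "read_annotation_table",
    "read_genome_metadata",
    "read_length_table",
    "read_localization_table",
    "write_alignment_table",
    "write_annotation_table",
    "write_genome_metadata",
    "write_length_table",
    "write_localization_table",
]

#: COG-style single-letter functional category alphabet.
CATEGORY_ALPHABET = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


class TableFormatError(ValueError):
    """A tabular input violates its format contract (named line where known)."""


class ConsistencyWarning(UserWarning):
    """Input is accepted but internally inconsistent (e.g. counts vs total)."""


class Habitat(enum.Enum):
    GUT = "gut"
    NON_GUT = "non_gut"
    AMBIGUOUS = "ambiguous"
    UNLABELED = "unlabeled"

    @classmethod
    def from_label(cls, label: str, aliases: Mapping[str, str] | None = None) -> "Habitat":
        """Map a habitat string to an enum member.

        Only canonical names (and ``non-gut``/``nongut`` spellings) are
        accepted; anything else must be mapped through an explicit ``aliases``
        dict, otherwise a :class:`TableFormatError` is raised. This keeps
        environment metadata like "soil" from silently becoming a cohort.
        """
        text = label.strip()
        if aliases and text in aliases:
            text = aliases[text]
        key = text.lower().replace("-", "_").replace(" ", "_")
        for member in cls:
            if member.value == key:
                return member
        raise TableFormatError(f"unknown habitat label {label!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of tabular homology-search output.

    ``query_length``/``subject_length`` are None in the bare 12-column dialect
    unless a companion length table supplies them.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity {self.percent_identity} outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length {self.alignment_length} < 1")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score {self.bit_score}")
        for name in ("query_length", "subject_length"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome with its habitat attribution and proteome size."""

    genome_id: str
    habitat: Habitat
    total_proteins: int

    def __post_init__(self) -> None:
        if self.total_proteins < 1:
            raise ValueError(f"total_proteins must be >= 1, got {self.total_proteins}")


@dataclass(frozen=True)
class OrthologGroupAnnotation:
    """An ortholog group with its functional description and category letters."""

    nog_id: str
    description: str = ""
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = set(self.categories) - CATEGORY_ALPHABET
        if bad:
            raise ValueError(f"invalid functional category letters: {sorted(bad)}")


@dataclass(frozen=True)
class LocalizationProfile:
    """Per-genome predicted protein localization counts.

    pse/sec/cyto/mem: potentially surface exposed, secreted, cytoplasmic and
    membrane proteins; ``total`` is the proteome size. The component sum is
    allowed to disagree with ``total`` (a warning is emitted at read time)
    because published tables contain such rows; fraction computations always
    use the printed total.
    """

    genome_id: str
    pse: int
    sec: int
    cyto: int
    mem: int
    total: int

    def __post_init__(self) -> None:
        for name in ("pse", "sec", "cyto", "mem"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} count is negative ({v}) for {self.genome_id}")
            if v > self.total:
                raise ValueError(f"{name} count {v} exceeds total {self.total} for {self.genome_id}")
        if self.total < 1:
            raise ValueError(f"total must be >= 1 for {self.genome_id}")

    @property
    def component_sum(self) -> int:
        return self.pse + self.sec + self.cyto + self.mem


# ---------------------------------------------------------------------------
# alignment tables


_TWELVE = "twelve_column"
_EXTENDED = "extended_with_lengths"


def _parse_alignment_row(
    fields: Sequence[str],
    dialect: str,
    lengths: Mapping[str, int] | None,
    lineno: int,
) -> AlignmentHit:
    expected = 12 if dialect == _TWELVE else 14
    if len(fields) != expected:
        raise TableFormatError(f"line {lineno}: expected {expected} columns, found {len(fields)}")
    try:
        identity = float(fields[2])
        aln_len = int(fields[3])
        evalue = float(fields[10])
        bit_score = float(fields[11])
    except ValueError as exc:
        raise TableFormatError(f"line {lineno}: non-numeric field ({exc})") from None
    qlen = slen = None
    if dialect == _EXTENDED:
        try:
            qlen, slen = int(fields[12]), int(fields[13])
        except ValueError as exc:
            raise TableFormatError(f"line {lineno}: non-numeric length field ({exc})") from None
    elif lengths is not None:
        qlen = lengths.get(fields[0])
        slen = lengths.get(fields[1])
    try:
        return AlignmentHit(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=identity,
            alignment_length=aln_len,
            evalue=evalue,
            bit_score=bit_score,
            query_length=qlen,
            subject_length=slen,
        )
    except ValueError as exc:
        raise TableFormatError(f"line {lineno}: {exc}") from None


def read_alignment_table(
    path: str | Path,
    dialect: str = _TWELVE,
    lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Read a headerless tab-separated alignment table.

    ``dialect`` is ``"twelve_column"`` (lengths, if wanted, come from
    ``lengths``, typically :func:`read_length_table` output) or
    ``"extended_with_lengths"`` (two extra qlen/slen columns). Malformed rows
    raise :class:`TableFormatError` naming the offending line; use
    :func:`read_alignment_table_lenient` to collect them instead.
    """
    if dialect not in (_TWELVE, _EXTENDED):
        raise TableFormatError(f"unknown alignment dialect {dialect!r}")
    hits = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            hits.append(_parse_alignment_row(line.rstrip("\n").split("\t"), dialect, lengths, lineno))
    return hits


def read_alignment_table_lenient(
    path: str | Path,
    dialect: str = _TWELVE,
    lengths: Mapping[str, int] | None = None,
) -> tuple[list[AlignmentHit], list[tuple[int, str]]]:
    """Like :func:`read_alignment_table` but returns ``(hits, malformed)``.

    ``malformed`` holds ``(line_number, message)`` pairs; parsed + malformed
    always account for every non-blank input row.
    """
    if dialect not in (_TWELVE, _EXTENDED):
        raise TableFormatError(f"unknown alignment dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    malformed: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                hits.append(_parse_alignment_row(line.rstrip("\n").split("\t"), dialect, lengths, lineno))
            except TableFormatError as exc:
                malformed.append((lineno, str(exc)))
    return hits, malformed


def write_alignment_table(path: str | Path, hits: Iterable[AlignmentHit], dialect: str = _TWELVE) -> None:
    """Write hits in the headerless tabular layout.

    The 12-column dialect cannot carry lengths; positional columns the reader
    ignores (mismatches, gap opens, coordinates) are written as zeros.
    """
    if dialect not in (_TWELVE, _EXTENDED):
        raise TableFormatError(f"unknown alignment dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as handle:
        for h in hits:
            fields = [
                h.query_id,
                h.subject_id,
                format(h.percent_identity, "g"),
                str(h.alignment_length),
                "0", "0", "0", "0", "0", "0",
                format(h.evalue, "g"),
                format(h.bit_score, "g"),
            ]
            if dialect == _EXTENDED:
                if h.query_length is None or h.subject_length is None:
                    raise TableFormatError(f"hit {h.query_id}->{h.subject_id} lacks lengths for extended dialect")
                fields += [str(h.query_length), str(h.subject_length)]
            handle.write("\t".join(fields) + "\n")


def read_length_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``sequence_id <tab> length`` table (with header)."""
    lengths: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["sequence_id", "length"]:
            raise TableFormatError(f"length table header must be sequence_id/length, found {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise TableFormatError(f"line {lineno}: expected 2 columns, found {len(fields)}")
            try:
                length = int(fields[1])
            except ValueError:
                raise TableFormatError(f"line {lineno}: non-integer length {fields[1]!r}") from None
            if length < 1:
                raise TableFormatError(f"line {lineno}: non-positive length {length}")
            if fields[0] in lengths and lengths[fields[0]] != length:
                raise TableFormatError(f"line {lineno}: conflicting length for {fields[0]!r}")
            lengths[fields[0]] = length
    return lengths


def write_length_table(path: str | Path, lengths: Mapping[str, int]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("sequence_id\tlength\n")
        for seq_id, length in lengths.items():
            handle.write(f"{seq_id}\t{length}\n")


# ---------------------------------------------------------------------------
# genome metadata


def _read_header(handle, required: Sequence[str], path) -> list[str]:
    header = handle.readline().rstrip("\n").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return header


def read_genome_metadata(
    path: str | Path,
    habitat_aliases: Mapping[str, str] | None = None,
) -> list[GenomeRecord]:
    """Read genome_id / habitat_label / total_proteins records.

    Non-canonical habitat strings are rejected unless routed through an
    explicit ``habitat_aliases`` map; duplicate genome ids are an error.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        header = _read_header(handle, ["genome_id", "habitat_label", "total_proteins"], path)
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            genome_id = fields[idx["genome_id"]]
            if genome_id in seen:
                raise TableFormatError(f"line {lineno}: duplicate genome_id {genome_id!r}")
            seen.add(genome_id)
            try:
                total = int(fields[idx["total_proteins"]])
                record = GenomeRecord(
                    genome_id=genome_id,
                    habitat=Habitat.from_label(fields[idx["habitat_label"]], habitat_aliases),
                    total_proteins=total,
                )
            except (ValueError, TableFormatError) as exc:
                raise TableFormatError(f"line {lineno}: {exc}") from None
            records.append(record)
    return records


def write_genome_metadata(path: str | Path, records: Iterable[GenomeRecord]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("genome_id\thabitat_label\ttotal_proteins\n")
        for r in records:
            handle.write(f"{r.genome_id}\t{r.habitat.value}\t{r.total_proteins}\n")


# ---------------------------------------------------------------------------
# localization tables


def read_localization_table(path: str | Path) -> list[LocalizationProfile]:
    """Read per-genome localization counts.

    Rows whose four compartment counts do not sum to the printed total are
    accepted with a :class:`ConsistencyWarning` (published tables contain such
    rows); negative counts or missing columns are errors.
    """
    profiles: list[LocalizationProfile] = []
    with open(path, encoding="utf-8") as handle:
        header = _read_header(handle, ["genome_id", "pse", "sec", "cyto", "mem", "total"], path)
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                profile = LocalizationProfile(
                    genome_id=fields[idx["genome_id"]],
                    pse=int(fields[idx["pse"]]),
                    sec=int(fields[idx["sec"]]),
                    cyto=int(fields[idx["cyto"]]),
                    mem=int(fields[idx["mem"]]),
                    total=int(fields[idx["total"]]),
                )
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: {exc}") from None
            if profile.component_sum != profile.total:
                warnings.warn(
                    f"{profile.genome_id}: compartment counts sum to "
                    f"{profile.component_sum}, printed total is {profile.total}",
                    ConsistencyWarning,
                    stacklevel=2,
                )
            profiles.append(profile)
    return profiles


def write_localization_table(path: str | Path, profiles: Iterable[LocalizationProfile]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("genome_id\tpse\tsec\tcyto\tmem\ttotal\n")
        for p in profiles:
            handle.write(f"{p.genome_id}\t{p.pse}\t{p.sec}\t{p.cyto}\t{p.mem}\t{p.total}\n")


# ---------------------------------------------------------------------------
# ortholog-group annotation tables


def read_annotation_table(path: str | Path) -> list[OrthologGroupAnnotation]:
    """Read nog_id / description / categories rows.

    ``categories`` is a string of concatenated single letters (may be empty);
    descriptions may be empty. Duplicate nog ids are an error.
    """
    annotations: list[OrthologGroupAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        header = _read_header(handle, ["nog_id", "description", "categories"], path)
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            nog_id = fields[idx["nog_id"]]
            if nog_id in seen:
                raise TableFormatError(f"line {lineno}: duplicate nog_id {nog_id!r}")
            seen.add(nog_id)
            try:
                annotations.append(
                    OrthologGroupAnnotation(
                        nog_id=nog_id,
                        description=fields[idx["description"]],
                        categories=frozenset(fields[idx["categories"]]),
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: {exc}") from None
    return annotations


def write_annotation_table(path: str | Path, annotations: Iterable[OrthologGroupAnnotation]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("nog_id\tdescription\tcategories\n")
        for a in annotations:
            handle.write(f"{a.nog_id}\t{a.description}\t{''.join(sorted(a.categories))}\n")
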