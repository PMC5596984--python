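"""Aligned-sequence and group-assignment input/output.

This module owns the two data containers everything downstream consumes — an
:class:`Alignment` (equal-length nucleotide records keyed by sample id, e.g.
a 658-bp COI barcode alignment) and a :class:`GroupingMap` (sample → group
label, where a group is a taxon or a haplogroup) — plus the
:class:`SitePolicy` that states how gaps and IUPAC ambiguity codes enter the
site-wise statistics.

Residues are normalized on ingestion: upper-case, ``U`` → ``T`` and ``?`` →
``N``, because barcode records arriving from BOLD/GenBank mix these
conventions. Sites are 0-based internally and 1-based in human-facing
output.
"""

from __future__ import annotations

import sys
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Errors

class BarcodivError(Exception):
    """Base class for all package errors."""


class AlignmentError(BarcodivError):
    """Records do not form a valid alignment (ragged lengths, bad residues)."""


class InputError(BarcodivError):
    """Malformed or inconsistent user input (duplicate ids, empty files...)."""


class SampleLookupError(BarcodivError, KeyError):
    """A referenced sample id or group label does not exist."""


class UndefinedDistanceError(BarcodivError):
    """A pairwise distance has zero comparable sites."""


# ---------------------------------------------------------------------------
# Residue alphabet

#: IUPAC nucleotide codes accepted after normalization.
UNAMBIGUOUS = frozenset("ACGT")
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")
MISSING = frozenset("N-")
VALID_RESIDUES = UNAMBIGUOUS | AMBIGUITY_CODES | MISSING

_NORMALIZE = str.maketrans({"U": "T", "u": "T", "?": "N"})


def normalize_residues(raw: str) -> str:
    """Upper-case a residue string and map ``U``→``T``, ``?``→``N``.

    Raises :class:`AlignmentError` on any character outside the IUPAC
    nucleotide alphabet plus ``N`` and ``-``.
    """
    seq = raw.translate(_NORMALIZE).upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise AlignmentError(
            f"invalid residue(s) {sorted(bad)!r}; expected IUPAC nucleotide "
            "codes, 'N' or '-'"
        )
    return seq


# ---------------------------------------------------------------------------
# Site policy

@dataclass(frozen=True)
class SitePolicy:
    """How masked residues enter site-wise statistics.

    mode
        ``pairwise_deletion`` drops, for each pair of sequences, only the
        sites masked in that pair; ``complete_deletion`` drops a site for
        the whole computation if it is masked in any participating record.
    ambiguity
        ``treat_as_missing`` masks IUPAC ambiguity codes like ``N``;
        ``strict_mismatch`` keeps them as comparable states that never
        match any residue, themselves included.

    The default (pairwise deletion, ambiguities as missing) is the de-facto
    standard of barcoding distance software.
    """

    mode: str = "pairwise_deletion"
    ambiguity: str = "treat_as_missing"

    def __post_init__(self) -> None:
        if self.mode not in ("pairwise_deletion", "complete_deletion"):
            raise InputError(f"unknown deletion mode {self.mode!r}")
        if self.ambiguity not in ("treat_as_missing", "strict_mismatch"):
            raise InputError(f"unknown ambiguity setting {self.ambiguity!r}")

    def masked(self, residue: str) -> bool:
        """True if *residue* is excluded from comparable sites."""
        if residue in MISSING:
            return True
        return self.ambiguity == "treat_as_missing" and residue in AMBIGUITY_CODES


DEFAULT_POLICY = SitePolicy()


# ---------------------------------------------------------------------------
# Alignment

@dataclass
class Alignment:
    """Equal-length nucleotide records keyed by unique sample id.

    ``records`` preserves input order; every statistic in the package is
    computed on this container.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {sid: len(seq) for sid, seq in self.records.items()}
        distinct = set(lengths.values())
        if len(distinct) > 1:
            ref_id = next(iter(lengths))
            offender = next(
                sid for sid, n in lengths.items() if n != lengths[ref_id]
            )
            raise AlignmentError(
                f"ragged alignment: record {offender!r} has length "
                f"{lengths[offender]}, expected {lengths[ref_id]} "
                f"(as in {ref_id!r})"
            )
        if 0 in distinct:
            raise AlignmentError("alignment length must be positive")
        for sid in self.records:
            if not sid:
                raise AlignmentError("empty sample id")

    @property
    def length(self) -> int:
        """Number of aligned sites L."""
        return len(next(iter(self.records.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> str:
        try:
            return self.records[sample_id]
        except KeyError:
            raise SampleLookupError(f"unknown sample id {sample_id!r}") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.records


def restrict(alignment: Alignment, ids: Sequence[str]) -> Alignment:
    """Sub-alignment containing *ids* in the given order; same length L."""
    if not ids:
        raise InputError("empty sample selection")
    missing = [sid for sid in ids if sid not in alignment]
    if missing:
        raise SampleLookupError(f"unknown sample id(s): {missing!r}")
    return Alignment({sid: alignment.records[sid] for sid in ids})


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    The record id is the first whitespace-delimited token of the header
    (BOLD process ids appear that way); the rest of the description is
    dropped. Residues are normalized (see :func:`normalize_residues`).
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise InputError(f"{path}: record with empty id")
        if rec.id in records:
            raise InputError(f"{path}: duplicate sample id {rec.id!r}")
        try:
            records[rec.id] = normalize_residues(str(rec.seq))
        except AlignmentError as exc:
            raise AlignmentError(f"{path}: record {rec.id!r}: {exc}") from None
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    try:
        return Alignment(records)
    except AlignmentError as exc:
        raise AlignmentError(f"{path}: {exc}") from None


def write_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    """Write the alignment as wrapped FASTA, preserving record order."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment.records.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Grouping map

@dataclass
class GroupingMap:
    """Sample → group label assignments (taxa or haplogroups).

    ``group_order`` follows first appearance. Groups with a single member
    are legal but trigger a warning for fixed-site logic, where a singleton
    is trivially invariant.
    """

    assignments: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise InputError("grouping map has no assignments")
        seen: list[str] = []
        for sid, label in self.assignments.items():
            if not label:
                raise InputError(f"blank group label for sample {sid!r}")
            if label not in seen:
                seen.append(label)
        if not self.group_order:
            self.group_order = seen
        elif set(self.group_order) != set(seen):
            raise InputError("group_order does not match assigned labels")

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group label → member sample ids, in assignment order."""
        out: dict[str, list[str]] = {g: [] for g in self.group_order}
        for sid, label in self.assignments.items():
            out[label].append(sid)
        return out

    def members(self, label: str) -> list[str]:
        if label not in self.group_order:
            raise SampleLookupError(f"unknown group label {label!r}")
        return [s for s, g in self.assignments.items() if g == label]

    def __getitem__(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise SampleLookupError(f"sample {sample_id!r} not in grouping") from None

    def check_against(self, alignment: Alignment) -> None:
        """Require every assigned sample to exist in *alignment*."""
        missing = [s for s in self.assignments if s not in alignment]
        if missing:
            raise SampleLookupError(
                f"grouped sample(s) absent from alignment: {missing!r}"
            )


def read_grouping(path: str | Path, header: bool = False) -> GroupingMap:
    """Read a two-column tab-delimited ``sample_id<TAB>group`` table.

    Lines starting with ``#`` are comments; *header* skips the first
    non-comment line. Re-listing a sample with the same group is tolerated;
    a conflicting re-listing is an error.
    """
    path = Path(path)
    assignments: dict[str, str] = {}
    skipped_header = not header
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not skipped_header:
                skipped_header = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            sid, label = parts[0].strip(), parts[1].strip()
            if not sid:
                raise InputError(f"{path}:{lineno}: empty sample id")
            if not label:
                raise InputError(f"{path}:{lineno}: blank group label")
            if sid in assignments and assignments[sid] != label:
                raise InputError(
                    f"{path}:{lineno}: sample {sid!r} listed with conflicting "
                    f"groups {assignments[sid]!r} and {label!r}"
                )
            assignments[sid] = label
    if not assignments:
        raise InputError(f"{path}: no assignments found")
    return GroupingMap(assignments)


def write_grouping(grouping: GroupingMap, path: str | Path) -> None:
    with open(path, "w") as handle:
        for sid, label in grouping.assignments.items():
            handle.write(f"{sid}\t{label}\n")


def warn_singletons(grouping: GroupingMap, labels: Iterable[str]) -> None:
    """Warn on stderr for groups of size 1 entering fixed-site logic."""
    groups = grouping.groups
    for label in labels:
        if len(groups.get(label, [])) == 1:
            print(
                f"warning: group {label!r} has a single member; it is "
                "trivially invariant at every site",
                file=sys.stderr,
            )
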