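"""Readers and writers for RNA sequences and interaction edge lists.

Supported dialects are deliberately narrow: plain (uncompressed) FASTA over
the {A,C,G,U} alphabet after normalization, and 2-3 column tab-separated
edge lists.  Anything outside the dialect is an error, never silently
coerced.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "RnaSequence",
    "InteractionTable",
    "read_fasta",
    "write_fasta",
    "read_interactions",
    "write_interactions",
]

RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates the supported dialect."""


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA string with a type tag.

    ``seq`` is always the normalized form: uppercase, T replaced by U.
    """

    id: str
    seq: str
    rna_type: str = "lncRNA"  # "lncRNA" | "miRNA"

    def __post_init__(self):
        if not self.id:
            raise FormatError("empty sequence identifier")
        if self.rna_type not in ("lncRNA", "miRNA"):
            raise ValueError(f"unknown rna_type {self.rna_type!r}")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(sequences must be over A/C/G/U; ambiguity codes such as N "
                "are rejected)"
            )
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


def normalize_seq(raw: str) -> str:
    """Uppercase and map DNA T to RNA U.  Validation happens downstream."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path, rna_type: str = "lncRNA") -> list[RnaSequence]:
    """Parse a FASTA file into normalized :class:`RnaSequence` records.

    Record ids are the first whitespace-delimited token of the header.
    Duplicate ids, empty files and non-ACGU(T/N) characters are errors;
    records containing N are rejected outright.
    """
    path = Path(path)
    records: list[RnaSequence] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = normalize_seq("".join(chunks))
        if "N" in seq:
            raise FormatError(
                f"record {header!r} contains ambiguity code N; "
                "ambiguous bases are not supported"
            )
        rec = RnaSequence(id=header, seq=seq, rna_type=rna_type)
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(rec)

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"empty FASTA header in {path}")
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"sequence data before first header in {path}")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[RnaSequence], path: str | Path,
                width: int = 70) -> None:
    """Write records in input order, wrapping sequence lines at ``width``."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


@dataclass
class InteractionTable:
    """Deduplicated (lncRNA, miRNA, label) pairs with stable id orderings."""

    pairs: list[tuple[str, str, int]]
    lnc_ids: list[str] = field(default_factory=list)
    mi_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str, int]],
                   lnc_ids: Sequence[str] | None = None,
                   mi_ids: Sequence[str] | None = None) -> "InteractionTable":
        """Build a table, deduplicating pairs and deriving id orderings.

        Explicit id lists may extend beyond the ids present in ``pairs``
        (entities with no known interaction are legal graph nodes).
        """
        seen: set[tuple[str, str]] = set()
        dedup: list[tuple[str, str, int]] = []
        for lnc, mi, label in pairs:
            if lnc == mi:
                raise FormatError(f"self-pair with identical id {lnc!r}")
            if int(label) not in (0, 1):
                raise FormatError(f"label must be 0/1, got {label!r}")
            key = (lnc, mi)
            if key in seen:
                continue
            seen.add(key)
            dedup.append((lnc, mi, int(label)))
        if lnc_ids is None:
            lnc_ids = list(dict.fromkeys(p[0] for p in dedup))
        else:
            lnc_ids = list(lnc_ids)
        if mi_ids is None:
            mi_ids = list(dict.fromkeys(p[1] for p in dedup))
        else:
            mi_ids = list(mi_ids)
        if len(set(lnc_ids)) != len(lnc_ids) or len(set(mi_ids)) != len(mi_ids):
            raise FormatError("duplicate entries in id lists")
        collisions = set(lnc_ids) & set(mi_ids)
        if collisions:
            raise FormatError(f"ids used for both types: {sorted(collisions)}")
        known_lnc, known_mi = set(lnc_ids), set(mi_ids)
        for lnc, mi, _ in dedup:
            if lnc not in known_lnc or mi not in known_mi:
                raise FormatError(f"pair ({lnc!r}, {mi!r}) references unknown id")
        return cls(pairs=dedup, lnc_ids=lnc_ids, mi_ids=mi_ids)

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_ids)

    @property
    def n_mi(self) -> int:
        return len(self.mi_ids)

    @property
    def positives(self) -> list[tuple[str, str]]:
        return [(l, m) for l, m, y in self.pairs if y == 1]


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a 2-3 column TSV edge list (lnc_id, mi_id[, label]).

    A missing label column means label 1 (verified positive).  Malformed
    rows raise with their line number; duplicates are dropped keeping the
    first occurrence.
    """
    path = Path(path)
    raw: list[tuple[str, str, int]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns, got {len(row)}")
            lnc, mi = row[0].strip(), row[1].strip()
            if not lnc or not mi:
                raise FormatError(f"{path}:{lineno}: empty identifier")
            label = 1
            if len(row) >= 3 and row[2].strip():
                try:
                    label = int(row[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer label {row[2]!r}") from None
            if lnc == mi:
                raise FormatError(f"{path}:{lineno}: self-pair {lnc!r}")
            raw.append((lnc, mi, label))
    if not raw:
        raise FormatError(f"no interaction rows found in {path}")
    return InteractionTable.from_pairs(raw)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lnc, mi, label in table.pairs:
            fh.write(f"{lnc}\t{mi}\t{label}\n")
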