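"""Protein sequence I/O with species provenance.

Reads and writes amino-acid FASTA, validates the alphabet (20 standard
residues plus ``U`` for selenocysteine and ``X`` for unknown), and collapses
exact sequence duplicates within a species.  Selenocysteine is never
translated to cysteine here: the Sec/Cys distinction is itself a
classification output downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: 20 standard residues + selenocysteine (U) + unknown (X)
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = STANDARD_AA | {"U", "X"}


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class SequenceValidationError(ValueError):
    """A record violated the amino-acid alphabet or id constraints."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with species provenance."""

    protein_id: str
    species_id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.protein_id or any(c.isspace() for c in self.protein_id):
            raise SequenceValidationError(
                f"protein_id {self.protein_id!r} is empty or contains whitespace"
            )
        if len(self.sequence) < 1:
            raise SequenceValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise SequenceValidationError(
                f"{self.protein_id}: illegal residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DedupReport:
    """Result of exact-duplicate collapsing within species.

    ``duplicate_counts`` maps each retained protein_id to the number of
    *additional* identical sequences that were collapsed into it, mirroring
    the superscript convention of gene-census tables.
    """

    unique_records: list[ProteinRecord] = field(default_factory=list)
    duplicate_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_input(self) -> int:
        return len(self.unique_records) + sum(self.duplicate_counts.values())


def _clean_sequence(protein_id: str, raw: str, lenient: bool) -> str:
    seq = raw.strip().upper()
    # predicted proteomes commonly carry terminal stop characters
    seq = seq.strip("*")
    if "*" in seq:
        raise SequenceValidationError(
            f"{protein_id}: internal stop character '*' (broken gene model?)"
        )
    if "-" in seq or "." in seq:
        raise SequenceValidationError(f"{protein_id}: gap characters in sequence")
    if lenient:
        seq = "".join(c if c in VALID_AA else "X" for c in seq)
    return seq


def read_fasta(
    path: str | Path,
    species_id: str | None = None,
    lenient: bool = False,
) -> list[ProteinRecord]:
    """Read one proteome FASTA into :class:`ProteinRecord` objects.

    Species provenance precedence: explicit ``species_id`` argument (as set
    by a manifest) first, then the filename stem.  ``U`` is preserved
    verbatim.  In strict mode (default) an illegal residue raises
    :class:`SequenceValidationError`; ``lenient=True`` maps unknown residues
    to ``X`` instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sp = species_id if species_id is not None else path.stem
    _prevalidate_fasta(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(entry.id, str(entry.seq), lenient)
        records.append(
            ProteinRecord(
                protein_id=entry.id,
                species_id=sp,
                sequence=seq,
                description=entry.description,
            )
        )
    if not records:
        warnings.warn(f"{path}: no FASTA entries found", stacklevel=2)
    return records


def _prevalidate_fasta(path: Path) -> None:
    """Cheap structural check so errors carry a line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: expected '>' header before sequence data", line=i
                )
            return  # first meaningful line is a header; hand off to Bio.SeqIO


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapped at ``wrap`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}")
            desc = rec.description
            if desc and desc != rec.protein_id:
                # Bio.SeqIO stores "id rest..." in description; avoid doubling
                if desc.startswith(rec.protein_id + " "):
                    desc = desc[len(rec.protein_id) + 1 :]
                    fh.write(f" {desc}")
                elif desc != rec.protein_id:
                    fh.write(f" {desc}")
            fh.write("\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_manifest(path: str | Path) -> dict[str, Path]:
    """Read a two-column TSV manifest: species_id <TAB> fasta path.

    Relative paths resolve against the manifest's directory.  The manifest
    is authoritative for species assignment.
    """
    path = Path(path)
    out: dict[str, Path] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FastaParseError(
                    f"{path}: manifest rows need exactly 2 tab-separated fields",
                    line=i,
                )
            sp, p = parts
            fp = Path(p)
            if not fp.is_absolute():
                fp = path.parent / fp
            out[sp] = fp
    return out


def read_proteomes(manifest: str | Path, lenient: bool = False) -> list[ProteinRecord]:
    """Read every proteome listed in a species manifest."""
    records: list[ProteinRecord] = []
    for sp, fp in read_manifest(manifest).items():
        records.extend(read_fasta(fp, species_id=sp, lenient=lenient))
    return records


def dedupe_exact(records: Sequence[ProteinRecord]) -> DedupReport:
    """Collapse exact sequence duplicates within each species.

    Groups by (species_id, sequence string); the lexicographically smallest
    protein_id of each group is retained, so the result is deterministic
    regardless of input order.  Counts conserve:
    ``len(unique) + sum(duplicate_counts.values()) == len(records)``.
    """
    groups: dict[tuple[str, str], list[ProteinRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species_id, rec.sequence), []).append(rec)
    unique: list[ProteinRecord] = []
    dup_counts: dict[str, int] = {}
    for members in groups.values():
        keeper = min(members, key=lambda r: r.protein_id)
        unique.append(keeper)
        if len(members) > 1:
            dup_counts[keeper.protein_id] = len(members) - 1
    # keep original (then id) order stable for reporting
    order = {rec.protein_id: i for i, rec in enumerate(records)}
    unique.sort(key=lambda r: order[r.protein_id])
    return DedupReport(unique_records=unique, duplicate_counts=dup_counts)
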