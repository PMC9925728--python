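"""GPX reference data: catalytic-tetrad typing and subfamily group references.

GPX classification is phylogenetic: queries are placed against a labelled
reference set spanning the four animal GPX evolutionary groups (GPX1/2,
GPX3/5/6, GPX4/PHGPX, GPX7/8).  The catalytic tetrad (Sec/Cys, Gln, Trp,
Asn) is located by globally aligning the query's GSHPx region to a
reference sequence with annotated tetrad positions; the residue at the
first tetrad role decides selenium- vs cysteine-dependent catalysis.

The bundled reference sequence, group consensi, and reference alignment are
*synthetic* stand-ins (built by :func:`build_reference_data` from a fixed
seed); users with curated GPX references should substitute their own files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import ProteinRecord
from . import motifs

GPX_GROUPS = ("GPX1/2", "GPX3/5/6", "GPX4/PHGPX", "GPX7/8")

#: tetrad role order: catalytic Sec/Cys first, then Gln, Trp, Asn
TETRAD_ROLES = ("UC", "Q", "W", "N")

SELENIUM = "selenium-dependent"
CYSTEINE = "cysteine-dependent"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class TetradReference:
    """Reference sequence with annotated 1-based tetrad positions."""

    sequence: str
    positions: Mapping[str, int]  # role -> 1-based position


@dataclass(frozen=True)
class TetradCall:
    """Residues resolved at the four tetrad roles plus the catalysis type."""

    residues: Mapping[str, str | None]
    catalysis: str
    reason: str = ""
    coverage: float = 0.0


def _data_text(filename: str) -> str:
    return resources.files("peroxfam.data").joinpath(filename).read_text()


def load_tetrad_reference(path: str | Path | None = None) -> TetradReference:
    raw = json.loads(_data_text("gpx_reference.json") if path is None else Path(path).read_text())
    return TetradReference(sequence=raw["sequence"], positions={k: int(v) for k, v in raw["positions"].items()})


def load_gpx_group_consensi(path: str | Path | None = None) -> dict[str, str]:
    raw = json.loads(_data_text("gpx_groups.json") if path is None else Path(path).read_text())
    return {k: v for k, v in raw.items() if not k.startswith("_")}


def load_reference_alignment(
    fasta_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Bundled labelled GPX reference alignment: ([(id, row)], id -> group)."""
    if fasta_path is None:
        text = _data_text("gpx_reference_alignment.fasta")
    else:
        text = Path(fasta_path).read_text()
    rows: list[tuple[str, str]] = []
    rid, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if rid is not None:
                rows.append((rid, "".join(chunks)))
            rid, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if rid is not None:
        rows.append((rid, "".join(chunks)))
    if labels_path is None:
        ltext = _data_text("gpx_reference_labels.tsv")
    else:
        ltext = Path(labels_path).read_text()
    labels: dict[str, str] = {}
    for line in ltext.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pid, label = line.split("\t")
        labels[pid] = label
    return rows, labels


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def gpx_tetrad(
    record: ProteinRecord,
    region: tuple[int, int] | None = None,
    reference: TetradReference | None = None,
    min_coverage: float = 0.5,
) -> TetradCall:
    """Locate the GPX catalytic tetrad and type the catalysis.

    The query (its GSHPx region when given) is globally aligned to the
    annotated reference; reference tetrad positions map through the
    alignment to query residues.  Selenocysteine ``U`` is scored as ``C``
    during alignment but reported verbatim: ``U`` at the first role means
    selenium-dependent, ``C`` cysteine-dependent, anything else (or a
    deleted/unaligned position, or reference coverage below
    ``min_coverage``) leaves the type undetermined.
    """
    if reference is None:
        reference = load_tetrad_reference()
    if region is not None:
        lo, hi = region
        if not (1 <= lo <= hi <= len(record.sequence)):
            raise motifs.RegionError(f"region {region} outside {record.protein_id}")
        query = record.sequence[lo - 1 : hi]
        q_offset = lo - 1
    else:
        query = record.sequence
        q_offset = 0
    aligner = _make_aligner()
    # BLOSUM62 has no U column; align a Cys-masked copy, report originals
    ref_masked = reference.sequence.replace("U", "C")
    query_masked = query.replace("U", "C")
    alignment = aligner.align(ref_masked, query_masked)[0]
    ref_to_query: dict[int, int] = {}
    ref_blocks, query_blocks = alignment.aligned
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        for k in range(re_ - rs):
            ref_to_query[rs + k] = qs + k
    coverage = len(ref_to_query) / len(reference.sequence)
    residues: dict[str, str | None] = {}
    for role in TETRAD_ROLES:
        rpos0 = reference.positions[role] - 1
        qpos0 = ref_to_query.get(rpos0)
        residues[role] = None if qpos0 is None else record.sequence[q_offset + qpos0]
    if coverage < min_coverage:
        return TetradCall(residues=residues, catalysis=UNDETERMINED,
                          reason=f"reference coverage {coverage:.2f} < {min_coverage}",
                          coverage=coverage)
    first = residues["UC"]
    if first == "U":
        catalysis = SELENIUM
    elif first == "C":
        catalysis = CYSTEINE
    else:
        return TetradCall(residues=residues, catalysis=UNDETERMINED,
                          reason=f"catalytic slot holds {first!r}", coverage=coverage)
    return TetradCall(residues=residues, catalysis=catalysis, coverage=coverage)


# --- synthetic reference construction --------------------------------------

_REFERENCE_LENGTH = 120
_TETRAD_POSITIONS = {"UC": 40, "Q": 70, "W": 95, "N": 100}
_GROUP_DIVERGENCE = 0.25   # per-site mutation rate base -> group consensus
_MEMBER_DIVERGENCE = 0.04  # per-site mutation rate consensus -> reference member
_STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            frozen: Sequence[int] = ()) -> str:
    """Point-mutate each non-frozen position with probability ``rate``."""
    frozen_set = set(frozen)
    out = list(seq)
    for i in range(len(out)):
        if (i + 1) in frozen_set:
            continue
        if rng.random() < rate:
            choices = [a for a in _STANDARD if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _sanitized_random_sequence(length: int, rng: np.random.Generator) -> str:
    seq = "".join(_STANDARD[rng.integers(20)] for _ in range(length))
    return motifs_break(seq)


def motifs_break(seq: str) -> str:
    """Remove accidental occurrences of every bundled strict pattern."""
    patterns = list(motifs.BUNDLED_PATTERNS.values())
    return motifs.break_accidental_matches(seq, patterns)


def build_reference_data(outdir: str | Path, seed: int = 1905) -> None:
    """Regenerate the bundled synthetic GPX reference files.

    Writes ``gpx_reference.json`` (tetrad-annotated reference),
    ``gpx_groups.json`` (per-group consensi; Sec at the catalytic slot for
    all groups except the exclusively cysteine-dependent GPX7/8), and the
    labelled reference alignment FASTA/TSV.  Deterministic from ``seed``.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    frozen = list(_TETRAD_POSITIONS.values())
    base = list(_sanitized_random_sequence(_REFERENCE_LENGTH, rng))
    base[_TETRAD_POSITIONS["UC"] - 1] = "C"
    base[_TETRAD_POSITIONS["Q"] - 1] = "Q"
    base[_TETRAD_POSITIONS["W"] - 1] = "W"
    base[_TETRAD_POSITIONS["N"] - 1] = "N"
    base = "".join(base)

    ref_seq = list(base)
    ref_seq[_TETRAD_POSITIONS["UC"] - 1] = "U"
    (outdir / "gpx_reference.json").write_text(json.dumps({
        "_comment": "Synthetic tetrad-annotated GPX reference (not a natural sequence).",
        "sequence": "".join(ref_seq),
        "positions": _TETRAD_POSITIONS,
    }, indent=2) + "\n")

    consensi: dict[str, str] = {}
    for group in GPX_GROUPS:
        cons = list(_mutate(base, _GROUP_DIVERGENCE, rng, frozen=frozen))
        cons[_TETRAD_POSITIONS["UC"] - 1] = "C" if group == "GPX7/8" else "U"
        consensi[group] = motifs.break_accidental_matches(
            "".join(cons), list(motifs.BUNDLED_PATTERNS.values()),
            protected=[(p, p) for p in frozen],
        )
    (outdir / "gpx_groups.json").write_text(json.dumps(
        {"_comment": "Synthetic per-group GPX consensi; tetrad positions as in gpx_reference.json.",
         **consensi}, indent=2) + "\n")

    fasta_lines, label_lines = [], []
    for group in GPX_GROUPS:
        tag = group.replace("/", "").replace("GPX", "G")
        for i in range(6):
            member = _mutate(consensi[group], _MEMBER_DIVERGENCE, rng, frozen=frozen)
            rid = f"REF_{tag}_{i+1}"
            fasta_lines.append(f">{rid}\n{member}")
            label_lines.append(f"{rid}\t{group}")
    (outdir / "gpx_reference_alignment.fasta").write_text("\n".join(fasta_lines) + "\n")
    (outdir / "gpx_reference_labels.tsv").write_text("\n".join(label_lines) + "\n")
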