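"""Pfam domain-hit handling and family-level architecture rules.

The pipeline is hit-table-driven: per-domain tabular output from a
profile-HMM scanner (HMMER3 ``--domtblout`` dialect) is parsed into
:class:`DomainHit` intervals, thresholded, and matched against per-family
presence rules:

* CAT — both catalase (PF00199) and catalase_rel (PF06628);
* PRX — PF00578 plus at least one of PF08534 / PF10417 (relaxable);
* GPX — GSHPx (PF00255);
* SRX — ParB-like nuclease domain (PF02195).

Envelope coordinates define the domain interval (1-based inclusive).
Multiple hits of one accession on a protein count once for presence logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class DomtbloutParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class RuleConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit interval on a protein (1-based inclusive)."""

    protein_id: str
    accession: str
    domain_name: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise DomtbloutParseError(
                f"{self.protein_id}/{self.accession}: bad interval "
                f"{self.start}-{self.end}"
            )
        if self.evalue < 0:
            raise DomtbloutParseError(
                f"{self.protein_id}/{self.accession}: negative e-value"
            )


@dataclass(frozen=True)
class ArchitectureRule:
    """Presence logic for one family.

    ``require_all``: every accession must be present.
    ``require_any``: at least one must be present; empty set is vacuously
    satisfied.
    """

    family: str
    require_all: frozenset[str]
    require_any: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.require_all & self.require_any:
            raise RuleConfigError(
                f"{self.family}: require_all and require_any overlap"
            )

    def satisfied_by(self, accessions: set[str]) -> bool:
        if not self.require_all <= accessions:
            return False
        return (not self.require_any) or bool(self.require_any & accessions)


FAMILIES = ("CAT", "PRX", "GPX", "SRX")

#: Pfam accessions used by the bundled rules
PF_CATALASE = "PF00199"
PF_CATALASE_REL = "PF06628"
PF_PRX = "PF00578"       # AhpC-TSA / thioredoxin-fold peroxidase domain
PF_AHPC_TSA = "PF08534"  # labelled AhpC-TSA in some sources (see rules docs)
PF_1CYSPRX_C = "PF10417"
PF_GSHPX = "PF00255"
PF_PARBC = "PF02195"


def default_rules(prx_any_optional: bool = False) -> dict[str, ArchitectureRule]:
    """Bundled per-family architecture rules.

    ``prx_any_optional=True`` relaxes the PRX auxiliary-domain requirement
    (PF08534/PF10417) from required-any to optional, for users who want the
    core peroxidase domain alone to nominate.
    """
    prx_any = frozenset() if prx_any_optional else frozenset({PF_AHPC_TSA, PF_1CYSPRX_C})
    return {
        "CAT": ArchitectureRule("CAT", frozenset({PF_CATALASE, PF_CATALASE_REL})),
        "PRX": ArchitectureRule("PRX", frozenset({PF_PRX}), prx_any),
        "GPX": ArchitectureRule("GPX", frozenset({PF_GSHPX})),
        "SRX": ArchitectureRule("SRX", frozenset({PF_PARBC})),
    }


def _strip_version(acc: str) -> str:
    return acc.split(".")[0] if acc.startswith("PF") else acc


def parse_domtblout(path: str | Path, orientation: str = "auto") -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into :class:`DomainHit` rows.

    ``orientation`` selects which side of the table is the protein:
    ``"hmmscan"`` (target = Pfam model, query = protein), ``"hmmsearch"``
    (target = protein, query = Pfam model), or ``"auto"`` to detect per row
    from which accession column looks like a Pfam accession.  Envelope
    coordinates (columns 20-21) become start/end; the independent (per
    domain) e-value and per-domain bit score are retained.
    """
    if orientation not in ("auto", "hmmscan", "hmmsearch"):
        raise RuleConfigError(f"unknown orientation {orientation!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise DomtbloutParseError(
                    f"{path}: domtblout row has {len(parts)} fields, need >= 22",
                    line=lineno,
                )
            try:
                mode = orientation
                if mode == "auto":
                    if parts[1].startswith("PF"):
                        mode = "hmmscan"
                    elif parts[4].startswith("PF"):
                        mode = "hmmsearch"
                    else:  # fall back to hmmscan convention
                        mode = "hmmscan"
                if mode == "hmmscan":
                    domain_name, accession = parts[0], parts[1]
                    protein_id = parts[3]
                else:
                    protein_id = parts[0]
                    domain_name, accession = parts[3], parts[4]
                ievalue = float(parts[12])
                score = float(parts[13])
                env_from, env_to = int(parts[19]), int(parts[20])
            except ValueError as exc:
                raise DomtbloutParseError(f"{path}: {exc}", line=lineno) from None
            if env_from > env_to:
                raise DomtbloutParseError(
                    f"{path}: inverted envelope {env_from}>{env_to}", line=lineno
                )
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    accession=_strip_version(accession),
                    domain_name=domain_name,
                    start=env_from,
                    end=env_to,
                    score=score,
                    evalue=ievalue,
                )
            )
    return hits


def filter_hits(
    hits: Sequence[DomainHit],
    max_evalue: float = 1e-5,
    min_score: float | None = None,
) -> list[DomainHit]:
    """Keep hits with e-value <= ``max_evalue`` and (if set) score >= ``min_score``.

    Order is preserved.  ``max_evalue=math.inf`` is the identity filter.
    """
    if max_evalue < 0:
        raise RuleConfigError("max_evalue must be non-negative")
    if min_score is not None and math.isnan(min_score):
        raise RuleConfigError("min_score must be a number")
    out = []
    for h in hits:
        if h.evalue > max_evalue:
            continue
        if min_score is not None and h.score < min_score:
            continue
        out.append(h)
    return out


def group_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return grouped


def apply_architecture_rule(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    rule: ArchitectureRule,
) -> set[str]:
    """Nominate proteins whose accession set satisfies ``rule``.

    Presence logic only: repeated hits of one accession count once, and the
    result is invariant to hit-list order.
    """
    if rule.family not in FAMILIES:
        raise RuleConfigError(f"unknown family {rule.family!r}")
    nominated = set()
    for pid, hits in hits_by_protein.items():
        accs = {h.accession for h in hits}
        if rule.satisfied_by(accs):
            nominated.add(pid)
    return nominated


def nominate_candidates(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    rules: Mapping[str, ArchitectureRule] | None = None,
) -> dict[str, set[str]]:
    """Apply every family rule; returns family -> nominated protein ids."""
    rules = rules if rules is not None else default_rules()
    return {
        fam: apply_architecture_rule(hits_by_protein, rule)
        for fam, rule in rules.items()
    }


@dataclass
class ArchitectureLayout:
    """Start-sorted domain intervals on one protein."""

    protein_id: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    has_overlap: bool = False


def layout(hits_by_protein: Mapping[str, Sequence[DomainHit]]) -> dict[str, ArchitectureLayout]:
    """Order each protein's domain hits by start and flag interval overlaps."""
    out: dict[str, ArchitectureLayout] = {}
    for pid, hits in hits_by_protein.items():
        ivals = sorted(((h.accession, h.start, h.end) for h in hits), key=lambda t: (t[1], t[2], t[0]))
        overlap = any(
            ivals[i][1] <= ivals[i - 1][2] for i in range(1, len(ivals))
        )
        out[pid] = ArchitectureLayout(protein_id=pid, intervals=ivals, has_overlap=overlap)
    return out


def domain_region(
    hits: Sequence[DomainHit], accession: str
) -> tuple[int, int] | None:
    """Union extent (1-based inclusive) of all hits of one accession, or None."""
    spans = [(h.start, h.end) for h in hits if h.accession == accession]
    if not spans:
        return None
    return min(s for s, _ in spans), max(e for _, e in spans)
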