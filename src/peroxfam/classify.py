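"""Per-protein family/subfamily calls, species SRX status, and the census.

The filter chain mirrors the comparative-genomic annotation procedure:

* CAT — accepted on domain architecture alone (catalase + catalase_rel);
  an optional, explicitly approximate minimum-length floor stands in for
  manual structural curation of reduced-length sequences.
* PRX — architecture AND the strictly conserved C_P active-site motif;
  candidates lacking C_P are excluded with an auditable reason.
* GPX — GSHPx domain AND a resolved catalytic-tetrad first role (Sec ->
  selenium-dependent, Cys -> cysteine-dependent; anything else rejects).
* SRX — ParB-like nuclease domain candidates are tracked per species as a
  tri-state (competent / domain_only / absent) rather than census counts.

Subfamily labels: PRX via the C_P active-site profile, optionally
cross-checked against phylogenetic clade placement (clade wins on
disagreement, with a flag — final labels are tree-derived); GPX via clade
placement only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import domains, motifs, profiles, references
from .phylo import CladeAssignment
from .sequence_io import DedupReport, ProteinRecord

logger = logging.getLogger(__name__)

PRX_SUBFAMILIES = (
    "AhpC-PRX1", "PRX5", "PRX6", "PRX4-like", "CNID-PRX-like",
)
GPX_SUBFAMILIES = references.GPX_GROUPS
UNCLASSIFIED = "unclassified"


@dataclass
class FamilyCall:
    """Accepted/rejected verdict for one protein with its evidence trail."""

    protein_id: str
    species_id: str
    family: str  # CAT / PRX / GPX / SRX / none
    status: str  # accepted / rejected
    reject_reasons: list[str] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)
    compartments: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.status == "accepted" and self.reject_reasons:
            raise ValueError(f"{self.protein_id}: accepted call with reject reasons")
        if self.status == "rejected" and not self.reject_reasons:
            raise ValueError(f"{self.protein_id}: rejected call without a reason")


@dataclass
class SubfamilyCall:
    protein_id: str
    label: str
    method: str  # active_site_profile / clade_placement / both
    agreement: bool | None = None
    scores: dict = field(default_factory=dict)
    cause: str = ""

    def __post_init__(self):
        if self.method == "both" and self.agreement is None:
            raise ValueError(f"{self.protein_id}: method=both needs agreement flag")
        if self.label == UNCLASSIFIED and not self.cause:
            raise ValueError(f"{self.protein_id}: unclassified without a cause")


@dataclass
class HyperoxidationCall:
    protein_id: str
    sensitive: bool
    ab_substitution_count: int = 0
    notes: str = ""


@dataclass(frozen=True)
class SrxStatus:
    """Species-level sulfiredoxin verdict.

    ``competent``: >=1 protein with the ParB-like domain AND the F(S/G)GCHR
    N-terminal binding motif; ``domain_only``: domain present but the motif
    absent from every candidate; ``absent``: no domain hit at all.
    """

    species_id: str
    status: str  # competent / domain_only / absent


@dataclass
class SpeciesSummary:
    """One census row: unique accepted counts + duplicate superscripts."""

    species_id: str
    counts: dict[str, int] = field(default_factory=dict)
    duplicates: dict[str, int] = field(default_factory=dict)
    srx_status: str = "absent"
    compartments: dict[str, int] = field(default_factory=dict)


CENSUS_CATEGORIES = ("CAT", "AhpC-PRX1", "PRX5", "PRX6", "GPX")


# --- family calling --------------------------------------------------------


def call_family(
    record: ProteinRecord,
    hits: Sequence[domains.DomainHit],
    nominated: Mapping[str, bool],
    cp_match: motifs.MotifMatch | None = None,
    tetrad: references.TetradCall | None = None,
    cat_length_floor: int | None = 400,
) -> FamilyCall:
    """Integrate architecture nomination with motif/tetrad filters.

    ``nominated`` maps family -> whether this protein passed that family's
    architecture rule.  A protein nominated by several family rules is
    resolved to the family whose supporting domains score highest (logged).
    The CAT length floor approximates manual curation of reduced-length
    sequences and is explicitly approximate; set it to ``None`` to disable.
    """
    families = [f for f in domains.FAMILIES if nominated.get(f)]
    if not families:
        return FamilyCall(
            protein_id=record.protein_id, species_id=record.species_id,
            family="none", status="rejected",
            reject_reasons=["no family architecture"],
        )
    if len(families) > 1:
        rules = domains.default_rules()
        def fam_score(f):
            accs = rules[f].require_all | rules[f].require_any
            return max((h.score for h in hits if h.accession in accs), default=0.0)
        families.sort(key=lambda f: (-fam_score(f), f))
        logger.info(
            "%s: nominated by multiple families %s; keeping %s",
            record.protein_id, families, families[0],
        )
    family = families[0]
    evidence: dict = {
        "domains": [
            (h.accession, h.start, h.end, h.score, h.evalue) for h in hits
        ],
    }
    reasons: list[str] = []
    if family == "CAT":
        if cat_length_floor is not None and len(record) < cat_length_floor:
            reasons.append(
                f"below length floor ({len(record)} < {cat_length_floor}; approximate structural filter)"
            )
    elif family == "PRX":
        if cp_match is None:
            reasons.append("missing C_P active-site motif")
        else:
            evidence["cp"] = {
                "start": cp_match.start,
                "position": cp_match.catalytic_positions.get("CP"),
            }
    elif family == "GPX":
        if tetrad is None:
            reasons.append("catalytic tetrad not evaluated")
        elif tetrad.catalysis == references.UNDETERMINED:
            reasons.append(f"tetrad undetermined: {tetrad.reason}")
        else:
            evidence["tetrad"] = {
                "residues": dict(tetrad.residues),
                "catalysis": tetrad.catalysis,
            }
    # SRX candidates carry through; species_srx_status handles the verdict
    status = "rejected" if reasons else "accepted"
    return FamilyCall(
        protein_id=record.protein_id, species_id=record.species_id,
        family=family, status=status, reject_reasons=reasons, evidence=evidence,
    )


# --- subfamily calling -----------------------------------------------------


def classify_prx_subfamily(
    record: ProteinRecord,
    cp_match: motifs.MotifMatch,
    profile_set: Mapping[str, profiles.SubfamilyProfile] | None = None,
    halfwidth: int | None = None,
    clade: CladeAssignment | None = None,
    margin_threshold: float = 0.5,
) -> SubfamilyCall:
    """PRX subfamily from the C_P active-site profile, plus optional clade.

    Disagreement between profile and clade resolves to the clade label
    (final labels are tree-derived) with ``agreement=False``.
    """
    if profile_set is None or halfwidth is None:
        loaded, w = profiles.load_profiles()
        profile_set = profile_set or loaded
        halfwidth = halfwidth if halfwidth is not None else w
    cp_pos = cp_match.catalytic_positions["CP"]
    ps = profiles.classify_window(
        record.sequence, cp_pos, profile_set, halfwidth, margin_threshold
    )
    scores = {"profile_scores": dict(ps.scores), "margin": ps.margin}
    if ps.truncated:
        scores["window_truncated"] = True
    if clade is not None and clade.label is not None:
        if ps.label is None:
            return SubfamilyCall(
                protein_id=record.protein_id, label=clade.label,
                method="clade_placement", scores=scores,
            )
        return SubfamilyCall(
            protein_id=record.protein_id, label=clade.label, method="both",
            agreement=(clade.label == ps.label), scores=scores,
        )
    if ps.label is None:
        return SubfamilyCall(
            protein_id=record.protein_id, label=UNCLASSIFIED,
            method="active_site_profile", scores=scores,
            cause=f"profile margin {ps.margin:.3f} below threshold {margin_threshold}",
        )
    return SubfamilyCall(
        protein_id=record.protein_id, label=ps.label,
        method="active_site_profile", scores=scores,
    )


def classify_gpx_subfamily(
    record: ProteinRecord, clade: CladeAssignment | None
) -> SubfamilyCall:
    """GPX group from clade placement only (no profile fallback)."""
    if clade is None or clade.label is None:
        cause = clade.cause if clade is not None else "no clade placement"
        return SubfamilyCall(
            protein_id=record.protein_id, label=UNCLASSIFIED,
            method="clade_placement", cause=cause or "no clade placement",
        )
    return SubfamilyCall(
        protein_id=record.protein_id, label=clade.label,
        method="clade_placement",
        scores={"support": clade.support, "clade_size": clade.clade_size},
    )


def hyperoxidation_call(record: ProteinRecord, result: motifs.HyperoxResult) -> HyperoxidationCall:
    """Sensitivity verdict for an AhpC-PRX1 sequence: GGLG AND YF both full."""
    return HyperoxidationCall(
        protein_id=record.protein_id,
        sensitive=result.gglg and result.yf,
        ab_substitution_count=len(result.a_b_substitutions),
        notes="; ".join(f"{m}:{r}->{o}" for m, r, o in result.a_b_substitutions),
    )


# --- species-level reporting -----------------------------------------------


def species_srx_status(
    species_id: str,
    records: Sequence[ProteinRecord],
    srx_candidate_ids: set[str],
) -> SrxStatus:
    """Tri-state sulfiredoxin verdict for one species."""
    candidates = [r for r in records if r.protein_id in srx_candidate_ids]
    if not candidates:
        return SrxStatus(species_id=species_id, status="absent")
    if any(motifs.srx_motif(r) for r in candidates):
        return SrxStatus(species_id=species_id, status="competent")
    return SrxStatus(species_id=species_id, status="domain_only")


def ingest_localization(
    calls: Sequence[FamilyCall], table_path: str | Path
) -> list[str]:
    """Attach predicted subcellular compartments to calls.

    The table is TSV: protein_id <TAB> compartment labels separated by
    ``|`` (multi-compartment predictions allowed).  Unknown protein ids are
    returned as an orphan list, not an error.
    """
    by_id = {c.protein_id: c for c in calls}
    orphans: list[str] = []
    with open(table_path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise ValueError(
                    f"{table_path}: malformed localization row (line {i})"
                )
            pid, comps = parts
            if pid not in by_id:
                orphans.append(pid)
                continue
            by_id[pid].compartments = [c.strip() for c in comps.split("|") if c.strip()]
    return orphans


def summarize_species(
    family_calls: Sequence[FamilyCall],
    subfamily_calls: Mapping[str, SubfamilyCall],
    dedup_reports: Mapping[str, DedupReport],
    srx_statuses: Mapping[str, SrxStatus],
) -> list[SpeciesSummary]:
    """Build the per-species census.

    Counts are over unique accepted sequences (post exact-dedup); the
    number of additional identical copies per category is reported
    separately, mirroring the superscript convention of published census
    tables.  PRX counts split by subfamily; unclassified PRX appear under
    ``PRX-unclassified`` so every accepted protein lands in exactly one
    cell.
    """
    species = sorted({c.species_id for c in family_calls} | set(srx_statuses))
    out = []
    for sp in species:
        counts: dict[str, int] = {}
        dups: dict[str, int] = {}
        dup_map = dedup_reports[sp].duplicate_counts if sp in dedup_reports else {}
        for call in family_calls:
            if call.species_id != sp or call.status != "accepted":
                continue
            if call.family == "CAT":
                cat = "CAT"
            elif call.family == "PRX":
                sub = subfamily_calls.get(call.protein_id)
                label = sub.label if sub is not None else UNCLASSIFIED
                if label in ("AhpC-PRX1", "PRX5", "PRX6"):
                    cat = label
                elif label in ("PRX4-like", "CNID-PRX-like"):
                    # tree-derived refinements of AhpC-PRX1
                    cat = "AhpC-PRX1"
                else:
                    cat = "PRX-unclassified"
            elif call.family == "GPX":
                cat = "GPX"
            else:
                continue  # SRX reported via status, not the census
            counts[cat] = counts.get(cat, 0) + 1
            extra = dup_map.get(call.protein_id, 0)
            if extra:
                dups[cat] = dups.get(cat, 0) + extra
        status = srx_statuses[sp].status if sp in srx_statuses else "absent"
        comps: dict[str, int] = {}
        for call in family_calls:
            if call.species_id == sp and call.status == "accepted":
                for comp in call.compartments:
                    comps[comp] = comps.get(comp, 0) + 1
        out.append(SpeciesSummary(
            species_id=sp, counts=counts, duplicates=dups,
            srx_status=status, compartments=comps,
        ))
    return out


def census_table(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Render summaries as a census DataFrame.

    Cells show ``N^k`` (N unique sequences, k additional identical copies)
    and zero-count cells render as an en dash, as census tables print them.
    """
    rows = {}
    for s in summaries:
        row = {}
        for cat in CENSUS_CATEGORIES + ("PRX-unclassified",):
            n = s.counts.get(cat, 0)
            k = s.duplicates.get(cat, 0)
            if n == 0:
                row[cat] = "–"
            elif k:
                row[cat] = f"{n}^{k}"
            else:
                row[cat] = str(n)
        row["SRX"] = s.srx_status
        rows[s.species_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    if (df.get("PRX-unclassified") == "–").all():
        df = df.drop(columns=["PRX-unclassified"])
    return df
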