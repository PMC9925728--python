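"""Synthetic proteome benchmark generator with truth ledgers.

Emits everything the annotation pipeline consumes — per-species proteome
FASTA, an HMMER3-style per-domain hit table, aligned subfamily FASTA — plus
a truth ledger recording what was planted where, so every pipeline stage is
testable without genome downloads.

Design points:

* Domain *presence* is asserted through the emitted hit table (the
  pipeline's contract is hit-table-driven; profile-HMM search is out of
  scope), while catalytic/functional motifs are literally planted in the
  sequences at recorded coordinates.
* Random scaffolds are deterministically sanitised against accidental
  occurrences of every scanned motif, so planted truth is exact.
* Lesions (C_P knockout, C_R->Val, Sec->Cys, GGLG/YF loss, SRX motif
  degradation, truncation) are applied to a base protein *before* exact
  duplication, so duplicate groups stay exact copies.
* Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import domains, motifs, profiles, references
from .phylo import Alignment
from .sequence_io import ProteinRecord, write_fasta

_STANDARD = "ACDEFGHIKLMNPQRSTVWY"

LESION_TYPES = (
    "cp_knockout", "cr_to_val", "sec_to_cys",
    "gglg_loss", "yf_loss", "srx_motif_degradation", "truncation",
)

#: paper-scale default family composition per synthetic species
DEFAULT_COMPOSITION: dict[str, int] = {
    "CAT": 2,
    "AhpC-PRX1": 3,
    "PRX5": 1,
    "PRX6": 1,
    "GPX1/2": 1,
    "GPX3/5/6": 1,
    "GPX4/PHGPX": 1,
    "GPX7/8": 1,
    "SRX": 1,
}

DEFAULT_DECOYS: dict[str, int] = {
    "CAT_partial": 1,   # one CAT domain only -> never nominated
    "PRX_no_cp": 3,     # PRX architecture but no C_P -> nominated then excluded
    "random": 5,        # background proteins without family hits
}


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_species: int = 19
    composition: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    decoys: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_DECOYS))
    corruption: Mapping[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.05
    profile_noise: float = 0.1     # per-site noise on non-critical C_P window positions
    cat_length: int = 500
    prx_length: int = 240
    srx_length: int = 130

    def __post_init__(self):
        for k, v in self.corruption.items():
            if k not in LESION_TYPES:
                raise ConfigError(f"unknown lesion type {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"lesion rate {k}={v} outside [0,1]")
        if any(c < 0 for c in self.composition.values()):
            raise ConfigError("composition counts must be >= 0")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ConfigError("duplicate_rate outside [0,1]")

    def rate(self, lesion: str) -> float:
        return float(self.corruption.get(lesion, 0.0))


@dataclass
class PlantedProtein:
    """Ledger row for one base protein (duplicates reference it)."""

    protein_id: str
    species_id: str
    truth_family: str      # CAT / AhpC-PRX1 / PRX5 / PRX6 / GPX* group / SRX / none
    census_category: str | None   # expected census cell, None if not counted
    planted_motifs: list[tuple[str, int, int]] = field(default_factory=list)
    lesions: list[str] = field(default_factory=list)
    duplicate_group: str | None = None
    n_duplicates: int = 0
    cp_position: int | None = None
    expected_catalysis: str | None = None   # GPX only
    srx_motif_intact: bool | None = None    # SRX only


@dataclass
class TruthLedger:
    proteins: list[PlantedProtein] = field(default_factory=list)
    expected_census: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    # species -> category -> {"unique": n, "duplicates": k}
    expected_srx: dict[str, str] = field(default_factory=dict)

    def by_id(self) -> dict[str, PlantedProtein]:
        return {p.protein_id: p for p in self.proteins}

    def to_json(self) -> str:
        return json.dumps({
            "proteins": [asdict(p) for p in self.proteins],
            "expected_census": self.expected_census,
            "expected_srx": self.expected_srx,
        }, indent=1)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    records: list[ProteinRecord]
    hits: list[domains.DomainHit]
    ledger: TruthLedger

    def write(self, outdir: str | Path) -> None:
        """Write per-species FASTA + manifest, domtblout, and ledger JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_sp: dict[str, list[ProteinRecord]] = {}
        for r in self.records:
            by_sp.setdefault(r.species_id, []).append(r)
        manifest_lines = []
        for sp in sorted(by_sp):
            write_fasta(by_sp[sp], outdir / f"{sp}.fasta")
            manifest_lines.append(f"{sp}\t{sp}.fasta")
        (outdir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
        write_domtblout(self.hits, outdir / "hits.domtblout")
        (outdir / "truth_ledger.json").write_text(self.ledger.to_json() + "\n")


def write_domtblout(hits: Sequence[domains.DomainHit], path: str | Path) -> None:
    """Emit hits in the HMMER3 per-domain table layout (hmmscan orientation)."""
    lines = [
        "#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for h in hits:
        tlen = h.end - h.start + 1
        lines.append(
            f"{h.domain_name:<21}{h.accession:<11}{tlen:>5} {h.protein_id:<20} "
            f"{'-':<11}{h.end + 20:>5} {h.evalue:>9.2g} {h.score:>6.1f} {0.1:>5.1f} "
            f"{1:>3} {1:>3} {h.evalue:>9.2g} {h.evalue:>9.2g} {h.score:>6.1f} {0.1:>5.1f} "
            f"{1:>5} {tlen:>5} {h.start:>5} {h.end:>5} {h.start:>5} {h.end:>5} 0.98 synthetic"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --- sequence construction helpers -----------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_STANDARD[i] for i in rng.integers(0, 20, size=length))


def _plant(seq: list[str], start1: int, insert: str) -> None:
    seq[start1 - 1 : start1 - 1 + len(insert)] = list(insert)


def _sanitize_patterns() -> list[motifs.MotifPattern]:
    pats = [
        motifs.CP_PATTERN, motifs.SRX_PATTERN,
        motifs.GGLG_PATTERN, motifs.YF_PATTERN,
    ]
    pats.extend(motifs.load_motif_definitions().values())
    return pats


def _hit(pid: str, accession: str, name: str, start: int, end: int,
         rng: np.random.Generator) -> domains.DomainHit:
    return domains.DomainHit(
        protein_id=pid, accession=accession, domain_name=name,
        start=start, end=end,
        score=float(np.round(rng.uniform(80, 300), 1)),
        evalue=float(10.0 ** -rng.uniform(10, 40)),
    )


def _clip_hits(hits: list[domains.DomainHit], length: int) -> list[domains.DomainHit]:
    out = []
    for h in hits:
        if h.start > length:
            continue
        if h.end > length:
            h = domains.DomainHit(h.protein_id, h.accession, h.domain_name,
                                  h.start, length, h.score, h.evalue)
        out.append(h)
    return out


# --- the generator ---------------------------------------------------------


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Build a full synthetic multi-species dataset with its truth ledger."""
    rng = np.random.default_rng(config.seed)
    sanitize_pats = _sanitize_patterns()
    profile_set, halfwidth = profiles.load_profiles()
    gpx_consensi = references.load_gpx_group_consensi()
    tetrad_ref = references.load_tetrad_reference()
    tetrad_slot1 = tetrad_ref.positions["UC"]
    tetrad_frozen = list(tetrad_ref.positions.values())

    records: list[ProteinRecord] = []
    all_hits: list[domains.DomainHit] = []
    ledger = TruthLedger()

    def lesion_on(name: str) -> bool:
        return rng.random() < config.rate(name)

    for si in range(config.n_species):
        sp = f"SP{si + 1:02d}"
        counter = 0

        def next_id(tag: str) -> str:
            nonlocal counter
            counter += 1
            return f"{sp}_{tag}{counter:03d}"

        species_proteins: list[tuple[PlantedProtein, str, list[domains.DomainHit]]] = []

        def emit(planted: PlantedProtein, seq: str, hits: list[domains.DomainHit]):
            species_proteins.append((planted, seq, hits))

        # ---- CAT ----
        for _ in range(config.composition.get("CAT", 0)):
            pid = next_id("CAT")
            L = config.cat_length
            seq = motifs.break_accidental_matches(_random_seq(rng, L), sanitize_pats)
            hits = [
                _hit(pid, domains.PF_CATALASE, "Catalase", 30, 380, rng),
                _hit(pid, domains.PF_CATALASE_REL, "Catalase-rel", 400, 480, rng),
            ]
            lesions = []
            category: str | None = "CAT"
            if lesion_on("truncation"):
                lesions.append("truncation")
                seq = seq[:300]          # below the default length floor
                hits = _clip_hits(hits, 300)
                category = None          # fails architecture and/or floor
            emit(PlantedProtein(pid, sp, "CAT", category, lesions=lesions), seq, hits)

        # ---- PRX subfamilies ----
        prx_specs = {
            "AhpC-PRX1": (domains.PF_AHPC_TSA, "AhpC-TSA"),
            "PRX5": (domains.PF_AHPC_TSA, "AhpC-TSA"),
            "PRX6": (domains.PF_1CYSPRX_C, "1-cysPrx_C"),
        }
        for subfam, (aux_acc, aux_name) in prx_specs.items():
            for _ in range(config.composition.get(subfam, 0)):
                pid = next_id(subfam.replace("-", "")[:6].upper())
                L = config.prx_length
                base = list(_random_seq(rng, L))
                planted: list[tuple[str, int, int]] = []
                # C_P window: profile consensus with noise off the motif-critical slots
                cp_pos = 70
                win_start = cp_pos - halfwidth
                window = list(profile_set[subfam].consensus)
                critical = {1, 5, 8}  # P, T/S, C of the C_P motif (window coords)
                # noise alphabet avoids Y/F so no unremovable YF dimer can
                # arise inside the protected window span
                noise_alpha = [a for a in _STANDARD if a not in "YF"]
                for wi in range(len(window)):
                    if (wi + 1) not in critical and rng.random() < config.profile_noise:
                        window[wi] = noise_alpha[rng.integers(len(noise_alpha))]
                _plant(base, win_start, "".join(window))
                planted.append(("CP", win_start, cp_pos))
                protect = [(win_start, cp_pos)]
                if subfam == "AhpC-PRX1":
                    _plant(base, 100, "GEVCPAGW")
                    planted.append(("CR_AhpC-PRX1", 100, 107))
                    _plant(base, 140, "FRYHEIA")
                    planted.append(("motif_a", 140, 146))
                    _plant(base, 170, "GGLG")
                    planted.append(("GGLG", 170, 173))
                    _plant(base, 190, "YF")
                    planted.append(("YF", 190, 191))
                    _plant(base, 205, "LDNWSVK")
                    planted.append(("motif_b", 205, 211))
                    protect += [(100, 107), (140, 146), (170, 173), (190, 191), (205, 211)]
                elif subfam == "PRX5":
                    _plant(base, 100, "DSQCGEVR")
                    planted.append(("CR_PRX5", 100, 107))
                    protect += [(100, 107)]
                else:  # PRX6: PLA2 triad with the GXSXG serine
                    _plant(base, 110, "H")
                    _plant(base, 130, "GASTG")
                    _plant(base, 150, "D")
                    planted.append(("PLA2", 110, 150))
                    planted.append(("GXSXG", 130, 134))
                    # protect only the planted residues, not the whole triad
                    # span, so accidental motifs in between stay removable
                    protect += [(110, 110), (130, 134), (150, 150)]
                keep = {(n, s) for n, s, _ in planted}
                seq = motifs.break_accidental_matches(
                    "".join(base), sanitize_pats, keep=keep, protected=protect,
                )
                hits = [
                    _hit(pid, domains.PF_PRX, "AhpC-TSA-core", 50, 160, rng),
                    _hit(pid, aux_acc, aux_name, 165, 235, rng),
                ]
                lesions = []
                category: str | None = subfam
                seq_l = list(seq)
                if lesion_on("cp_knockout"):
                    lesions.append("cp_knockout")
                    seq_l[cp_pos - 1] = "S"
                    category = None
                if subfam in ("AhpC-PRX1", "PRX5") and lesion_on("cr_to_val"):
                    lesions.append("cr_to_val")
                    seq_l[103 - 1] = "V"  # CR slot of both contexts (element 4)
                if subfam == "AhpC-PRX1":
                    if lesion_on("gglg_loss"):
                        lesions.append("gglg_loss")
                        seq_l[170 - 1] = "A"
                    if lesion_on("yf_loss"):
                        lesions.append("yf_loss")
                        seq_l[190 - 1] = "A"
                seq = "".join(seq_l)
                if lesion_on("truncation"):
                    lesions.append("truncation")
                    seq = seq[: cp_pos + 15]   # drops the auxiliary domain
                    hits = _clip_hits(hits, cp_pos + 15)
                    category = None            # architecture no longer satisfied
                emit(PlantedProtein(
                    pid, sp, subfam, category, planted_motifs=planted,
                    lesions=lesions, cp_position=cp_pos,
                ), seq, hits)

        # ---- GPX groups ----
        for group in references.GPX_GROUPS:
            for _ in range(config.composition.get(group, 0)):
                pid = next_id("GPX")
                cons = gpx_consensi[group]
                seq_l = list(cons)
                for i in range(len(seq_l)):
                    if (i + 1) not in tetrad_frozen and rng.random() < 0.04:
                        choices = [a for a in _STANDARD if a != seq_l[i]]
                        seq_l[i] = choices[rng.integers(len(choices))]
                lesions = []
                catalysis = (references.CYSTEINE if cons[tetrad_slot1 - 1] == "C"
                             else references.SELENIUM)
                if lesion_on("sec_to_cys") and seq_l[tetrad_slot1 - 1] == "U":
                    lesions.append("sec_to_cys")
                    seq_l[tetrad_slot1 - 1] = "C"
                    catalysis = references.CYSTEINE
                seq = "".join(seq_l)
                hits = [_hit(pid, domains.PF_GSHPX, "GSHPx", 5, 115, rng)]
                category: str | None = "GPX"
                if lesion_on("truncation"):
                    lesions.append("truncation")
                    seq = seq[:55]            # reference coverage < 0.5
                    hits = _clip_hits(hits, 55)
                    category = None
                emit(PlantedProtein(
                    pid, sp, group, category, lesions=lesions,
                    expected_catalysis=None if category is None else catalysis,
                ), seq, hits)

        # ---- SRX ----
        for _ in range(config.composition.get("SRX", 0)):
            pid = next_id("SRX")
            L = config.srx_length
            base = list(motifs.break_accidental_matches(_random_seq(rng, L), sanitize_pats))
            variant = "FSGCHR" if rng.random() < 0.5 else "FGGCHR"
            _plant(base, 30, variant)
            lesions = []
            intact = True
            if rng.random() < config.rate("srx_motif_degradation"):
                lesions.append("srx_motif_degradation")
                base[30 - 1] = "A"
                intact = False
            seq = motifs.break_accidental_matches(
                "".join(base), sanitize_pats,
                keep={("SRX_NTERM", 30)}, protected=[(30, 35)],
            )
            hits = [_hit(pid, domains.PF_PARBC, "ParBc", 10, 110, rng)]
            emit(PlantedProtein(
                pid, sp, "SRX", None,
                planted_motifs=[("SRX_NTERM", 30, 35)] if intact else [],
                lesions=lesions, srx_motif_intact=intact,
            ), seq, hits)

        # ---- decoys ----
        for _ in range(config.decoys.get("CAT_partial", 0)):
            pid = next_id("DCAT")
            seq = motifs.break_accidental_matches(_random_seq(rng, 450), sanitize_pats)
            hits = [_hit(pid, domains.PF_CATALASE, "Catalase", 30, 380, rng)]
            emit(PlantedProtein(pid, sp, "none", None), seq, hits)
        for _ in range(config.decoys.get("PRX_no_cp", 0)):
            pid = next_id("DPRX")
            seq = motifs.break_accidental_matches(
                _random_seq(rng, config.prx_length), sanitize_pats)
            hits = [
                _hit(pid, domains.PF_PRX, "AhpC-TSA-core", 50, 160, rng),
                _hit(pid, domains.PF_AHPC_TSA, "AhpC-TSA", 165, 235, rng),
            ]
            emit(PlantedProtein(pid, sp, "none", None), seq, hits)
        for di in range(config.decoys.get("random", 0)):
            pid = next_id("BG")
            seq = motifs.break_accidental_matches(_random_seq(rng, 200), sanitize_pats)
            hits = []
            if di == 0:  # one weak, sub-threshold hit to exercise e-value filtering
                hits = [domains.DomainHit(pid, domains.PF_PRX, "AhpC-TSA-core",
                                          20, 120, 12.0, 1e-3)]
            emit(PlantedProtein(pid, sp, "none", None), seq, hits)

        # ---- duplication (exact copies of the post-lesion base) ----
        census: dict[str, dict[str, int]] = {}
        for planted, seq, hits in species_proteins:
            n_dup = 0
            if rng.random() < config.duplicate_rate:
                n_dup = 1 + int(rng.random() < 0.3)
                planted.duplicate_group = planted.protein_id
                planted.n_duplicates = n_dup
            records.append(ProteinRecord(planted.protein_id, sp, seq))
            all_hits.extend(hits)
            for k in range(n_dup):
                dup_id = f"{planted.protein_id}_v{k + 2}"
                records.append(ProteinRecord(dup_id, sp, seq))
                for h in hits:
                    all_hits.append(domains.DomainHit(
                        dup_id, h.accession, h.domain_name,
                        h.start, h.end, h.score, h.evalue,
                    ))
            ledger.proteins.append(planted)
            if planted.census_category is not None:
                cell = census.setdefault(
                    planted.census_category, {"unique": 0, "duplicates": 0})
                cell["unique"] += 1
                cell["duplicates"] += n_dup
        ledger.expected_census[sp] = census

        srx_planted = [p for p, _, _ in species_proteins if p.truth_family == "SRX"]
        if not srx_planted:
            ledger.expected_srx[sp] = "absent"
        elif any(p.srx_motif_intact for p in srx_planted):
            ledger.expected_srx[sp] = "competent"
        else:
            ledger.expected_srx[sp] = "domain_only"

    return SyntheticDataset(config=config, records=records, hits=all_hits, ledger=ledger)


# --- subfamily alignment generator -----------------------------------------


@dataclass
class SubfamilyAlignment:
    alignment: Alignment
    labels: dict[str, str]
    gap_columns: list[tuple[int, float]]  # (0-based column index, gap fraction)


def generate_subfamily_alignment(
    seed: int = 0,
    n_groups: int = 4,
    members_per_group: int = 6,
    length: int = 200,
    within_divergence: float = 0.05,
    between_divergence: float = 0.4,
    n_gap_columns: int = 0,
) -> SubfamilyAlignment:
    """Aligned sequence groups with known structure and injected gap columns.

    Each group evolves from its own consensus (itself mutated from a shared
    base at ``between_divergence / 2`` per site), members mutate the group
    consensus at ``within_divergence / 2`` per site, so within-group
    distances stay below between-group distances.  Gap columns are injected
    at recorded indices with recorded (achieved) gap fractions.
    """
    if n_groups < 2 or members_per_group < 3:
        raise ConfigError("need >= 2 groups and >= 3 members per group")
    if not within_divergence < between_divergence:
        raise ConfigError("within-group divergence must be < between-group divergence")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length)

    def mutate(seq: str, rate: float) -> str:
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < rate:
                choices = [a for a in _STANDARD if a != out[i]]
                out[i] = choices[rng.integers(len(choices))]
        return "".join(out)

    ids, rows, labels = [], [], {}
    for g in range(n_groups):
        group = f"G{g + 1}"
        consensus = mutate(base, between_divergence / 2.0)
        for m in range(members_per_group):
            rid = f"{group}_{m + 1}"
            ids.append(rid)
            rows.append(mutate(consensus, within_divergence / 2.0))
            labels[rid] = group
    n_rows = len(rows)
    gap_cols: list[tuple[int, float]] = []
    if n_gap_columns:
        col_indices = sorted(rng.choice(length, size=n_gap_columns, replace=False).tolist())
        mat = [list(r) for r in rows]
        for col in col_indices:
            k = int(rng.integers(0, n_rows + 1))
            which = rng.choice(n_rows, size=k, replace=False)
            for r in which:
                mat[r][col] = "-"
            gap_cols.append((int(col), k / n_rows))
        rows = ["".join(r) for r in mat]
    return SubfamilyAlignment(
        alignment=Alignment(ids=ids, rows=rows),
        labels=labels,
        gap_columns=gap_cols,
    )
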