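"""Restricted motif grammar and catalytic-site scanners.

The grammar covers exactly what the family filters need — no more:

* an uppercase residue letter is a fixed position (``P`` matches only P);
* ``X`` matches any residue;
* ``[TS]`` is an alternation (any residue in the set);
* ``X{m,n}`` is a bounded gap of m..n arbitrary residues.

So the peroxidatic-cysteine (C_P) active-site motif ``PXXX(T/S)XXC`` is
written ``PXXX[TS]XXC``, the sulfiredoxin N-terminal binding motif is
``F[SG]GCHR``, and the phospholipase-A2 catalytic triad is the gapped
pattern ``HX{0,60}SX{0,60}D``.

Named *roles* attach catalytic meaning to pattern elements (e.g. the C_P
cysteine is element 8 of the C_P motif); matches report the sequence
position each role landed on.

Selenocysteine ``U`` is distinct from ``C`` except where a scan explicitly
enables Sec/Cys equivalence — the Sec-vs-Cys distinction at the GPX
catalytic position is itself a classification output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTUVWXY"


class MotifSyntaxError(ValueError):
    """Pattern text failed to compile; carries the column offset."""

    def __init__(self, message: str, column: int):
        self.column = column
        super().__init__(f"{message} (column {column})")


class RegionError(ValueError):
    pass


# --- pattern elements ------------------------------------------------------
# ("set", frozenset)   fixed residue or alternation
# ("any",)             X wildcard, exactly one residue
# ("gap", min, max)    bounded run of arbitrary residues


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif: ordered elements plus named catalytic roles.

    ``roles`` maps a role name (e.g. ``"CP"``) to a 1-based element index.
    ``expected`` optionally records the canonical residue for a role whose
    pattern slot is a wildcard (used for substitution reporting).
    """

    name: str
    spec: str
    elements: tuple[tuple, ...]
    roles: Mapping[str, int] = field(default_factory=dict)
    expected: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        non_wild = [e for e in self.elements if e[0] == "set"]
        if not non_wild:
            raise MotifSyntaxError(f"{self.name}: pattern has no fixed element", 0)
        for role, idx in self.roles.items():
            if not 1 <= idx <= len(self.elements):
                raise MotifSyntaxError(
                    f"{self.name}: role {role} element index {idx} out of range", 0
                )

    @property
    def min_length(self) -> int:
        return sum(e[1] if e[0] == "gap" else 1 for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """One located motif occurrence (1-based inclusive coordinates)."""

    protein_id: str
    motif: str
    start: int
    end: int
    substring: str
    catalytic_positions: Mapping[str, int] = field(default_factory=dict)


def compile_pattern(
    spec: str,
    name: str | None = None,
    roles: Mapping[str, int] | None = None,
    expected: Mapping[str, str] | None = None,
) -> MotifPattern:
    """Compile a pattern string into a :class:`MotifPattern`.

    Raises :class:`MotifSyntaxError` with the 0-based column offset of the
    first offending character.
    """
    if not spec:
        raise MotifSyntaxError("empty pattern", 0)
    elements: list[tuple] = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == "[":
            j = spec.find("]", i)
            if j < 0:
                raise MotifSyntaxError("unterminated '['", i)
            members = spec[i + 1 : j]
            if not members or any(m not in AMINO_ACIDS or m == "X" for m in members):
                raise MotifSyntaxError(f"bad alternation [{members}]", i)
            elements.append(("set", frozenset(members)))
            i = j + 1
        elif c == "X":
            if i + 1 < len(spec) and spec[i + 1] == "{":
                j = spec.find("}", i)
                if j < 0:
                    raise MotifSyntaxError("unterminated '{'", i + 1)
                body = spec[i + 2 : j]
                try:
                    lo_s, hi_s = body.split(",")
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise MotifSyntaxError(f"bad gap bounds {{{body}}}", i + 1) from None
                if not (0 <= lo <= hi):
                    raise MotifSyntaxError(f"gap bounds must satisfy 0<=min<=max", i + 1)
                elements.append(("gap", lo, hi))
                i = j + 1
            else:
                elements.append(("any",))
                i += 1
        elif c in AMINO_ACIDS:
            elements.append(("set", frozenset(c)))
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {c!r}", i)
    return MotifPattern(
        name=name or spec,
        spec=spec,
        elements=tuple(elements),
        roles=dict(roles or {}),
        expected=dict(expected or {}),
    )


def _residue_ok(residue: str, allowed: frozenset[str], sec_equivalence: bool) -> bool:
    if residue in allowed:
        return True
    return sec_equivalence and residue == "U" and "C" in allowed


def _match_at(
    seq: str, start0: int, elements: Sequence[tuple], sec_equivalence: bool
) -> tuple[int, dict[int, int]] | None:
    """Try to match ``elements`` at 0-based offset ``start0``.

    Returns (exclusive end offset, element-index -> 0-based position) for the
    *shortest* match (gaps expand minimally), or None.  Gap elements map to
    the position of the following consumed residue's predecessor only for
    non-gap elements; gap elements themselves carry no role position.
    """

    def rec(pos: int, ei: int, trace: dict[int, int]):
        if ei == len(elements):
            return pos, trace
        el = elements[ei]
        kind = el[0]
        if kind == "set":
            if pos < len(seq) and _residue_ok(seq[pos], el[1], sec_equivalence):
                trace[ei] = pos
                result = rec(pos + 1, ei + 1, trace)
                if result is not None:
                    return result
                del trace[ei]
            return None
        if kind == "any":
            if pos < len(seq):
                trace[ei] = pos
                result = rec(pos + 1, ei + 1, trace)
                if result is not None:
                    return result
                del trace[ei]
            return None
        # gap: try shortest expansion first
        _, lo, hi = el
        for k in range(lo, hi + 1):
            if pos + k > len(seq):
                break
            result = rec(pos + k, ei + 1, trace)
            if result is not None:
                return result
        return None

    return rec(start0, 0, {})


def scan(
    record: ProteinRecord | str,
    pattern: MotifPattern,
    region: tuple[int, int] | None = None,
    flank: int = 0,
    sec_equivalence: bool = False,
) -> list[MotifMatch]:
    """All motif occurrences, left to right by start (overlaps allowed).

    At each start offset at most one (the shortest) match is reported.
    ``region`` is a 1-based inclusive interval constraining the match *start*
    to the interval expanded by ``flank`` on both sides.
    """
    if isinstance(record, ProteinRecord):
        seq, pid = record.sequence, record.protein_id
    else:
        seq, pid = record, ""
    n = len(seq)
    if region is not None:
        lo, hi = region
        if not (1 <= lo <= hi <= n):
            raise RegionError(f"region {region} outside sequence of length {n}")
        start_lo = max(1, lo - flank)
        start_hi = min(n, hi + flank)
    else:
        start_lo, start_hi = 1, n
    matches: list[MotifMatch] = []
    # cheap prefilter: a fixed first element restricts candidate starts
    first = pattern.elements[0]
    if first[0] == "set" and not sec_equivalence:
        starts = [
            s1 for s1 in range(start_lo, start_hi + 1) if seq[s1 - 1] in first[1]
        ]
    elif first[0] == "set":
        allowed = first[1] | ({"U"} if "C" in first[1] else set())
        starts = [
            s1 for s1 in range(start_lo, start_hi + 1) if seq[s1 - 1] in allowed
        ]
    else:
        starts = list(range(start_lo, start_hi + 1))
    for s1 in starts:
        hit = _match_at(seq, s1 - 1, pattern.elements, sec_equivalence)
        if hit is None:
            continue
        end0, trace = hit
        roles = {
            role: trace[idx - 1] + 1
            for role, idx in pattern.roles.items()
            if idx - 1 in trace
        }
        matches.append(
            MotifMatch(
                protein_id=pid,
                motif=pattern.name,
                start=s1,
                end=end0,
                substring=seq[s1 - 1 : end0],
                catalytic_positions=roles,
            )
        )
    return matches


_REPLACEMENT_ORDER = "AGVLITSERKPDQNFHMWYC"


def break_accidental_matches(
    seq: str,
    patterns: Sequence[MotifPattern],
    keep: Iterable[tuple[str, int]] = (),
    protected: Sequence[tuple[int, int]] = (),
    max_rounds: int = 25,
) -> str:
    """Mutate a sequence until it carries no unintended motif occurrences.

    Used by synthetic-data construction: random scaffolds occasionally
    contain chance occurrences of short motifs, which would make planted
    truth ill-defined.  Every match of ``patterns`` not listed in ``keep``
    (as ``(pattern name, 1-based start)``) is destroyed by mutating one of
    its fixed-element positions lying outside all ``protected`` spans.
    Deterministic: the replacement residue is the first in a fixed order
    that breaks the element.  Mutations can create new matches, hence the
    bounded re-scan loop.
    """
    keep_set = set(keep)

    def in_protected(pos1: int) -> bool:
        return any(lo <= pos1 <= hi for lo, hi in protected)

    current = seq
    for _ in range(max_rounds):
        changed = False
        for pattern in patterns:
            for m in scan(current, pattern):
                if (pattern.name, m.start) in keep_set:
                    continue
                trace = _match_at(current, m.start - 1, pattern.elements, False)
                if trace is None:  # destroyed by an earlier mutation this round
                    continue
                _, elem_pos = trace
                target = None
                allowed: frozenset[str] = frozenset()
                for ei, el in enumerate(pattern.elements):
                    if el[0] != "set" or ei not in elem_pos:
                        continue
                    pos1 = elem_pos[ei] + 1
                    if not in_protected(pos1):
                        target, allowed = pos1, el[1]
                        break
                if target is None:
                    logger.warning(
                        "cannot sanitize %s match at %d: all fixed positions protected",
                        pattern.name, m.start,
                    )
                    continue
                old = current[target - 1]
                repl = next(
                    a for a in _REPLACEMENT_ORDER if a not in allowed and a != old
                )
                current = current[: target - 1] + repl + current[target:]
                changed = True
        if not changed:
            return current
    return current


# --- bundled patterns ------------------------------------------------------

#: C_P active-site motif PXXX(T/S)XXC; the catalytic cysteine is element 8.
CP_PATTERN = compile_pattern("PXXX[TS]XXC", name="CP", roles={"CP": 8})
#: Sulfiredoxin N-terminal binding motif.
SRX_PATTERN = compile_pattern("F[SG]GCHR", name="SRX_NTERM", roles={"C": 4})
GGLG_PATTERN = compile_pattern("GGLG", name="GGLG")
YF_PATTERN = compile_pattern("YF", name="YF")
#: Lipase/esterase motif of PRX6; the catalytic serine is element 3.
GXSXG_PATTERN = compile_pattern("GXSXG", name="GXSXG", roles={"S": 3})
#: Phospholipase-A2 catalytic triad with bounded inter-role gaps.
PLA2_PATTERN = compile_pattern(
    "HX{0,60}SX{0,60}D", name="PLA2_TRIAD", roles={"H": 1, "S": 3, "D": 5}
)

BUNDLED_PATTERNS: dict[str, MotifPattern] = {
    p.name: p
    for p in (CP_PATTERN, SRX_PATTERN, GGLG_PATTERN, YF_PATTERN, GXSXG_PATTERN, PLA2_PATTERN)
}


def _load_json_data(filename: str):
    with resources.files("peroxfam.data").joinpath(filename).open() as fh:
        return json.load(fh)


def load_motif_definitions(path=None) -> dict[str, MotifPattern]:
    """Load user-editable motif definitions (C_R contexts, a/b motifs).

    The bundled file ships *provisional* definitions: the source literature
    displays these sites in figures or defers them to citations without
    printing scannable patterns, so the residue content here is a synthetic
    stand-in users should replace with curated patterns.
    """
    if path is None:
        raw = _load_json_data("motif_definitions.json")
    else:
        with open(path) as fh:
            raw = json.load(fh)
    out = {}
    for name, d in raw.items():
        if name.startswith("_"):
            continue
        out[name] = compile_pattern(
            d["pattern"], name=name, roles=d.get("roles", {}), expected=d.get("expected", {})
        )
    return out


# --- family-specific scanners ---------------------------------------------


def find_cp(record: ProteinRecord) -> MotifMatch | None:
    """Leftmost C_P active-site match; absence is a definitive negative.

    When several C_P matches exist the leftmost is "the" catalytic site and
    the alternative count is logged; all matches remain recoverable via
    :func:`scan`.
    """
    matches = scan(record, CP_PATTERN)
    if not matches:
        return None
    if len(matches) > 1:
        logger.info(
            "%s: %d C_P matches; reporting leftmost at %d",
            record.protein_id, len(matches), matches[0].start,
        )
    return matches[0]


@dataclass(frozen=True)
class CrStatus:
    """Resolving-cysteine (C_R) status.

    ``status`` is ``present`` (context matched, Cys in the catalytic slot),
    ``substituted`` (context matched, another residue — e.g. the Val
    replacement seen in sponge PRX5), or ``absent`` (no context match, e.g.
    1-Cys PRX6 or a truncated sequence).
    """

    status: str
    residue: str | None = None
    position: int | None = None


def find_cr(
    record: ProteinRecord,
    subfamily_hint: str,
    contexts: Mapping[str, MotifPattern] | None = None,
    after: int | None = None,
) -> CrStatus:
    """Resolve C_R status from the subfamily-specific context pattern.

    The context pattern holds the conserved residues flanking C_R with a
    wildcard at the cysteine slot (role ``CR``); the observed slot residue
    decides present vs substituted.  Subfamilies without a bundled context
    (PRX6 is 1-Cys) report ``absent``.  ``after`` restricts the search to
    start beyond that 1-based position (typically the C_P site).
    """
    if contexts is None:
        contexts = load_motif_definitions()
    key = f"CR_{subfamily_hint}"
    pattern = contexts.get(key)
    if pattern is None:
        return CrStatus(status="absent")
    matches = scan(record, pattern)
    if after is not None:
        matches = [m for m in matches if m.start > after]
    if not matches:
        return CrStatus(status="absent")
    m = matches[0]
    pos = m.catalytic_positions.get("CR")
    residue = record.sequence[pos - 1] if pos else None
    if residue == "C":
        return CrStatus(status="present", residue="C", position=pos)
    return CrStatus(status="substituted", residue=residue, position=pos)


@dataclass(frozen=True)
class TriadStatus:
    """PLA2 catalytic triad verdict: full / partial(missing roles) / absent."""

    status: str
    missing: tuple[str, ...] = ()
    positions: Mapping[str, int] = field(default_factory=dict)


_TRIAD_SUBPATTERNS = {
    # two-role ordered subpatterns; the absent role is the dict key
    "D": compile_pattern("HX{0,60}S", name="PLA2_HS", roles={"H": 1, "S": 3}),
    "S": compile_pattern("HX{0,121}D", name="PLA2_HD", roles={"H": 1, "D": 3}),
    "H": compile_pattern("SX{0,60}D", name="PLA2_SD", roles={"S": 1, "D": 3}),
}


def pla2_triad(
    record: ProteinRecord, region: tuple[int, int], flank: int = 0
) -> TriadStatus:
    """Assess the ordered H..S..D phospholipase-A2 triad within ``region``.

    ``full`` requires all three roles in order within the configured gap
    bounds (0-60 residues between consecutive roles); when a GXSXG match
    exists its serine is preferred as the triad serine.  If exactly one role
    fails, the two-role ordered subpattern identifies it (``partial``);
    otherwise ``absent`` — note an order violation (e.g. D before H) is
    absent, not partial.
    """
    g = gxsxg_match(record, region, flank=flank)
    full_matches = scan(record, PLA2_PATTERN, region=region, flank=flank)
    if full_matches:
        chosen = full_matches[0]
        if g is not None:
            s_pos = g.catalytic_positions["S"]
            anchored = [m for m in full_matches if m.catalytic_positions.get("S") == s_pos]
            if anchored:
                chosen = anchored[0]
        return TriadStatus(status="full", positions=dict(chosen.catalytic_positions))
    for missing_role, sub in _TRIAD_SUBPATTERNS.items():
        m = scan(record, sub, region=region, flank=flank)
        if m:
            return TriadStatus(
                status="partial",
                missing=(missing_role,),
                positions=dict(m[0].catalytic_positions),
            )
    return TriadStatus(status="absent", missing=("H", "S", "D"))


def gxsxg_match(
    record: ProteinRecord, region: tuple[int, int] | None = None, flank: int = 0
) -> MotifMatch | None:
    matches = scan(record, GXSXG_PATTERN, region=region, flank=flank)
    return matches[0] if matches else None


def gxsxg(record: ProteinRecord, region: tuple[int, int] | None = None, flank: int = 0) -> bool:
    """Presence of the GXSXG lipase motif (optionally within a region)."""
    return gxsxg_match(record, region, flank=flank) is not None


def srx_motif(record: ProteinRecord) -> bool:
    """Presence of the strictly conserved F(S/G)GCHR sulfiredoxin motif."""
    return bool(scan(record, SRX_PATTERN))


@dataclass(frozen=True)
class HyperoxResult:
    """Hyperoxidation-sensitivity motif report for AhpC-PRX1 sequences."""

    gglg: bool
    yf: bool
    a_b_substitutions: tuple[tuple[str, str, str], ...] = ()  # (motif, role, observed)
    a_b_found: Mapping[str, bool] = field(default_factory=dict)


def hyperox_motifs(
    record: ProteinRecord,
    definitions: Mapping[str, MotifPattern] | None = None,
    cterm_only: bool = True,
) -> HyperoxResult:
    """Scan the hyperoxidation-sensitivity motifs GGLG and YF plus a/b motifs.

    GGLG and YF are searched in the C-terminal half by default (both are
    C-terminal in this family; set ``cterm_only=False`` for the full
    sequence).  The a/b motifs are evaluated against the bundled provisional
    definitions: each carries wildcard role slots with an expected residue,
    and any observed deviation is reported as (motif, role, observed) —
    e.g. a missing His in motif a.
    """
    n = len(record.sequence)
    region = (max(1, n // 2), n) if cterm_only and n > 1 else None
    gglg_present = bool(scan(record, GGLG_PATTERN, region=region))
    yf_present = bool(scan(record, YF_PATTERN, region=region))
    if definitions is None:
        definitions = load_motif_definitions()
    subs: list[tuple[str, str, str]] = []
    found: dict[str, bool] = {}
    for name in ("motif_a", "motif_b"):
        pattern = definitions.get(name)
        if pattern is None:
            continue
        matches = scan(record, pattern)
        found[name] = bool(matches)
        if not matches:
            continue
        m = matches[0]
        for role, pos in m.catalytic_positions.items():
            expect = pattern.expected.get(role)
            if expect is None:
                continue
            observed = record.sequence[pos - 1]
            if observed != expect:
                subs.append((name, role, observed))
    return HyperoxResult(
        gglg=gglg_present,
        yf=yf_present,
        a_b_substitutions=tuple(subs),
        a_b_found=found,
    )
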