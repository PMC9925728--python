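# Methods

## Scope and data flow

`peroxfam` annotates predicted proteomes for the three H₂O₂-targeting
antioxidant enzyme families (CAT, PRX, GPX) and the SRX reductant. The
pipeline is deliberately *hit-table-driven*: profile-HMM search itself is
out of scope, and domain evidence enters as a parsed HMMER3 per-domain
table (`--domtblout`, hmmscan or hmmsearch orientation, auto-detected per
row). Envelope coordinates define domain intervals, 1-based inclusive, the
convention of the per-domain table format. Sequences enter as amino-acid
FASTA with species provenance taken from a two-column manifest
(authoritative) or the filename stem (fallback). Selenocysteine `U` is a
first-class residue throughout and is never silently translated: the
Sec/Cys distinction at the GPX catalytic position is itself an output.

Exact duplicate sequences are collapsed per species before calling; the
lexicographically smallest protein id of each group is retained so results
are order- and platform-independent. Census cells report unique counts with
the number of collapsed identical copies carried separately (the
superscript convention of published gene-census tables).

## Candidate nomination and filtering

Architecture rules are presence logic over Pfam accessions (see README
table); repeated hits of one accession count once, so nomination is
invariant to hit order, and tightening the e-value threshold can only
shrink candidate sets. The default per-domain acceptance threshold is
i-E-value ≤ 1e-5 with no score floor — a conservative common default,
surfaced in configuration so census counts can be chased under other
settings. One published domain naming wrinkle is preserved as
configuration rather than resolved in code: PF08534 is labelled "AhpC-TSA"
in some sources while that name conventionally attaches to PF00578, so the
rule sets ship as data and either reading can be configured. A protein
nominated by two family rules is resolved to the family whose supporting
domains carry the higher bit score, with the conflict logged.

CAT candidates are accepted on architecture alone. Published censuses of this family
typically also remove reduced-length CAT sequences by manual curation after
alignment and structural inspection; that step is approximated here by an
explicitly approximate, configurable minimum-length floor (default 400
residues, roughly the length below which a catalase cannot contain both
domains intact). Set it to `None` to disable.

PRX candidates must contain the C_P motif `PXXX[TS]XXC`; absence is a
definitive negative and the protein is excluded with reason
`missing C_P active-site motif`. When several C_P matches occur the
leftmost is "the" catalytic site (tie rule); alternatives remain visible
through the scanner API and the count is logged.

GPX candidates must yield a resolved catalytic tetrad (below); an
undetermined tetrad rejects with the reason recorded.

SRX candidates never enter the census; they produce a per-species
tri-state: *competent* (≥1 protein with the ParB-like domain and an intact
`F[SG]GCHR` motif), *domain_only*, or *absent*.

## The motif grammar

The scanner implements exactly the grammar the filters need: fixed
residues, `X` wildcards, alternations `[TS]`, and bounded gaps `X{m,n}`
(no backreferences, anchors, or PROSITE import). At each start offset at
most one match is reported — the shortest, i.e. gaps expand minimally —
and matches are returned left to right. Named roles map pattern elements to
catalytic meaning (the C_P cysteine is element 8 of its motif), and every
match reports the sequence position of each role. `U` matches `C`-fixed
positions only where a scan explicitly enables Sec/Cys equivalence.

Gap bounds for the PLA₂ triad `H…S…D` default to 0–60 residues between
consecutive roles (the literature prints the triad with unspecified
spacing; 60 spans the inter-role spacings seen in PRX6 structures while keeping chance
matches in unrelated sequence bounded). The triad verdict is three-valued:
*full* requires all three roles in order within bounds, preferring the
serine of a `GXSXG` match when one exists; if exactly one role fails, the
two-role ordered subpatterns (`H…S`, `H…D` with a widened 0–121 gap, `S…D`)
identify it as *partial(missing role)*; anything else — including an order
violation such as D before H — is *absent*. A sequence carrying only one of
the three roles therefore reports *absent*, not partial; the two-role
requirement is what separates a broken triad from background noise.

GGLG and YF are scanned in the C-terminal half by default (both are
C-terminal in this family), configurable to the full sequence.
Hyperoxidation sensitivity requires both.

Two motif classes are not printed as scannable patterns in the primary
literature and therefore ship as clearly *provisional* definitions in an
editable data file (`data/motif_definitions.json`): the subfamily-specific
C_R context patterns and the a/b hyperoxidation-modulation motifs, whose
residue content the literature shows in figures or defers to citations
rather than printing as patterns. Each is a
context pattern with conserved anchors and a wildcard at the role slot, so
a substituted residue (e.g. C_R→Val) still matches the context and is
reported as a substitution rather than an absence. Users with curated
patterns should replace these files; the bundled synthetic benchmark
plants the bundled definitions.

## PRX subfamily profiles

Subfamily classification keys on the ±7-residue window around C_P, scored
against per-subfamily position-specific profiles as the mean per-position
log-odds versus a uniform 1/20 background. Profiles are
consensus-with-concentration (consensus residue probability 0.7, remainder
spread evenly); the bundled consensi are synthetic stand-ins distinct
enough for benchmark classification and live in `data/prx_profiles.json`
for substitution by curated profiles. The best label is assigned only when
its margin over the runner-up exceeds a threshold (default 0.5 mean-nats);
raising the threshold can only convert classified to unclassified.
Windows clipped at a sequence end score over the available positions and
are flagged. When a clade placement is also available the final label is
the clade's (tree placement is the conventional arbiter of final
subfamily identity in comparative studies), with an agreement flag recording whether the profile concurred;
tree-derived refinements such as PRX4-like still tally under AhpC-PRX1 in
the census.

## GPX tetrad typing and group assignment

The catalytic tetrad (Sec/Cys, Gln, Trp, Asn) is located by global
pairwise alignment (BLOSUM62, gap open −11 / extend −1) of the query's
GSHPx region to a tetrad-annotated reference sequence; `U` is scored as
`C` during alignment but reported verbatim. Typing requires reference
coverage ≥ 0.5; below that, or when the first tetrad role resolves to
neither U nor C (including a deleted/unaligned position), the catalysis
type is undetermined and the candidate is rejected with the reason kept.

GPX groups (GPX1/2, GPX3/5/6, GPX4/PHGPX, GPX7/8) are assigned purely
phylogenetically — no profile fallback — by placing queries against a
labelled reference set. The bundled reference (tetrad reference, group
consensi, and a 4-group × 6-member reference alignment, Sec at the
catalytic slot in all groups except the exclusively cysteine-dependent
GPX7/8) is *synthetic*, generated from a fixed seed by
`references.build_reference_data`, and shipped as data files for
substitution by curated sets. The default placement path stacks queries of
matching length onto the ungapped reference alignment (the synthetic
benchmark's case); real proteomes with indels should supply an externally
computed alignment or tree.

## Alignment editing, trees, and clade assignment

Gap-column editing removes columns whose gap fraction *strictly* exceeds
0.5 — "more than 50% gaps" keeps the exact-boundary column — and reports
removed indices (0-based). The rule is per-column; a block-window variant
is deliberately left to configuration rather than guessed. The operation
is idempotent.

Distances are computed over mutually ungapped column pairs (p-distance or
Poisson-corrected d = −ln(1−p); a pair with no comparable columns, or
p = 1 under Poisson, is an error naming the pair; `U` counts as `C`).
Trees come from classical neighbor-joining (scikit-bio's implementation;
negative branch lengths clamped to zero, standard practice preserving the
non-negative-length invariant). Supports come from seeded column-resampling
bootstrap: B replicates, support = percentage of replicate trees containing
each internal bipartition, reproducible given the seed. This NJ+bootstrap
stack is a desk-scale stand-in for an external maximum-likelihood workflow
(model selection, ultrafast bootstrap are non-goals); support-annotated
newick from such tools is accepted directly, with numeric internal-node
labels parsed as supports.

Clade assignment uses unrooted semantics: a "clade" is an edge-induced
bipartition side. The smallest side containing the query and ≥1 labelled
reference defines the assignment; the label is granted iff every reference
in it shares one label and, when configured, the defining edge's support
passes. Several sides can tie at minimal size (e.g. a query sister to the
entire reference set); a label is then granted only if all minimal sides
agree on one pure label, otherwise the placement is *mixed* — this makes
the sister-to-everything case correctly unclassifiable instead of
arbitrarily labelled.

## The synthetic benchmark generator

The generator emulates exactly the features the pipeline filters on, not
biological realism (no indel evolution, no rate heterogeneity, no
localization signals). Each planted protein is a uniform-background
scaffold carrying literal motif instances at recorded coordinates, with
domain presence asserted through emitted hit-table rows (scores and
e-values drawn well inside the acceptance threshold; one deliberately
sub-threshold decoy hit per species exercises e-value filtering).
Scaffolds are deterministically sanitised against chance occurrences of
every scanned pattern so that planted truth is exact — without this, short
motifs like YF would arise by chance and make ledger comparisons
ill-defined. Per-species composition defaults to published-census
magnitudes (a few members per family per species) plus decoys: a
single-domain CAT, PRX-architecture proteins without C_P (reproducing the
many-nominated → few-accepted funnel shape of real censuses), and background
proteins.

Lesions model the biological variants the classifier must distinguish:
C_P knockout (C→S; removes the protein from the PRX census and nothing
else), C_R→Val (reported as substitution), Sec→Cys (flips catalysis type
only), GGLG/YF loss, SRX motif degradation (F→A, driving the species to
*domain_only*), and truncation (drops the auxiliary domain or reference
coverage, removing the protein from the census). Lesions are decided and
applied to the base protein before exact-copy duplication, so duplicate
groups stay identical. The truth ledger records per-protein family,
planted coordinates, lesions, and duplicate groups, plus per-species
expected census cells and SRX status, derived from the lesion semantics
above rather than by re-running the classifier.

The subfamily-alignment generator evolves groups from distinct consensi
(group consensus = shared base mutated at `between/2` per site; members at
`within/2`), validating within < between, and injects gap columns at
recorded indices with recorded achieved fractions. Defaults (within 0.05,
between 0.4, 200 columns, 4 × 6 members) separate groups far enough that
NJ recovers them monophyletically with full bootstrap support.

## Numerical and tie-break choices

* Motif matching: shortest match per offset; leftmost match is "the" site.
* Dedup keeper: lexicographically smallest id.
* Profile margin: best minus runner-up mean log-odds; ties below threshold
  stay unclassified.
* NJ tie-breaking follows scikit-bio's deterministic argmin; bipartitions
  are canonicalised to the side not containing the lexicographically
  smallest leaf.
* All randomness flows from a single `numpy` Generator per operation,
  seeded explicitly; outputs are byte-reproducible.

## Problem sizes used in the checks

The shipped acceptance benchmark runs 19 synthetic species at ~100 planted
proteins each (the census/precision/recall and lesion checks), 1000
random 300-residue sequences for the motif-scanner oracle, 50 random
8-taxon additive matrices for NJ recovery, one 4-group family at B=100
for bootstrap support, and 200 random labelings of ≤16-leaf trees for the
clade-assignment oracle. These sizes exercise every code path while
keeping a full run to seconds.

## Known limitations

* Manual curation steps used in real censuses (structural inspection of
  CAT candidates, judging whether a domain layout is characteristically
  GPX) are approximated by the length floor and the domain+tetrad checks;
  counts on real proteomes can differ from manually curated ones.
* Default GPX clade placement requires queries stackable on the bundled
  ungapped reference alignment; real data needs an external alignment/tree.
* The C_R contexts, a/b motifs, PRX profiles, and GPX references are
  synthetic provisional stand-ins, marked as such in their data files.
* Profile-HMM search, maximum-likelihood inference, and subcellular
  localization prediction are consumed, never computed (localization
  enters only as an ingested table).
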