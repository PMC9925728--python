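# peroxfam

Comparative-genomic annotation of the enzymatic antioxidant families that
target hydrogen peroxide — monofunctional **catalase (CAT)**,
**peroxiredoxin (PRX)**, and **glutathione peroxidase (GPX)** — plus the
**sulfiredoxin (SRX)** reductant that reactivates hyperoxidized PRXs.

The package is aimed at comparative genomicists running gene-family censuses
across predicted proteomes: given per-species amino-acid FASTA files and a
profile-HMM per-domain hit table (HMMER3 `--domtblout`), it nominates
candidates by domain architecture, filters them by catalytic-site motifs,
classifies subfamilies, and assembles a per-species census table with an
auditable reject trail. A synthetic-proteome generator with a truth ledger
makes every stage testable without genome downloads.

## The annotation model

Candidates are nominated per family by Pfam domain architecture:

| family | rule |
|---|---|
| CAT | PF00199 (catalase) **and** PF06628 (catalase_rel) |
| PRX | PF00578 **and** ≥1 of PF08534 / PF10417 |
| GPX | PF00255 (GSHPx) |
| SRX | PF02195 (ParB-like nuclease domain) |

Nominees then pass through family-specific catalytic filters expressed in a
restricted motif grammar (fixed residues, alternations `[TS]`, bounded gaps
`X{m,n}`):

* **PRX** requires the strictly conserved peroxidatic-cysteine (C_P) active
  site `PXXX[TS]XXC`; sequences lacking it are excluded with a recorded
  reason. Subfamily (AhpC-PRX1 / PRX5 / PRX6) is called from a
  position-specific profile of the ±7-residue window around C_P, scored as
  mean log-odds against a uniform background, optionally cross-checked
  against phylogenetic clade placement (the tree wins on disagreement).
  AhpC-PRX1 sequences are further annotated for hyperoxidation sensitivity
  (GGLG + YF motifs, a/b-motif substitutions) and resolving-cysteine (C_R)
  status — present, substituted (e.g. the Val replacement seen in sponge
  PRX5), or absent. PRX6 is annotated for the phospholipase-A2 triad
  `HX{0,60}SX{0,60}D` and the `GXSXG` lipase motif.
* **GPX** requires the catalytic tetrad (Sec/Cys, Gln, Trp, Asn), located by
  global alignment to an annotated reference; `U` at the first tetrad role
  means selenium-dependent, `C` cysteine-dependent. Subfamily groups
  (GPX1/2, GPX3/5/6, GPX4/PHGPX, GPX7/8) come from placement in a labelled
  reference tree: a query takes the label of its smallest enclosing clade
  whose references agree.
* **SRX** is a species-level tri-state: *competent* (domain + the
  `F[SG]GCHR` N-terminal binding motif), *domain_only*, or *absent*.

The phylogenetic stand-in is classical: alignment columns with gap fraction
strictly > 0.5 are removed, distances are p- or Poisson-corrected
(d = −ln(1 − p)), trees come from neighbor-joining, and supports from
seeded column-resampling bootstrap. Externally built, support-annotated
newick trees (e.g. maximum-likelihood trees) are first-class inputs.

## Worked example

```python
from peroxfam import synthetic, pipeline

cfg = synthetic.SyntheticConfig(seed=7, n_species=4)   # paper-scale species
ds = synthetic.generate_dataset(cfg)                   # FASTA + hits + truth
res = pipeline.annotate(ds.records, ds.hits)
print(res.census.to_string())
```

prints

```
         CAT AhpC-PRX1 PRX5 PRX6  GPX        SRX
species
SP01       2         3    1  1^2    4  competent
SP02     2^1         3  1^2    1    4  competent
SP03       2         3    1    1  4^1  competent
SP04       2         3    1    1    4  competent
```

Each cell counts unique accepted sequences per category; a superscript is
the number of additional identical copies that were collapsed (so `1^2`
means one unique PRX6 sequence plus two exact duplicates), and `–` marks an
empty cell. The SRX column is the species tri-state. The funnel
(`res.funnel`) records nominated vs accepted counts per family — here
`PRX: 36 nominated -> 20 accepted`, the excluded 16 being candidates with
PRX architecture but no C_P motif.

The same workflow is available from the shell:

```bash
peroxfam simulate --seed 7 --species 4 --out data/
peroxfam classify --manifest data/manifest.tsv --domtblout data/hits.domtblout --out results/
peroxfam tree --alignment fam.fasta --labels refs.tsv --bootstrap 100 --seed 1 --out tree/
```

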