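# triosift

Family-based prioritization of whole-exome variants for a small pedigree with
affected siblings and an unaffected parent, built around the screening
strategy used in rare-disease family studies of antiphospholipid syndrome
(APS): a five-stage filter cascade over a multi-sample VCF, curated gene-panel
and known-variant screens, and a synthetic pedigree generator with planted
ground truth.

## Who this is for

Groups analyzing a familial cluster of a complex disease by whole-exome
sequencing (WES), where the question is not "which known Mendelian mutation
explains this" but "which rare, protein-affecting variants segregate with the
phenotype inside this family". The package consumes a jointly called VCF (GT
and DP per sample), a 6-column PED file, and a variant annotation table
(population allele frequency, gene, transcript, consequence, 5-tier
pathogenicity class) as either VCF INFO keys or a sidecar TSV.

## The filter cascade

Given affected set *A* and unaffected set *U*, a variant *v* with population
allele frequency AF(*v*), pathogenicity class C(*v*), consequence q(*v*) and
per-sample depth DP<sub>s</sub>(*v*) is a candidate iff

1. **frequency** — AF(*v*) < 0.01 (gnomAD-style cohort AF; missing AF passes:
   novel implies rare);
2. **affected sharing** — every s ∈ *A* carries ≥ 1 alt allele (het or hom-alt);
3. **unaffected exclusion** — no s ∈ *U* carries an alt allele;
4. **class/consequence** — C(*v*) ∉ {benign, likely benign} and q(*v*) affects
   the protein (missense, nonsense, frameshift, splice region, in-frame indel);
5. **depth** — DP<sub>s</sub>(*v*) ≥ 20 for every family member reporting depth,

followed by a report restriction to the consequence classes actually tabled
(default: missense). Every threshold and policy is a `CascadeConfig` field;
missing genotypes are handled conservatively (`strict_drop`) by default. The
cascade emits a per-variant `FilterTrace` naming the stage that removed each
variant, with telescoping per-stage counts.

The screens then ask the complementary questions: do the candidates touch an
8-gene thrombophilia panel or the 16 genes associated with thrombotic primary
APS; do they match a catalogue of variants previously associated with APS
(rsID-anchored; rsIDs are authoritative when present on both sides); and what
does the β2-glycoprotein I gene (APOH) carry in the *pre*-cascade
affected-shared set, where common/benign variation stays visible.

## Worked example

The packaged fixture reconstructs the candidate table of a published APS
family study (two triple-aPL-positive siblings, unaffected father) plus
distractor records that each fail exactly one filter:

```
$ triosift simulate --fixture table3 --out demo/fixture
$ triosift filter --vcf demo/fixture/family_study.vcf \
    --ped demo/fixture/family_study.ped \
    --annotations demo/fixture/family_study_annotations.tsv --out demo/run
frequency: 39 -> 30
affected_sharing: 30 -> 30
unaffected_carrier: 30 -> 27
class_consequence: 27 -> 27
depth: 27 -> 27
report: 27 -> 27
candidates: 27
```

Of 39 input variants, the frequency stage removes the 9 common ones (six
shared APOH polymorphisms and three thrombophilia-gene polymorphisms), the
unaffected-exclusion stage removes the 3 rare variants also carried by the
father, and 27 heterozygous missense candidates remain — the count the study
reports. `demo/run/` holds `candidates.tsv`, the per-variant `trace.tsv`, and
a `manifest.txt` with the full configuration snapshot:

```
gene	full_name	rsid	chrom	pos	transcript	effect	zygosity_PT1	zygosity_PT2
CROCC	Ciliary rootlet coiled-coil/Rootletin	rs1444279934	1	17270657	NM_014675.3	missense (p.Gln624Leu)	Het	Het
HSPG2	Heparan sulfate proteoglycan 2	rs766963773	1	22207015	NM_005529.5	missense (p.Arg679His)	Het	Het
...
```

The screens reproduce the study's negative and gene-level findings:

```
$ triosift screen --vcf ... --ped ... --annotations ... --panel thrombophilia --gene APOH
panel thrombophilia: 0 hit(s) / 27 variant(s) screened
gene APOH: 6 shared variant(s)
  17:64208101 A>G af=0.12 (common) class=benign
  ...
```

(The six APOH records are synthetic stand-ins with the study's stated
properties — shared, common, benign — since the individual SNPs were not
published.) `triosift simulate --planted 5 --seed 42 --out d` generates a
random family dataset whose `truth.tsv` lists the planted candidates and each
distractor's designed failure stage; `triosift report` runs cascade plus every
packaged screen in one pass.

## Layout

- `src/triosift/variant_model.py` — domain types, VCF/sidecar/candidate-table I/O
- `src/triosift/pedigree.py` — PED parsing and design validation
- `src/triosift/cascade.py` — the five filters, configuration, trace
- `src/triosift/panel_screen.py` — panels, known-variant catalogue, gene report
- `src/triosift/synthetic_data.py` — generator with truth table; study fixture
- `src/triosift/cli.py` — `simulate` / `filter` / `screen` / `report`
- `src/triosift/data/` — packaged panels, catalogue, aliases, transcription

See `docs/methods.md` for modeling assumptions, defaults, and limitations.
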