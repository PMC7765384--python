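# Methods

## Problem and model

The package formalizes a family-based WES screening strategy for a disease
with unclear genetic architecture: given genotyped affected siblings and an
unaffected parent, reduce an exome's worth of variants to a short list of
rare, protein-affecting variants that segregate with the phenotype. The
implied inheritance model is a shared dominant-acting rare allele: every
affected member must carry at least one alt allele and no unaffected member
may carry one. No statistical segregation evidence (LOD scores, association
tests) is computed — with two affected and one unaffected sample there is no
power for that; the cascade is a deterministic sieve, and prioritization past
it is biological (panels, literature).

Each of the five filters is a pure per-record predicate, so the surviving set
is invariant under any ordering of the stages; the published order
(frequency → sharing → unaffected exclusion → class/consequence → depth) is
kept as the default because the provenance trace — which stage removed each
variant, with telescoping counts — is part of the output and should match how
such pipelines are described.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `af_threshold` | 0.01 | fraction | the conventional rare-variant cut-off; comparison is strict (<), so AF exactly 1% is removed |
| `missing_af_passes` | true | — | a variant absent from the population resource is treated as novel, hence rare |
| `excluded_classes` | benign, likely_benign | 5-tier scale | candidate workflows conventionally keep VUS and above; the literal benign-only reading is one flag away |
| `allowed_consequences` | missense, nonsense, frameshift, splice_region, inframe_indel | — | "affects protein function"; synonymous/UTR/intronic are removed here |
| `report_consequences` | missense | — | the reported table class; layered separately because the protein-affecting filter is broader |
| `min_depth` | 20 | reads | the usual minimum coverage for a confident germline call; ≥ passes at the boundary |
| `*_missing_gt_policy` | strict_drop | — | an unverifiable genotype removes the variant (a missing call neither proves sharing nor proves absence in the control); `lenient_keep` implements the permissive reading |
| `snv_only` | false | — | restricts to single-nucleotide variants when set; by default indels are governed by the consequence filter rather than removed a priori |

Missing classification is treated as *uncertain significance* (kept): absence
of a pathogenicity assertion is not evidence of benignity. Depth is enforced
per family member; a record with no depth assertion anywhere is kept with a
warning, because absent DP fields make no coverage claim (in the source
workflow coverage was verified by inspection outside the VCF).

Variant identity everywhere is `(chrom, pos, ref, alt)` on GRCh37/hg19;
rsIDs are annotation only. In known-variant matching, rsIDs are authoritative
when present on both sides (coordinate agreement never overrides an rsID
mismatch); catalogue entries without an rsID match on coordinates, and
haplotype-style entries with no point coordinate match at gene level only —
a documented limitation, since haplotype calling is out of scope.

## Synthetic data: what it emulates and what it does not

`generate_family_vcf` emulates the statistical structure the cascade assumes:
biallelic SNVs on autosome-named contigs, a frequency spectrum split around
the 1% cut-off (rare candidates log-uniform on 1e-5–5e-3, with 20% of records
lacking AF; common distractors uniform on 0.05–0.5), Gaussian depths (mean
100×, floor 30×) so only the designed low-depth class dips below 20×, and a
configurable family (default two affected + one unaffected). Planted
candidates satisfy all five predicates; each distractor class violates
exactly one (common AF; not shared; carried by the control; benign/likely
benign; silent consequence; low depth), giving an exact expected output — the
truth table — for any seed. Generation is fully deterministic per seed:
a single seeded generator, records sorted by coordinate at emission, so
outputs are byte-identical across runs and refactors.

It does **not** emulate linkage disequilibrium, recombination, mutation-rate
heterogeneity, multi-allelic or indel-rich loci, genotyping error, or reads
(no FASTQ/BAM). Passing the planted-truth property therefore shows the
cascade implements its rules exactly; it does not show robustness to
real-exome artifacts such as miscalled genotypes at the sharing stage.

The study fixture reconstructs the published 27-candidate table (25 genes;
one gene contributes three adjacent SNVs) with the printed coordinates,
rsIDs, transcripts and protein changes, heterozygous in both siblings and
hom-ref in the father (the publication prints zygosity only for the affected;
hom-ref for the father is the assumption consistent with the exclusion step).
Allele frequency (1e-4), classification (uncertain) and depth (100×) for
these rows are synthetic fixture metadata chosen safely inside every filter's
passing region — the publication prints none of them. Ref/alt bases come from
the printed allele pairs, or from the HGVS c. string for rows printed without
one. Distractors (six common benign APOH variants shared by the siblings,
three common thrombophilia-gene polymorphisms in all three members, three
father-carried rare missense variants) make the fixture cascade a real
filtering problem rather than a pass-through; APOH distractor coordinates
deliberately avoid the catalogued APOH missense position so the
known-variant screen stays a true negative. The six APOH records are
synthetic stand-ins: the study states their properties (shared, common,
benign) but not their identities.

## Numerical and design choices

- **Multi-allelic decomposition** is a naive per-alt split with genotype
  remapping (selected alt → 1, everything else → 0) and no left-realignment;
  adequate for SNVs, a documented limitation for complex indels.
- **Ordering** is numeric-then-lexicographic on chromosome (1–22, X, Y, MT,
  then others), then position, ref, alt.
- **Degenerate inputs**: an empty VCF body yields zero candidates with all
  stage counts zero; a design with zero unaffected members makes the
  exclusion stage the identity; validation is fatal (with the offending
  sample named) when a design sample is missing from the VCF or no affected
  sample exists.
- **Trace vocabulary**: survivors carry stage `none`; variants surviving all
  five filters but outside the reported consequence class carry stage
  `report`, keeping "stage = none ⇔ in the candidate table" exact.
- **Screens and the cascade**: `screen` / `report` match panels and the
  known-variant catalogue against the *post*-cascade candidates (the
  question being "does anything reported touch these genes"), while the
  gene-level report runs on the *pre*-cascade affected-shared set so common
  and benign variation remains visible; its output is therefore invariant to
  cascade configuration.
- **Annotation transport**: INFO keys (configurable names) and sidecar TSV
  are both supported; on conflict the sidecar wins with a warning, keeping
  the VCF dialect simple and the authoritative annotations reviewable as a
  table.

## Problem sizes

The test suite and acceptance script run entirely on generated data: the
39-record fixture, generator runs of 35–140 records across 20 seeds, 100
random sets of up to 200 records for brute-force equivalence, and 120 stage
permutations on 10 sets of 25 records — sizes chosen so the whole suite
completes in seconds while still exercising every filter dimension. The
filters are linear scans; exome-scale inputs (tens of thousands of records
after joint calling) pose no algorithmic difficulty.

## Known limitations

Single-alt SNV-centric normalization (no left-alignment, no compound-het
phasing, no de novo calling); autosomal logic only (no sex-chromosome-aware
inheritance); the population AF is a single configurable field, with no
distinction between global and population-maximum AF; consequence and
pathogenicity annotations are consumed, never predicted; sequencing-level
quality metrics beyond per-sample DP (genotype quality, allele balance) are
not modeled.
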