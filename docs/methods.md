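# Methods

## Scope and model

`xenoprio` prioritizes genes from a curated panel — detoxification enzymes
(DET) and regulators of blood–brain-barrier (BBB), placental (PLC) and
respiratory-cilia (RC) permeability — by combining two independent evidence
streams over case/control cohorts: rare predicted-damaging single-nucleotide
variants enriched in cases, and copy-number-variant carrier burden. The
package consumes *annotated* variants (VEP-style consequence terms, impact
classes, SIFT and PolyPhen-2 labels) and CNV *calls*; it never runs the
annotators or callers, and it takes gene models (symbol, chromosome,
0-based half-open span) as an explicit input because CNV–gene overlap
results depend on the annotation release used.

## SNV prioritization cascade

Stages run in a fixed order; a variant records the first stage that
rejected it, so stage counts always reconcile with the input count.

1. **Genotype QC** (when genotype-level data is available): genotypes with
   depth < `min_depth` (default 8 reads) or genotype quality < `min_gq`
   (default 21, i.e. GQ ≤ 20 fails) are set to missing; a variant whose
   missingness then exceeds `max_variant_missingness` (default 0.10) is
   dropped, and otherwise its case AC/AN are recomputed from the surviving
   genotypes. When only AC/AN summaries exist the QC stage is recorded as
   *not assessed*, never silently passed.
2. **Reference frequency ceiling**: variants with reference-cohort MAF
   above `max_reference_maf` (default 0.05) are removed. MAF is
   allele-based (AC/AN) throughout, matching reference-database convention.
3. **Consequence triage**: loss-of-function = {frameshift, start loss, stop
   loss, stop gain, splice donor/acceptor} with HIGH impact; candidate
   missense = `missense_variant` with MODERATE impact. Start-loss is
   handled on the LoF side only and never double-counted as missense; a
   start-loss record arriving with MODERATE impact is excluded. Unknown
   terms are logged and excluded, never fatal.
4. **Deleteriousness gate** (missense only): SIFT *deleterious* AND
   PolyPhen-2 *probably* or *possibly damaging*. Numeric scores are parsed
   and stored for reporting but filters act on labels only; a missing or
   *unknown* prediction fails the gate.
5. **Case enrichment, internal controls**: pass *exclusive* iff the
   alternate allele is absent from controls and present in cases; pass
   *ratio* iff present in both and MAF_case/MAF_ctrl strictly exceeds
   `enrichment_ratio` (default 1.5). A zero control MAF is always routed to
   the exclusive path, so every pass has a well-defined mode and no
   infinite ratios arise.
6. **Case enrichment, reference cohort**: the same rule against the large
   reference cohort by default (`reference_rule="same"`); an
   `exclusive_only` switch restricts the reference stage to absence. A
   variant is labelled *exclusive* overall only when it is absent from
   every configured comparison cohort; otherwise the mode is *ratio*.

"Unique SNV" means a distinct (chrom, pos, ref, alt) key regardless of
carrier count. Multi-allelic VCF records are decomposed per alt allele
before any filtering, since every rule is per-allele. Sex-chromosome AN
adjustment and imputation are out of scope (documented simplification).

## CNV carrier burden

A subject is a carrier for a gene when ≥ 1 of their CNVs overlaps the gene
footprint by ≥ 1 bp (0-based half-open; chromosome names normalized by
stripping a leading `chr`). DEL and DUP are pooled — a subject with both in
one gene is one carrier — and a subject counts at most once per gene per
cohort. Rarity filtering precedes counting, in either of two modes:
`dataset_freq` keeps calls with dataset frequency strictly below 0.01;
`common_region_overlap` keeps calls whose length-fraction overlapping
population regions of frequency ≥ 0.01 is ≤ 0.50.

Genes with case carriers and zero control carriers are reported on the
**exclusivity** path. Genes with carriers on both sides are tested one-tailed
(H₁: p_case > p_ctrl) with the **unpooled** Wald statistic

    z = (p̂₁ − p̂₂) / sqrt( p̂₁(1−p̂₁)/n₁ + p̂₂(1−p̂₂)/n₂ ),

upper-tail standard-normal p, no continuity correction. The unpooled form
(rather than the pooled null-variance estimate a textbook test would use)
is deliberate: it is the form consistent with the published per-gene
statistics this package reproduces in its acceptance tests — the pooled
form disagrees at the second decimal and beyond on the same counts — and
the no-continuity-correction choice follows for the same reason. Bonferroni
correction uses m = the number of genes *actually tested* in that dataset
(not the panel size): p_adj = min(1, m·p_raw), significance at α = 0.05.
Each case cohort is analyzed separately against the shared control cohort
and the per-cohort exclusive/significant sets are intersected.

### Calibration of the unpooled test

At the null design used in validation (equal carrier probability 0.01,
n_case = 500, n_ctrl = 2,000), exact enumeration over the binomial null
gives a one-sided type-I error of **0.0253** at nominal 0.05: count
discreteness makes the unpooled test *conservative* here (the pooled
statistic would give 0.056). The suite asserts the empirical rate matches
this exact value within Monte Carlo error and stays below nominal, and that
the Wald p ranks ≥ 500 random small tables the same way as a Fisher-exact
oracle (Spearman ρ ≥ 0.95; observed ≈ 0.99). Rank agreement is the relevant
guarantee, because gene prioritization depends on ordering and a fixed
threshold, not on exact tail digits.

## High-evidence classification

Each panel gene receives exactly one label, in precedence order: **C1** —
≥ 1 prioritized SNV and ≥ 1 CNV signal (exclusive or enriched), with no
minimum SNV count; **C2** — ≥ 5 unique prioritized SNVs; **C3** — CNVs
exclusively in cases; **C4** — Bonferroni-significant carrier excess; else
**none** (including genes with 1–4 prioritized SNVs and no CNV evidence).
CNV evidence from any case cohort suffices; exclusivity outranks enrichment
so the partition stays disjoint. The partition is a pure function of the
per-gene evidence, order-independent and idempotent; ablation tests confirm
that removing CNV evidence can only move genes toward {C2, none} and
removing SNV evidence toward {C3, C4, none}.

Maternal transmission is reported per *subject*, not per variant: a proband
is assessed iff maternal genotype data exists and the proband carries ≥ 1
prioritized variant in a detoxification-category high-evidence gene, and is
counted maternal iff the mother carries at least one of those variants. The
denominator is exposed in the output because different subset definitions
change it.

## Interaction mapping

Records are filtered to one organism (case-insensitive, trimmed string
equality; default *Homo sapiens*) and joined to the chemical whitelist
strictly by MeSH ID — names are display-only. Pairs are unique per
(gene, MeSH ID); the weight is the cardinality of the union of PMIDs across
the pair's records. Pairs supported only by records without publication
identifiers are kept with weight 0 and flagged, rather than dropped, since
curated interactions without listed references are a real feature of such
databases. Degrees and the genes × chemicals matrix order axes by degree
descending with alphabetical tie-break; zero-degree chemicals stay on the
axis (renderers may suppress them). Pair counts are snapshot-dependent, so
the pipeline records input file hashes in its run summary. Interaction-type
semantics and mixture effects are out of scope.

## Synthetic cohorts and what validation shows

The generator draws allele counts binomially from configured MAFs (cases,
internal controls, reference), CNV carriage Bernoulli per subject, maternal
carriage Bernoulli at the configured transmission probability, and
interaction records with planted per-gene degrees; everything derives from
one seeded `numpy` Generator, so a seed reproduces the study byte-for-byte,
and all outputs are written in exactly the dialects the readers consume.
Default toy scale: a 20-gene panel (8 DET / 5 BBB / 4 PLC / 3 RC),
n_case = n_ctrl = 500, n_reference = 5,000, CNV cohorts 500 vs 2,000,
200 trios — the full pipeline runs in about a second, which is also why the
validation suite can afford 50 independent seeds.

The default strong-effect design plants one gene per evidence route (plus a
second C2 and C4 gene, and a below-threshold SNV gene that must stay
unflagged): exclusive SNVs at case MAF 0.01, exclusive CNVs at carrier
probability 0.02, enriched CNVs at 0.10 vs 0.01, all chosen so the planted
class is recovered deterministically up to binomial tail events of order
10⁻⁴ (e.g. P(no case carrier) = 0.98⁵⁰⁰ ≈ 4·10⁻⁵). A gene with equal-rate
CNVs in both cohorts but a common dataset frequency (5%) exercises the
rarity filter end-to-end.

Two deliberate design points:

* **Background variants in the default design are benign-only.** An
  equal-frequency *damaging* background variant crosses the case-enrichment
  rule at that rule's inherent false-positive rate (≈ 1% per variant at
  these cohort sizes) and would occasionally promote a CNV-only gene to C1,
  making the planted truth non-deterministic. The planted truth must be
  derivable from the configuration alone, so the recovery benchmark keeps a
  benign background; equal-MAF damaging backgrounds remain available via
  `baseline_null_damaging_variants` and are used in the null-design tests,
  where the *gene-level* false-flag rate is what matters.
* **Genotype-level output is optional** (AC/AN summaries are always
  emitted), so both QC paths — genotype-level masking and summary-only
  "not assessed" — are exercised.

Passing these tests shows the pipeline's rules, bookkeeping and statistics
are implemented correctly under the stated sampling model. It does not show
robustness to properties real cohorts have and the generator omits:
linkage disequilibrium, realistic site-frequency spectra, batch effects
between cohorts, annotation disagreement between tools, or CNV boundary
uncertainty.

## Numerical and degenerate-input conventions

AN = 0 in a compared cohort is an error ("no_called_alleles"), never a zero
MAF. A burden test with zero case carriers returns a flagged not-applicable
result; zero control carriers is a contract violation (such genes belong on
the exclusivity path). Carrier percentages are reported to 1 decimal (3 for
the exclusivity tables); z to 2 decimals in tabular output, full precision
in memory. Enrichment and rarity inequalities are strict exactly where
stated (ratio > 1.5, frequency < 0.01, overlap ≤ 0.50). Readers either
yield a typed record or raise a named error per row — rows are never
silently dropped — and writers emit UTF-8 TSV that round-trips through the
corresponding reader.
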