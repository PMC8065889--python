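# Methods

## The calling model

The caller is deliberately rule-based, not probabilistic. Whole-genome
amplification of a few laser-captured gland cells distorts allele balance
enough that a binomial error model would be miscalibrated anyway; the two
count rules are transparent and auditable:

* **Presence.** `alt_reads >= min_alt_reads` (default 2). The threshold is
  read inclusively: exactly two alt reads qualify.
* **Absence.** `depth > min_ref_depth_for_absence` (default 20, strict:
  21× qualifies, 20× does not) **and** zero non-reference reads. "No change
  of nucleotides" is interpreted as zero reads for *any* non-reference
  allele, i.e. `alt_reads == 0 and other_reads == 0`, not merely zero reads
  of the candidate alt.
* **Somatic.** Present in tissue and positively absent in blood. When the
  tissue is positive but blood absence cannot be established (shallow or
  not clean), the call is `indeterminate` and surfaced as such in the
  call-status table — absence must be demonstrated, never assumed.

There is no VAF ceiling: low allele frequency (<10%) is an observed
property of this material, not a filter. A configurable gnomAD ceiling
exists (`max_population_af`) but defaults to annotate-only. Multi-allelic
evidence is handled by decomposition: each candidate alt allele is its own
record with its own counts.

Compartment assignment is per (patient, locus, alt): somatic in ≥1 ectopic
replicate only → `ECT`; eutopic only → `EU`; both → `BOTH`. Per-compartment
burden excludes `BOTH` variants (the bundled cohort's 24/31 split likewise
excludes its 4 shared variants; 24 + 31 + 4 = 59).

The non-silent filter always removes synonymous records. Its default mode
keeps UTR/intronic/upstream records, matching how the bundled cohort table
was curated (it contains UTR and deep-intronic rows among its 59
"non-silent" variants — an inconsistency we preserve rather than resolve);
`strict=True` removes them too, and the CLI reports the reduced count when
that mode is chosen.

## ADS verification

Candidates are re-sequenced at >2000× over all available replicates,
including WGA replicates that never entered discovery sequencing. Detection
per replicate requires `alt_reads >= 2` **and** `VAF >= 0.5%`: at 2500×,
two reads are 0.08% — indistinguishable from a 0.1% per-base error rate —
so the VAF floor is what separates signal from noise at this depth. Both
knobs live in `CallerConfig`. A variant detected in ≥1 replicate is
`confirmed` (detection in any replicate suffices, which is how one-of-two
outcomes are treated as confirmations); detected in 0 of ≥1 it is
`excluded`; with no ADS data it is `unevaluable`.

## The exact test

`fisher_exact_2x2` enumerates the full hypergeometric support of the
top-left cell with margins fixed, computing point probabilities via
log-gamma (no factorial overflow; the support is renormalised to sum to 1).
The two-sided p-value follows the minimum-likelihood rule — sum every table
whose point probability is ≤ the observed table's, with a 1e-7 relative
tolerance for floating-point ties (the convention of mainstream scientific
software). One-sided alternatives are exposed but non-default. Tests check
the implementation against exact rational brute-force enumeration and
against `scipy.stats.fisher_exact` on random tables; neither oracle is used
in the implementation path. Reported p-values are rounded to 4 decimals,
mutation chances to 3.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes, with
known truth:

| parameter | default | rationale |
|---|---|---|
| `coverage_mean` | 159× | discovery-sequencing mean depth |
| `coverage_dispersion` | 0.7396 | NB size; with mean 159 puts P(depth ≥ 20) at 82%, matching the reported on-target fraction (fixed by a one-off root search on the NB survival function) |
| `somatic_vaf_range` | (0.01, 0.10) | all observed somatic variants sat below 10% VAF |
| `ads_coverage_mean` | 2500× | verification depth (>2000× design) |
| `seq_error_rate` | 0.001 | typical Illumina per-base substitution rate |
| `wga_artifact_rate` | 0.5 / replicate | order-of-magnitude choice: artifacts must be common enough that verification matters (most tissue-shared candidates in the cohort failed it), but no measured rate exists |
| `wga_dropout_prob` | 0.1 | order-of-magnitude choice for allelic dropout of a true variant in one replicate |
| `n_germline_per_patient` | 30 | a token heterozygous background (real panels carry thousands; the count only needs to exercise the blood-positive path) |
| `n_somatic_ect/eu/shared` | 2/2/1 | per-patient scale of the cohort (24/31/4 over 13 patients) |
| `n_null_per_patient` | 20 | variant-free sites so false-positive rates are measurable |

Germline sites are heterozygous (alt reads binomial at VAF 0.5 in every
sample); homozygous sites are omitted since they never affect somatic
logic. Somatic sites draw alt reads binomially at their true VAF in the
carrying compartment's replicates and at `seq_error_rate` elsewhere. WGA
artifacts are replicate-private false variants — the mechanism that makes
replicate re-sequencing informative — and do not reproduce in ADS data,
where they appear only at the error rate. Dropout zeroes the alt reads of
one randomly chosen carrying replicate. Depth is negative-binomial per site
and sample; ADS depth is Poisson. A single global seed with fixed
`(seed, patient, stream)` substreams makes every patient independently
reproducible.

What the simulator does *not* model: read-level data (no FASTQ/BAM, no
mapping or base-quality structure), indel-specific error processes, GC or
capture bias beyond global overdispersion, phasing, and contamination.
Passing tests therefore demonstrate the correctness and calibration of the
downstream rules and statistics under the stated noise structure — not
performance on raw reads.

## Bundled data and its provenance limits

The cohort variant table (59 rows) is transcribed as printed: sample label,
gene, transcript, HGVS, gnomAD AF. Genomic coordinates are **not** part of
the source table; the loader synthesises deterministic placeholder loci
(CRC32 of gene + HGVS inside the gene's synthetic panel region) and parses
ref/alt from the cDNA change, so coordinate-level results (recurrence by
locus, VCF round-trips) are internally consistent but not mappable to a
reference genome. The panel (1296 genes) and the 85-gene driver list are
synthetic reconstructions: 55 real symbols from the table plus labelled
filler symbols, with driver flags chosen so that the per-class variant
counts are 5/19 (ectopic) and 2/29 (eutopic). KRAS, TP53 and ATRX are
known drivers here; ERBB3, BRIP1 and CASP8 complete the flags as plausible
endometrial/ovarian-cancer drivers, but individual flags beyond the first
three are reconstructions, as the `_synthetic` filenames indicate. The ADS
count fixture likewise reproduces the reported per-replicate detection
patterns with invented depths at the >2000× scale.

## Numerical and design choices

* Coordinates: 1-based fully-closed in VCF and count tables; BED half-open
  0-based. HGVS strings are carried verbatim (percent-encoded in VCF INFO);
  there is no HGVS validation or normalisation engine.
* Consequence classes are derived from HGVS patterns only: protein-level
  notation wins (fs → frameshift, gained stop → nonsense, in-frame del/dup →
  inframe_indel); cDNA-only descriptions classify by position, with intronic
  offsets ≤8 bp from the exon treated as splice-region.
* Gene symbols compare case-insensitively after uppercasing.
* VCF floats are 32-bit; VAF and gnomAD AF are rounded on read (6 and 8
  decimals) so write→read round-trips are exact at the stored precision.
* Zero depth makes VAF an error, not 0; a 2×2 test with an empty margin is
  an error, not p = 1.
* Problem sizes in tests (e.g. 10,000 depth draws for the coverage check,
  20 seeds for threshold-monotonicity, 200 random tables against the
  enumeration oracle) were chosen as the smallest sizes at which the checked
  statistics are stable at the stated tolerances.

## Known limitations

Real-cohort quantities that depend on unreleased raw sequencing data (the
159× observed coverage, per-patient discovery of the 59 variants) cannot be
recomputed; they enter only as generator calibration anchors and bundled
tabulated results. The driver-flag reconstruction means gene-level driver
identities beyond KRAS/TP53/ATRX should not be quoted from this package.
The caller's rules are intentionally simple; sites where blood coverage
hovers near 20× are systematically indeterminate rather than rescued by a
statistical model.
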