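# Methods

This note documents the models and procedures implemented in `pequant`, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Amplicon read preprocessing

Reads arrive as single-end Phred+33 FASTQ with a 20-nt sample barcode carried
in a `BC:` header tag (the sequenced insert itself starts at amplicon
position 0, which the amplicon-primer design guarantees). The pipeline order
is fixed and every read ends in exactly one bin:

1. **Demultiplexing.** A read is assigned to the unique sample whose barcode
   is within hamming distance 1 of the read barcode. A read within distance
   1 of zero or of two or more references is left unassigned — sample
   identity is never guessed. The spec validator therefore requires pairwise
   barcode distance ≥ 3, which makes distance-≤1 assignment provably
   unambiguous; the tie guard still exists for malformed inputs.
2. **Quality masking.** Base calls with Phred quality strictly below 30 are
   replaced by `N`. Qualities are retained; masking is idempotent. Only
   Phred+33 input is accepted; files whose decoded qualities exceed 60 are
   rejected as mis-encoded rather than silently mis-masked.
3. **Ambiguity filter.** The fraction of `N` among read positions mapping
   (ungapped, from the position-0 anchor) to the reference interval
   ±40 bp around the edit site — 81 positions when fully inside the
   amplicon — must not exceed 10% (strict `>` discards). The two-sided
   interval is a documented choice; the filter precedes alignment, so the
   mapping is deliberately ungapped. Reads too short to cover the interval
   are discarded as `no_coverage`.
4. **Seed filter.** The first 40 read bases are compared ungapped to the
   first 40 amplicon bases. `N` positions are excluded from both numerator
   and denominator ('masked' means non-informative, not mismatched); a seed
   with more than half `N` is discarded outright. Identity strictly below
   90% discards (identity exactly 0.90 is kept). The seed must not overlap
   the nick or edit sites; the target spec is validated against this
   (designs place them ≥ 75 bp from the read start).

## Global alignment

Kept reads are aligned to the wild-type amplicon with the Needleman–Wunsch
algorithm under Gotoh's affine-gap formulation: match +1, mismatch 0, gap
open −3 (charged to the first gapped position), gap extension −1, end gaps
penalized (true global mode). The fill runs in a numba-compiled kernel
(three float64 matrices); scores with these integer parameters are exact in
floating point, so traceback decisions compare exactly.

Open numerical choices, fixed here so classification is deterministic:

* **Tie-breaking.** When optima tie, traceback prefers diagonal, then
  vertical (read base over reference gap, i.e. insertion), then horizontal.
  Within a gap, ties between extending and closing resolve toward closing
  (the shorter gap).
* **Left-normalization.** Indel events are shifted to their leftmost
  equivalent placement against the reference (bounded by the previous
  event), so equivalent alignments of the same molecule yield identical
  event sets regardless of traceback details.
* **Masked bases.** `N` scores as a mismatch during the DP but an aligned
  column whose read base is `N` never becomes a substitution event: masked
  bases cannot create spurious errors (nor rescue a precise call — a masked
  edit base makes the read indistinguishable from WT and it is classified
  WT).

Alignments are cached by read sequence within an embryo; amplicon reads are
highly redundant, so typically well under 10% of reads require a fresh DP.

## Outcome classification

Classification windows are anchored at the nicks: method 1 uses the 40-nt
pegRNA-nick window [nick−18, nick+22) plus the 34-nt secondary-nick window
[secondary−17, secondary+17); method 2 uses the primary window only.
Windowing suppresses the influence of spontaneous background SNPs far from
the edit site. Event-window membership uses half-open interval arithmetic:
substitutions and deletions belong to a window iff they overlap it, and an
insertion belongs iff its left-flanking reference base lies inside it.

A read with no informative events in the considered window(s) is **WT**;
exactly the intended edit (compared as normalized events) and nothing else is
**PRECISE**; any other non-empty event set is **ERROR**. Method 1 uses union
semantics: a precise call requires the secondary window to be event-free, so
a read with the intended edit plus a secondary-window change is an error.
Fractions are computed over kept reads (the filters retain the vast majority,
so this matches percentages of total reads in practice). Background
adjustment subtracts the control mean error fraction and clips at zero, since
a sample cannot meaningfully have negative byproduct burden.

One geometric consequence worth knowing: a change falling strictly between
the two windows (the gap between primary end and secondary start) is
invisible to both methods. This mirrors the windowed design itself — the
windows, not the whole amplicon, define the assay.

## Statistical calls

* Control error fractions for a target/method are modeled as normal
  (mean, sample sd with n−1; ≥ 2 controls required). A degenerate zero sd is
  floored at 1e−6 with a warning — small control groups can be degenerate
  and a hard failure would be worse than an effectively-exact test.
* An embryo is *edited* iff its raw precise fraction strictly exceeds 1%
  (the boundary is assigned to unedited — a deliberately strict reading).
* Error significance is a one-sided upper-tail z-test (excess errors only)
  with Bonferroni correction at family-wise alpha 0.001. The family size
  defaults to the number of embryos called in the same batch and can be
  overridden; the choice of family is a reporting convention, not a property
  of the data.
* Group comparisons implement the pooled-variance Student and Welch
  t-statistics in closed form with group variances floored at (1e−6)², so
  zero-variance groups remain testable; on non-degenerate inputs the results
  match `scipy.stats.ttest_ind` to ~1e−10 (a property test enforces this).
  The sample (n−1) variance is used throughout.
* Predicted-vs-observed correlation is Pearson's r with the two-sided
  t-based p on n−2 degrees of freedom, plus the least-squares fit for
  plotting.

## Family WGS analysis

The input is a joint-genotyped multi-sample VCF with per-sample GT/DP/AD and
a pedigree table assigning each sample a role (parent, control offspring,
treated offspring). Multiallelic records are decomposed into biallelic rows
— genotypes carrying a *different* alternate allele are coded distinctly and
disqualify uniqueness — and indels are left-aligned before any rule is
applied, because the uniqueness and adjacency rules are allele-level.

A **unique variant** requires: depth ≥ 30 in *every* sample at the site; a
non-reference genotype call in exactly one sample with all others called
homozygous-reference (a missing call disqualifies — absence of evidence is
not reference); carrier VAF = AD/DP ≥ 0.2; autosomal location (the excluded
list covers X/Y aliases and the mouse RefSeq sex-chromosome accessions).
"Detected" is defined by the genotype call, not raw allele support, and the
VAF threshold applies to the single carrier.

Indels are typed by signed size (len(alt) − len(ref)); equal-length
multi-nucleotide changes are counted with SNVs since only the SNV/indel
distinction matters downstream. A unique −1 bp deletion is
*homopolymer-adjacent* when, after left-normalization, the deleted base lies
in or immediately abuts a run of ≥ 4 identical A or T bases. The tract
threshold of 4 is configurable; 4 is the shortest run length at which
polymerase slippage becomes the dominant mechanism for single-base deletions,
and shorter runs would flag essentially random context. Samples with zero
−1 bp deletions report an undefined (None) fraction rather than 0 — absence
of deletions is not evidence of absent tract bias.

Region checks count variants whose position falls within [start − pad,
end + pad) of each region: pad 100 bp for predicted off-target sites
(capturing variants near, not only inside, the protospacer match) and pad 0
for microsatellite panels. Fold changes divide each treated sample's
unique-indel count by the mean control count; the treated/control difference
is tested with Welch's t-test on counts (group variances are rarely equal).
A zero control mean leaves folds undefined and flagged rather than infinite.

## Synthetic data

### Embryo read sets

Each read's molecule class is drawn i.i.d. from the configured mixture:
wild type; precise edit; inter-nick deletion (uniform extent over the
inter-nick span, uniform placement — the class is defined by removing at
least some inter-nick sequence, and no distribution is implied beyond that);
"combined" intended edit plus a 3′ deletion of 2–10 nt starting within 5 nt
of the nick; or a 1–3-nt indel at the nick. Substitution noise is i.i.d. per
base (default 5×10⁻⁴, which puts the expected control background at
1 − 0.9995⁴⁰ ≈ 2.0% for the 40-nt window — the low end of the 1–6% band
observed in real unedited embryos). Qualities are two-valued (default
Q37/Q11, 0.2% low) — sufficient to exercise masking behavior, with no claim
of realism. Barcodes receive the same substitution noise. Defaults: 10,000
reads per embryo; a 220-bp amplicon with the pegRNA nick at 100, a +5 G>A
intended edit and a secondary nick at 140, so that nick/edit sit well past
the 40-bp seed and both windows fit.

Ground-truth manifests record the seed, the per-read class and the realized
class counts; every generator is a pure function of (config, seed) and
regenerates byte-identical output.

Not emulated: PCR chimeras and jackpots, indel sequencing errors, read-length
variation, UMI structure, paired ends. Passing recovery tests therefore shows
the pipeline is correct *given* mixture-of-molecules data with substitution
noise — not that real libraries are free of artifacts the generator omits.

In the recovery experiments (20 embryos at depth 10,000 with precise
fractions 0/0.3/0.6/0.9), substitution noise is set to 2.5×10⁻⁴ — the low
end of the control band. This is deliberate: a precise molecule gaining an
in-window noise substitution is correctly demoted to error, so the estimated
precise fraction is biased low by ≈ p·(window − 1)·rate. The recovery
experiment measures mixture recovery, and the noise level is chosen so this
known, rate-proportional demotion (≈ 1 percentage point at p = 0.9) stays
well inside the ±2-point recovery tolerance instead of dominating it. The
background-calibration experiment keeps 5×10⁻⁴, where the same demotion *is*
the quantity under test.

### Family variant tables

A toy reference of two autosome-like chromosomes (120 kb each) and one
sex-like chromosome (60 kb) is seeded with poly(A/T) tracts (3/kb, lengths
4–12, flanked by non-tract bases so each tract is maximal and every planted
tract deletion has a unique left-aligned representation). Planted per
sample: unique SNVs (Poisson mean 120), unique indels (Poisson mean 40 for
controls; treated samples at fold × 40, with 80% of the excess as
tract-adjacent −1 bp deletions), shared multi-carrier SNVs (Poisson mean
60), plus a few deliberately filter-failing variants (low depth, sub-0.2
VAF, sex-chromosome) whose exclusion the tests verify. Control −1 bp
deletions are tract-adjacent 25% of the time; non-tract deletions are placed
only where no A/T run of ≥ 4 is adjacent, so planted truth labels are exact.
Depths are Poisson (mean 100, matching 100–140× genomes); carrier allele
depths are Binomial(DP, VAF) with VAF ~ U(0.35, 0.55), so a planted variant
very occasionally falls below the 0.2 VAF threshold — recovery tests budget
a few such losses. Records are emitted already normalized and biallelic;
loading them back through the VCF reader is change-free (tested).

Not emulated: linkage/phasing, mapping artifacts, systematic coverage
dropout, genotyping error in non-carriers, dinucleotide-repeat slippage.

## Problem sizes used in the checks

The end-to-end checks run at: 500 random pairs (length ≤ 6) against the
exhaustive alignment enumerator; 20 embryos × 10,000 reads for mixture
recovery; 8 control embryos × 10,000 reads for the background closed form;
1,000 null embryos for z-test calibration; 1,000 random 50-variant ×
6-sample tables against the brute-force unique-variant oracle; and 10
simulated families for fold-change and adjacency recovery. These sizes give
each stochastic check comfortable statistical margin while keeping the whole
suite around a minute on one CPU.

## Known limitations

* Reads are assumed to start at amplicon position 0; designs with variable
  offsets (e.g. staggered primers) would need the ambiguity window and seed
  anchored differently.
* The aligner is O(n·m) per unique read sequence and intended for amplicons
  (hundreds of bp), not genomic reads.
* pegRNA scaffold insertions are reported as errors, not subcategorized.
* The background model is per-target/per-method and assumes control error
  fractions are approximately normal; with very few controls the z-test is
  only as good as that approximation.
* Inter-window changes (between the primary and secondary windows) are
  invisible by design, as discussed above.
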