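"""Family-based unique-variant filtering and off-target mutational signatures.

Given a joint-genotyped multi-sample VCF for one family (parents, control
siblings, treated embryos), a *unique variant* is one detected in exactly one
family member, with a minimum depth of 30 aligned reads in every sequenced
member at the position, a variant allele frequency >= 0.2 in the carrier, and
an autosomal location (sex chromosomes excluded).  Unique indels are typed by
signed size; unique −1 bp deletions are checked for direct adjacency to
poly(A/T) homopolymer tracts — the slippage signature expected when mismatch
repair is transiently impaired — and per-family fold-changes of unique-indel
counts in treated vs control members are computed with Welch's t-test.

Multiallelic records are decomposed into biallelic rows and indels are
left-aligned before any rule is applied.  "Detected" means a non-reference
genotype call; non-carriers are additionally required to be called
homozygous-reference.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import ConfigurationError
from .edit_stats import compare_groups

logger = logging.getLogger(__name__)

#: Chromosome names excluded from unique-variant analysis (sex chromosomes);
#: includes common aliases and the mouse GRCm39 RefSeq accessions.
DEFAULT_EXCLUDED_CHROMS = frozenset(
    {"X", "Y", "chrX", "chrY", "NC_000086.8", "NC_000087.8"}
)

#: Default unique-variant thresholds.
DEFAULT_MIN_DEPTH = 30
DEFAULT_MIN_VAF = 0.2
#: Minimum homopolymer run length counted as a poly(A/T) tract.
DEFAULT_MIN_TRACT = 4

#: Genotype codes used in :class:`VariantRecord`.
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1
GT_OTHER_ALT = 3  # carries a different alternate allele of the source record

ROLES = ("parent", "control_offspring", "treated_offspring")


@dataclass(frozen=True)
class VariantRecord:
    """One decomposed, normalized biallelic variant with per-sample evidence.

    ``pos`` is 0-based (converted from the 1-based variant file).  ``dp`` and
    ``alt_ad`` are per-sample arrays ordered as ``samples`` in the table;
    ``gt`` holds the genotype codes above, relative to this alternate allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dp: tuple[int, ...]
    alt_ad: tuple[int, ...]
    gt: tuple[int, ...]

    @property
    def size(self) -> int:
        """Signed length change: + insertion, − deletion, 0 SNV/MNV."""
        return len(self.alt) - len(self.ref)


@dataclass
class FamilyVariantTable:
    """Multi-sample variant table with treatment roles."""

    variants: list[VariantRecord]
    samples: list[str]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for sample in self.samples:
            role = self.roles.get(sample)
            if role not in ROLES:
                raise ConfigurationError(
                    f"sample {sample!r} has invalid role {role!r}; "
                    f"expected one of {ROLES}"
                )

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] != "treated_offspring"]

    @property
    def treated_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "treated_offspring"]


@dataclass
class UniqueVariant:
    """A variant detected in exactly one family member (post-filter)."""

    record: VariantRecord
    carrier_sample: str
    vaf: float
    var_class: str  # 'SNV', 'ins_<k>' or 'del_<k>'
    homopolymer_adjacent: bool | None = None
    tract_base: str | None = None


# ---------------------------------------------------------------------------
# Loading, decomposition, normalization
# ---------------------------------------------------------------------------


def trim_and_shift(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | None = None,
) -> tuple[int, str, str]:
    """Normalize one allele pair: trim shared bases and left-align indels.

    The shared suffix is trimmed first, then the shared prefix (advancing
    ``pos``), always keeping at least one base on each non-empty side.  When a
    reference is supplied, pure indels (anchor-base style) are shifted left
    while the preceding reference base equals the last allele base.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix down to the conventional single anchor base for
    # indels, or to nothing shared for SNV/MNVs
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) != len(alt) and reference is not None:
        seq = reference[chrom]
        # anchor-base indel: ref[0] == alt[0]; slide left while possible
        while (
            len(ref) > 0
            and len(alt) > 0
            and ref[0] == alt[0]
            and pos > 0
            and (
                (len(alt) == 1 and seq[pos] == ref[-1])  # deletion
                or (len(ref) == 1 and seq[pos] == alt[-1])  # insertion
            )
        ):
            pos -= 1
            anchor = seq[pos]
            if len(alt) == 1:  # deletion: rotate deleted bases right
                ref = anchor + ref[:-1]
                alt = anchor
            else:  # insertion
                alt = anchor + alt[:-1]
                ref = anchor
    return pos, ref, alt


def _decompose_site(
    chrom: str,
    pos0: int,
    ref: str,
    alts: Sequence[str],
    dp: np.ndarray,
    ad: np.ndarray,
    genotypes: Sequence[Sequence[int]],
    reference: Mapping[str, str] | None,
) -> list[VariantRecord]:
    """Split a (possibly multiallelic) site into normalized biallelic rows."""
    records = []
    for alt_idx, alt in enumerate(alts, start=1):
        gt_codes = []
        for alleles in genotypes:
            called = [a for a in alleles if a >= 0]
            if not called:
                gt_codes.append(GT_MISSING)
            elif all(a == 0 for a in called):
                gt_codes.append(GT_HOM_REF)
            elif all(a == alt_idx for a in called):
                gt_codes.append(GT_HOM_ALT)
            elif any(a == alt_idx for a in called):
                gt_codes.append(GT_HET)
            else:
                gt_codes.append(GT_OTHER_ALT)
        npos, nref, nalt = trim_and_shift(chrom, pos0, ref, alt, reference)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=npos,
                ref=nref,
                alt=nalt,
                dp=tuple(int(x) for x in dp),
                alt_ad=tuple(int(x) for x in ad[:, alt_idx]),
                gt=tuple(gt_codes),
            )
        )
    return records


def load_family(
    vcf_path: str | Path,
    pedigree: str | Path | pd.DataFrame,
    reference: Mapping[str, str] | None = None,
) -> FamilyVariantTable:
    """Load a joint-genotyped multi-sample VCF plus a pedigree/treatment table.

    The pedigree is a TSV (or DataFrame) with columns ``sample_id`` and
    ``role`` (parent / control_offspring / treated_offspring); every pedigree
    sample must be present in the VCF header.  Per-sample DP and AD FORMAT
    fields are required.  Multiallelic records are decomposed and indels
    left-aligned (against ``reference`` when given).
    """
    from cyvcf2 import VCF

    if isinstance(pedigree, (str, Path)):
        pedigree = pd.read_csv(pedigree, sep="\t")
    roles = dict(zip(pedigree["sample_id"].astype(str), pedigree["role"]))
    vcf = VCF(str(vcf_path))
    missing = [s for s in roles if s not in vcf.samples]
    if missing:
        raise ConfigurationError(
            f"pedigree samples missing from VCF header: {missing}"
        )
    # column order follows the pedigree
    samples = list(roles)
    col_idx = [vcf.samples.index(s) for s in samples]
    variants: list[VariantRecord] = []
    for v in vcf:
        dp = v.format("DP")
        ad = v.format("AD")
        if dp is None or ad is None:
            raise ConfigurationError(
                f"variant {v.CHROM}:{v.POS} lacks per-sample DP/AD fields"
            )
        dp = np.asarray(dp).reshape(len(vcf.samples))[col_idx]
        ad = np.asarray(ad).reshape(len(vcf.samples), -1)[col_idx, :]
        genotypes = [v.genotypes[i][:-1] for i in col_idx]
        variants.extend(
            _decompose_site(
                v.CHROM, v.POS - 1, v.REF, v.ALT, dp, ad, genotypes, reference
            )
        )
    logger.info(
        "loaded %d biallelic variant rows for %d samples from %s",
        len(variants),
        len(samples),
        vcf_path,
    )
    return FamilyVariantTable(variants=variants, samples=samples, roles=roles)


# ---------------------------------------------------------------------------
# Unique-variant filtering
# ---------------------------------------------------------------------------


def variant_class(record: VariantRecord) -> str:
    size = record.size
    if size == 0:
        return "SNV"  # MNVs counted with SNVs
    return f"ins_{size}" if size > 0 else f"del_{-size}"


def find_unique_variants(
    table: FamilyVariantTable,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
) -> dict[str, list[UniqueVariant]]:
    """Unique variants per sample under the four family-filter rules.

    A variant is retained iff (a) every sample has depth >= ``min_depth`` at
    the site; (b) exactly one sample carries a non-reference genotype and all
    others are called homozygous-reference; (c) the carrier's VAF (alt allele
    depth / depth) is >= ``min_vaf``; (d) the chromosome is not excluded.
    """
    out: dict[str, list[UniqueVariant]] = {s: [] for s in table.samples}
    for rec in table.variants:
        if rec.chrom in excluded_chroms:
            continue
        if any(d < min_depth for d in rec.dp):
            continue
        carriers = [i for i, g in enumerate(rec.gt) if g in (GT_HET, GT_HOM_ALT)]
        if len(carriers) != 1:
            continue
        others_ref = all(
            g == GT_HOM_REF for i, g in enumerate(rec.gt) if i != carriers[0]
        )
        if not others_ref:
            continue
        ci = carriers[0]
        vaf = rec.alt_ad[ci] / rec.dp[ci] if rec.dp[ci] else 0.0
        if vaf < min_vaf:
            continue
        sample = table.samples[ci]
        out[sample].append(
            UniqueVariant(
                record=rec,
                carrier_sample=sample,
                vaf=vaf,
                var_class=variant_class(rec),
            )
        )
    return out


def classify_indels(
    uniques: Mapping[str, Sequence[UniqueVariant]],
) -> pd.DataFrame:
    """Per-sample counts of unique variants by class (SNV / ins_k / del_k)."""
    counts = {
        sample: Counter(u.var_class for u in variants)
        for sample, variants in uniques.items()
    }
    frame = pd.DataFrame(counts).fillna(0).astype(int)
    frame.index.name = "var_class"
    return frame.sort_index()


# ---------------------------------------------------------------------------
# Homopolymer adjacency
# ---------------------------------------------------------------------------


def _run_length(seq: str, start: int, step: int) -> int:
    """Length of the homopolymer run extending from ``start`` in ``step`` direction."""
    base = seq[start]
    n = 0
    i = start
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += step
    return n


def is_tract_adjacent(
    seq: str, deleted_pos: int, min_tract: int = DEFAULT_MIN_TRACT
) -> tuple[bool, str | None]:
    """Whether a single-base deletion abuts (or lies in) a poly(A/T) tract.

    Checks the maximal run containing the deleted base, the run beginning
    immediately right of it and the run ending immediately left of it; the
    deletion is flagged when any of these is a run of >= ``min_tract``
    identical A or T bases.  Returns ``(flag, tract_base)``.
    """
    candidates: list[tuple[int, str]] = []
    base = seq[deleted_pos]
    run = (
        _run_length(seq, deleted_pos, -1) + _run_length(seq, deleted_pos, 1) - 1
    )
    candidates.append((run, base))
    if deleted_pos + 1 < len(seq):
        candidates.append(
            (_run_length(seq, deleted_pos + 1, 1), seq[deleted_pos + 1])
        )
    if deleted_pos > 0:
        candidates.append(
            (_run_length(seq, deleted_pos - 1, -1), seq[deleted_pos - 1])
        )
    for run, b in candidates:
        if b in "AT" and run >= min_tract:
            return True, b
    return False, None


def homopolymer_adjacent_fraction(
    uniques: Mapping[str, Sequence[UniqueVariant]],
    reference: Mapping[str, str],
    min_tract: int = DEFAULT_MIN_TRACT,
) -> dict[str, float | None]:
    """Per-sample fraction of unique −1 bp deletions adjacent to poly(A/T) tracts.

    Variants are assumed left-normalized (anchor base + one deleted base).
    Samples with zero −1 bp deletions report ``None`` (undefined), not 0.
    Flags are also stored on the :class:`UniqueVariant` objects.
    """
    fractions: dict[str, float | None] = {}
    for sample, variants in uniques.items():
        one_bp = [u for u in variants if u.record.size == -1]
        if not one_bp:
            fractions[sample] = None
            continue
        n_flagged = 0
        for u in one_bp:
            rec = u.record
            if rec.chrom not in reference:
                raise ValueError(f"chromosome {rec.chrom!r} not in reference")
            seq = reference[rec.chrom]
            deleted_pos = rec.pos + len(rec.alt)  # first deleted base
            if deleted_pos >= len(seq):
                raise ValueError(
                    f"variant at {rec.chrom}:{rec.pos} outside reference"
                )
            flag, base = is_tract_adjacent(seq, deleted_pos, min_tract)
            u.homopolymer_adjacent = flag
            u.tract_base = base
            n_flagged += flag
        fractions[sample] = n_flagged / len(one_bp)
    return fractions


# ---------------------------------------------------------------------------
# Region counts and fold change
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file into (chrom, start, end, name) tuples (0-based half-open)."""
    regions = []
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    for i, row in frame.iterrows():
        name = str(row[3]) if frame.shape[1] > 3 else f"region_{i}"
        regions.append((str(row[0]), int(row[1]), int(row[2]), name))
    return regions


def count_region_variants(
    uniques: Mapping[str, Sequence[UniqueVariant]],
    regions: Sequence[tuple[str, int, int, str]] | str | Path,
    pad_bp: int = 0,
) -> pd.DataFrame:
    """Per-region, per-sample counts of variants within padded intervals.

    A variant counts for a region iff its position lies within
    ``[start − pad_bp, end + pad_bp)``.  Use ``pad_bp=100`` for predicted
    off-target site checks and ``pad_bp=0`` for microsatellite regions.
    """
    if isinstance(regions, (str, Path)):
        regions = read_bed(regions)
    samples = list(uniques)
    counts = pd.DataFrame(
        0, index=[name for _, _, _, name in regions], columns=samples
    )
    counts.index.name = "region"
    for chrom, start, end, name in regions:
        lo, hi = start - pad_bp, end + pad_bp
        for sample in samples:
            counts.loc[name, sample] = sum(
                u.record.chrom == chrom and lo <= u.record.pos < hi
                for u in uniques[sample]
            )
    return counts


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-treated-sample unique-indel fold change vs the control mean."""

    folds: dict[str, float | None]
    treated_counts: dict[str, int]
    control_counts: dict[str, int]
    control_mean: float
    t: float
    p: float
    undefined: bool = False


def indel_fold_change(
    uniques: Mapping[str, Sequence[UniqueVariant]],
    roles: Mapping[str, str],
) -> FoldChangeResult:
    """Unique-indel counts in treated samples relative to the control mean.

    ``fold_s = count_s / mean(control counts)`` for each treated sample; the
    treated/control difference is tested with a two-sided Welch t-test on the
    counts.  A zero control mean leaves folds undefined (flagged).
    """
    def n_indels(sample: str) -> int:
        return sum(u.record.size != 0 for u in uniques[sample])

    treated = [s for s in uniques if roles.get(s) == "treated_offspring"]
    controls = [s for s in uniques if roles.get(s) != "treated_offspring"]
    if len(treated) < 1 or len(controls) < 2:
        raise ConfigurationError("need >= 1 treated and >= 2 control samples")
    treated_counts = {s: n_indels(s) for s in treated}
    control_counts = {s: n_indels(s) for s in controls}
    control_mean = float(np.mean(list(control_counts.values())))
    undefined = control_mean == 0.0
    folds: dict[str, float | None] = {
        s: (None if undefined else c / control_mean)
        for s, c in treated_counts.items()
    }
    t, p = compare_groups(
        list(treated_counts.values()), list(control_counts.values()), "welch"
    )
    return FoldChangeResult(
        folds=folds,
        treated_counts=treated_counts,
        control_counts=control_counts,
        control_mean=control_mean,
        t=t,
        p=p,
        undefined=undefined,
    )
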