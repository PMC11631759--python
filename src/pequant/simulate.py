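"""Synthetic-data generators for embryo amplicon reads and family variant tables.

Two generators emulate the statistical structure of real experiment inputs so
that every pipeline stage can be exercised end to end without external data:

* :func:`simulate_embryo_reads` draws per-embryo read sets (default depth
  10,000) as mixtures of wild-type, precise-edit and byproduct molecules
  (inter-nick deletions, "combined" edit + 3' deletion outcomes, small indels
  at the nick) with i.i.d. per-base substitution noise and a two-valued
  quality model, and records the ground truth of every read in a manifest.

* :func:`simulate_family` builds a toy reference (two autosome-like and one
  sex-like chromosome) seeded with poly(A/T) homopolymer tracts, plants
  shared and per-sample unique variants in a multi-sample VCF, and gives
  treated samples a configurable fold excess of unique indels, a set
  fraction of which are −1 bp deletions abutting A/T tracts — the slippage
  signature of impaired mismatch repair.

All generators are pure functions of (config, seed): the same seed yields
byte-identical FASTQ/VCF output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .amplicon_io import ConfigurationError, Edit, ReadRecord, TargetSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Read-class labels used in manifests, in mixture order.
CLASS_LABELS = (
    "wt",
    "precise",
    "internick_deletion",
    "combined",
    "small_indel",
)


# ---------------------------------------------------------------------------
# Target-spec construction for synthetic loci
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    # reject runs of >=4 identical bases so synthetic amplicons carry no
    # accidental homopolymer tracts that complicate indel normalization
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    out = list(seq)
    for i in range(3, length):
        if out[i] == out[i - 1] == out[i - 2] == out[i - 3]:
            alternatives = [b for b in "ACGT" if b != out[i]]
            out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def make_synthetic_target(
    n_samples: int = 1,
    amplicon_length: int = 220,
    nick_pos: int = 100,
    secondary_nick_pos: int | None = 140,
    edit_offset: int = 5,
    seed: int = 20_240_001,
) -> TargetSpec:
    """A deterministic synthetic target locus with a +5 G>A substitution.

    Mirrors the geometry of typical amplicon designs: the nick and edit
    sites sit >= 75 bp from the read start, the primary classification window
    fits the amplicon, and sample barcodes are 20 nt with pairwise hamming
    distance >= 3.
    """
    rng = np.random.default_rng(seed)
    amp = list(_random_seq(rng, amplicon_length))
    edit_pos = nick_pos + edit_offset
    amp[edit_pos] = "G"
    amplicon = "".join(amp)
    barcodes: dict[str, str] = {}
    while len(barcodes) < n_samples:
        bc = _random_seq(rng, 20)
        if all(sum(a != b for a, b in zip(bc, other)) >= 3 for other in barcodes.values()):
            barcodes[f"S{len(barcodes) + 1}"] = bc
    return TargetSpec(
        name="synthetic_locus",
        amplicon=amplicon,
        nick_pos=nick_pos,
        intended_edit=Edit(kind="substitution", offset=edit_offset, ref="G", alt="A"),
        secondary_nick_pos=secondary_nick_pos,
        barcode_map=barcodes,
    )


# ---------------------------------------------------------------------------
# Embryo amplicon reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbryoSimConfig:
    """Configuration of one simulated embryo read set.

    ``mix`` gives the molecule-class probabilities (wt, precise, inter-nick
    deletion, combined edit + 3' deletion, small indel at the nick) and must
    sum to 1.  ``quality_model`` is (high Phred, low Phred, probability of
    the low value per base).
    """

    spec: TargetSpec
    depth: int = 10_000
    mix: tuple[float, float, float, float, float] = (1.0, 0.0, 0.0, 0.0, 0.0)
    subst_error_rate: float = 0.0005
    quality_model: tuple[int, int, float] = (37, 11, 0.002)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-12:
            raise ConfigurationError("mix probabilities must sum to 1")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if not (0.0 <= self.subst_error_rate < 0.05):
            raise ConfigurationError("subst_error_rate must lie in [0, 0.05)")
        if (
            sum(self.mix[2:4]) > 0.0
            and self.spec.secondary_nick_pos is None
        ):
            raise ConfigurationError(
                "inter-nick / combined byproducts require a secondary nick"
            )


def _add_substitution_noise(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def _make_molecule(
    cls: str, spec: TargetSpec, rng: np.random.Generator
) -> str:
    amp = spec.amplicon
    nick = spec.nick_pos
    if cls == "wt":
        return amp
    if cls == "precise":
        return spec.edited_amplicon
    if cls == "internick_deletion":
        sec = spec.secondary_nick_pos
        span = sec - nick
        length = int(rng.integers(1, span + 1))
        start = nick + int(rng.integers(0, span - length + 1))
        return amp[:start] + amp[start + length :]
    if cls == "combined":
        edited = spec.edited_amplicon
        start = nick + int(rng.integers(0, 5))
        length = int(rng.integers(2, 11))
        return edited[:start] + edited[start + length :]
    if cls == "small_indel":
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            return amp[:nick] + amp[nick + length :]
        insert = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        return amp[:nick] + insert + amp[nick:]
    raise ValueError(f"unknown molecule class {cls!r}")


def simulate_embryo_reads(
    config: EmbryoSimConfig,
    embryo_id: str = "embryo",
    sample_id: str | None = None,
) -> tuple[list[ReadRecord], dict]:
    """Draw one embryo's read set and its ground-truth manifest.

    Each read's true class is drawn from ``mix``; the corresponding molecule
    is constructed from the target spec, i.i.d. substitution noise is applied
    at ``subst_error_rate`` (to the barcode as well), and per-base qualities
    are drawn from the two-valued quality model.  The manifest records the
    seed, per-read truth and realized per-class counts/fractions.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.spec
    if sample_id is None:
        sample_id = next(iter(spec.barcode_map))
    barcode = spec.barcode_map[sample_id]
    q_high, q_low, p_low = config.quality_model
    class_draws = rng.choice(len(CLASS_LABELS), size=config.depth, p=config.mix)
    reads: list[ReadRecord] = []
    per_read: list[str] = []
    for i, ci in enumerate(class_draws):
        cls = CLASS_LABELS[ci]
        molecule = _make_molecule(cls, spec, rng)
        bases = _add_substitution_noise(molecule, config.subst_error_rate, rng)
        bc = _add_substitution_noise(barcode, config.subst_error_rate, rng)
        quals = np.where(
            rng.random(len(bases)) < p_low, q_low, q_high
        ).astype(np.int16)
        reads.append(
            ReadRecord(
                read_id=f"{embryo_id}_r{i}",
                bases=bases,
                quals=quals,
                barcode=bc,
            )
        )
        per_read.append(cls)
    counts = {label: per_read.count(label) for label in CLASS_LABELS}
    manifest = {
        "embryo_id": embryo_id,
        "sample_id": sample_id,
        "seed": config.seed,
        "depth": config.depth,
        "mix": list(config.mix),
        "subst_error_rate": config.subst_error_rate,
        "true_counts": counts,
        "true_fractions": {k: v / config.depth for k, v in counts.items()},
        "per_read_class": per_read,
    }
    return reads, manifest


def expected_error_read_fraction(subst_error_rate: float, window_length: int) -> float:
    """Closed-form chance a wild-type read gains >= 1 substitution in-window.

    ``1 − (1 − rate)^window_length``; the observed error-classified fraction
    of an unedited control converges to this as depth grows (up to the small
    effect of quality masking).
    """
    return 1.0 - (1.0 - subst_error_rate) ** window_length


def simulate_control_cohort(
    spec: TargetSpec,
    n_embryos: int,
    depth: int = 10_000,
    subst_error_rate: float = 0.0005,
    quality_model: tuple[int, int, float] = (37, 11, 0.002),
    seed: int = 0,
    method: int = 2,
    band: tuple[float, float] = (0.01, 0.06),
) -> tuple[list[tuple[list[ReadRecord], dict]], float]:
    """Simulate unedited control embryos with a target background-error band.

    All molecules are wild type; the expected error-read fraction for the
    method's window length (40 nt for method 2, 40 + 34 nt for method 1) is
    computed in closed form and must lie within ``band`` (the 1–6% range seen
    in real unedited controls), otherwise the requested configuration is
    rejected.  Returns the cohort and the expectation.
    """
    if n_embryos < 2:
        raise ConfigurationError("need >= 2 control embryos")
    window_length = 40 if method == 2 else 74
    expected = expected_error_read_fraction(subst_error_rate, window_length)
    if not (band[0] <= expected <= band[1]):
        raise ConfigurationError(
            f"expected error fraction {expected:.4f} outside requested band {band}"
        )
    root = np.random.default_rng(seed)
    cohort = []
    for i in range(n_embryos):
        config = EmbryoSimConfig(
            spec=spec,
            depth=depth,
            mix=(1.0, 0.0, 0.0, 0.0, 0.0),
            subst_error_rate=subst_error_rate,
            quality_model=quality_model,
            seed=int(root.integers(0, 2**31 - 1)),
        )
        cohort.append(simulate_embryo_reads(config, embryo_id=f"control_{i}"))
    return cohort, expected


# ---------------------------------------------------------------------------
# Family WGS variant tables
# ---------------------------------------------------------------------------

DEFAULT_FAMILY_SAMPLES = (
    ("mother", "parent"),
    ("father", "parent"),
    ("ctrl_1", "control_offspring"),
    ("ctrl_2", "control_offspring"),
    ("treated_1", "treated_offspring"),
    ("treated_2", "treated_offspring"),
    ("treated_3", "treated_offspring"),
)


@dataclass(frozen=True)
class FamilySimConfig:
    """Configuration of one simulated family variant table.

    Rates are expected counts per sample (drawn Poisson).  Treated samples
    receive unique indels at ``unique_indel_rate_control × treated_indel_fold``;
    the extra indels beyond the control rate are −1 bp deletions abutting
    A/T tracts with probability ``tract_deletion_fraction``.  ``depth_model``
    is (mean DP, negative-binomial dispersion; dispersion 0 = Poisson).
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 120_000, "chr2": 120_000, "chrX": 60_000}
    )
    sex_chroms: tuple[str, ...] = ("chrX",)
    tract_density: float = 3.0  # tracts per kb
    samples: tuple[tuple[str, str], ...] = DEFAULT_FAMILY_SAMPLES
    shared_variant_rate: float = 60.0
    unique_snv_rate: float = 120.0
    unique_indel_rate_control: float = 40.0
    treated_indel_fold: float = 2.5
    tract_deletion_fraction: float = 0.8
    control_tract_fraction: float = 0.25
    depth_model: tuple[float, float] = (100.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treated_indel_fold < 1.0:
            raise ConfigurationError("treated_indel_fold must be >= 1")
        for rate in (
            self.shared_variant_rate,
            self.unique_snv_rate,
            self.unique_indel_rate_control,
        ):
            if rate < 0:
                raise ConfigurationError("rates must be >= 0")
        if not self.samples:
            raise ConfigurationError("samples must be non-empty")
        roles = [r for _, r in self.samples]
        if roles.count("treated_offspring") < 1 or (
            len(roles) - roles.count("treated_offspring") < 2
        ):
            raise ConfigurationError("need >= 1 treated and >= 2 control samples")


@dataclass
class FamilySimResult:
    """Reference, VCF text, pedigree and truth manifest of one simulated family."""

    reference: dict[str, str]
    vcf_text: str
    pedigree: list[tuple[str, str]]
    manifest: dict
    tracts: list[tuple[str, int, int, str]]  # chrom, start, end, base


def _build_reference(
    config: FamilySimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    reference: dict[str, str] = {}
    tracts: list[tuple[str, int, int, str]] = []
    for chrom, length in config.chrom_lengths.items():
        seq = list(_random_seq(rng, length))
        n_tracts = int(round(config.tract_density * length / 1000))
        occupied: set[int] = set()
        placed = 0
        while placed < n_tracts:
            tract_len = int(rng.integers(4, 13))
            start = int(rng.integers(50, length - tract_len - 50))
            span = range(start - 2, start + tract_len + 2)
            if any(p in occupied for p in span):
                continue
            base = "A" if rng.random() < 0.5 else "T"
            other = "C" if base == "A" else "G"
            # distinct flanks guarantee the tract is maximal and left-alignable
            seq[start - 1] = other
            seq[start + tract_len] = other
            for p in range(start, start + tract_len):
                seq[p] = base
            occupied.update(span)
            tracts.append((chrom, start, start + tract_len, base))
            placed += 1
        reference[chrom] = "".join(seq)
    return reference, tracts


def _has_tract_context(seq: str, pos: int, min_tract: int = 4) -> bool:
    from .wgs_family import is_tract_adjacent

    return is_tract_adjacent(seq, pos, min_tract)[0]


def _draw_depths(
    config: FamilySimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    mean, dispersion = config.depth_model
    if dispersion <= 0:
        return rng.poisson(mean, size=n)
    p = mean / (mean + dispersion * mean)
    return rng.negative_binomial(mean * p / (1 - p), p, size=n)


def simulate_family(config: FamilySimConfig) -> FamilySimResult:
    """Simulate one family's joint-genotyped variant table with known truth.

    Plants shared multi-sample variants, per-sample unique SNVs and indels
    (treated samples at the configured fold excess, partly as tract-adjacent
    −1 bp deletions), a handful of deliberately filter-failing variants
    (low depth, low VAF, sex-chromosome) to exercise the unique-variant
    rules, and writes everything as normalized biallelic VCF records.
    """
    rng = np.random.default_rng(config.seed)
    reference, tracts = _build_reference(config, rng)
    autosomes = [c for c in config.chrom_lengths if c not in config.sex_chroms]
    samples = [s for s, _ in config.samples]
    roles = dict(config.samples)
    n_samples = len(samples)
    used_positions: set[tuple[str, int]] = set()

    def pick_position(chroms: list[str], margin: int = 30) -> tuple[str, int]:
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(margin, len(reference[chrom]) - margin))
            if all(
                (chrom, p) not in used_positions for p in range(pos - 25, pos + 26)
            ):
                used_positions.add((chrom, pos))
                return chrom, pos

    def pick_nontract_position(chroms: list[str]) -> tuple[str, int]:
        while True:
            chrom, pos = pick_position(chroms)
            seq = reference[chrom]
            # deleted base would be pos+1; demand no A/T run >=4 near it and
            # a left-aligned single-base representation
            if (
                not _has_tract_context(seq, pos + 1)
                and seq[pos] != seq[pos + 1]
                and seq[pos + 1] != seq[pos + 2]
            ):
                return chrom, pos

    rows: list[dict] = []
    truth: dict[str, dict] = {
        s: {"unique_snvs": 0, "unique_indels": 0, "tract_deletions": 0}
        for s in samples
    }
    planted_deletions: list[dict] = []

    def plant(
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        carrier_idx: list[int],
        carrier_vaf: tuple[float, float] = (0.35, 0.55),
        dp_override: dict[int, int] | None = None,
        vaf_override: dict[int, float] | None = None,
    ) -> dict:
        dp = _draw_depths(config, n_samples, rng)
        dp = np.maximum(dp, 1)
        ad = np.zeros(n_samples, dtype=int)
        gt = ["0/0"] * n_samples
        for ci in carrier_idx:
            if dp_override and ci in dp_override:
                dp[ci] = dp_override[ci]
            if vaf_override and ci in vaf_override:
                # exact sub-threshold allele depth, not a binomial draw
                ad[ci] = max(1, int(vaf_override[ci] * dp[ci]))
                gt[ci] = "0/1"
                continue
            vaf = float(rng.uniform(*carrier_vaf))
            ad[ci] = max(1, int(rng.binomial(dp[ci], vaf)))
            gt[ci] = "0/1" if vaf < 0.9 else "1/1"
        if dp_override:
            for i, d in dp_override.items():
                dp[i] = d
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "dp": dp.tolist(),
            "ad": ad.tolist(),
            "gt": gt,
        }
        rows.append(row)
        return row

    def plant_snv(carrier_idx: list[int], chroms: list[str]) -> dict:
        chrom, pos = pick_position(chroms)
        ref = reference[chrom][pos]
        alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
        return plant(chrom, pos, ref, alt, carrier_idx)

    def plant_tract_deletion(carrier_idx: int) -> dict:
        while True:
            chrom, start, end, base = tracts[int(rng.integers(len(tracts)))]
            if chrom in config.sex_chroms:
                continue
            if (chrom, start) in used_positions:
                continue
            used_positions.add((chrom, start))
            break
        seq = reference[chrom]
        anchor = start - 1  # left-aligned: anchor differs from tract base
        row = plant(chrom, anchor, seq[anchor] + base, seq[anchor], [carrier_idx])
        planted_deletions.append(
            {"chrom": chrom, "pos": anchor, "carrier": samples[carrier_idx],
             "tract_adjacent": True}
        )
        return row

    def plant_plain_indel(carrier_idx: int, force_del1: bool = False) -> dict:
        chrom, pos = pick_nontract_position(autosomes)
        seq = reference[chrom]
        u = rng.random()
        if force_del1 or u < 0.5:  # -1 bp deletion, guaranteed non-tract
            row = plant(chrom, pos, seq[pos : pos + 2], seq[pos], [carrier_idx])
            planted_deletions.append(
                {"chrom": chrom, "pos": pos, "carrier": samples[carrier_idx],
                 "tract_adjacent": False}
            )
            return row
        if u < 0.7 and seq[pos] != seq[pos + 2]:  # left-aligned -2 bp deletion
            return plant(chrom, pos, seq[pos : pos + 3], seq[pos], [carrier_idx])
        # +1/+2 insertion whose last base differs from the anchor
        length = 1 if u < 0.9 else 2
        insert = "".join(
            "ACGT"[int(rng.integers(4))] for _ in range(length)
        )
        if insert[-1] == seq[pos]:
            insert = insert[:-1] + "ACGT".replace(seq[pos], "")[int(rng.integers(3))]
        return plant(chrom, pos, seq[pos], seq[pos] + insert, [carrier_idx])

    # shared (multi-carrier) variants — never unique, exercise rule (b)
    n_shared = int(rng.poisson(config.shared_variant_rate))
    for _ in range(n_shared):
        k = int(rng.integers(2, n_samples + 1))
        carriers = list(rng.choice(n_samples, size=k, replace=False))
        plant_snv([int(c) for c in carriers], autosomes)

    for si, sample in enumerate(samples):
        # unique SNVs
        for _ in range(int(rng.poisson(config.unique_snv_rate))):
            plant_snv([si], autosomes)
            truth[sample]["unique_snvs"] += 1
        # unique indels: control rate for everyone ...
        n_base = int(rng.poisson(config.unique_indel_rate_control))
        for _ in range(n_base):
            if rng.random() < config.control_tract_fraction:
                plant_tract_deletion(si)
                truth[sample]["tract_deletions"] += 1
            else:
                plant_plain_indel(si)
            truth[sample]["unique_indels"] += 1
        # ... plus the treated excess
        if roles[sample] == "treated_offspring":
            n_extra = int(
                rng.poisson(
                    config.unique_indel_rate_control
                    * (config.treated_indel_fold - 1.0)
                )
            )
            for _ in range(n_extra):
                if rng.random() < config.tract_deletion_fraction:
                    plant_tract_deletion(si)
                    truth[sample]["tract_deletions"] += 1
                else:
                    plant_plain_indel(si, force_del1=True)
                truth[sample]["unique_indels"] += 1

    # deliberately filter-failing variants (not counted in truth)
    failing: list[dict] = []
    for kind in ("low_depth", "low_vaf", "sex_chrom"):
        for _ in range(3):
            si = int(rng.integers(n_samples))
            if kind == "sex_chrom":
                chrom, pos = pick_position(list(config.sex_chroms))
                ref = reference[chrom][pos]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                plant(chrom, pos, ref, alt, [si])
            else:
                chrom, pos = pick_position(autosomes)
                ref = reference[chrom][pos]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                if kind == "low_depth":
                    other = int((si + 1) % n_samples)
                    plant(chrom, pos, ref, alt, [si],
                          dp_override={other: int(rng.integers(5, 30))})
                else:
                    plant(chrom, pos, ref, alt, [si],
                          vaf_override={si: 0.10})
            failing.append({"kind": kind, "chrom": chrom, "pos": pos,
                            "carrier": samples[si]})

    rows.sort(key=lambda r: (r["chrom"], r["pos"]))
    vcf_text = _format_vcf(rows, samples, config.chrom_lengths)
    control_counts = [
        truth[s]["unique_indels"] for s in samples
        if roles[s] != "treated_offspring"
    ]
    treated_counts = [
        truth[s]["unique_indels"] for s in samples
        if roles[s] == "treated_offspring"
    ]
    control_mean = float(np.mean(control_counts))
    manifest = {
        "seed": config.seed,
        "samples": {s: roles[s] for s in samples},
        "per_sample_truth": truth,
        "true_fold": config.treated_indel_fold,
        "realized_fold": (
            float(np.mean(treated_counts)) / control_mean if control_mean else None
        ),
        "planted_deletions": planted_deletions,
        "failing_variants": failing,
        "n_shared": n_shared,
    }
    return FamilySimResult(
        reference=reference,
        vcf_text=vcf_text,
        pedigree=[(s, roles[s]) for s in samples],
        manifest=manifest,
        tracts=tracts,
    )


def _format_vcf(
    rows: Iterable[dict], samples: list[str], chrom_lengths: dict[str, int]
) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pequant.simulate",
    ]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allele depths (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for row in rows:
        cells = [
            row["chrom"],
            str(row["pos"] + 1),
            ".",
            row["ref"],
            row["alt"],
            ".",
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for i in range(len(samples)):
            dp = row["dp"][i]
            ad = row["ad"][i]
            cells.append(f"{row['gt'][i]}:{dp}:{dp - ad},{ad}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_family(result: FamilySimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated family to disk (FASTA, VCF, pedigree TSV, manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out_dir / "reference.fa",
        "vcf": out_dir / "family.vcf",
        "pedigree": out_dir / "pedigree.tsv",
        "manifest": out_dir / "manifest.json",
    }
    with open(paths["reference"], "w") as fh:
        for chrom, seq in result.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["vcf"].write_text(result.vcf_text)
    with open(paths["pedigree"], "w") as fh:
        fh.write("sample_id\trole\n")
        for sample, role in result.pedigree:
            fh.write(f"{sample}\t{role}\n")
    paths["manifest"].write_text(json.dumps(result.manifest, indent=1))
    return paths
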