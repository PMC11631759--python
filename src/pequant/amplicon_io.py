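"""Amplicon read I/O, demultiplexing, quality masking and pre-alignment filters.

Reads from single-end amplicon sequencing of individual embryos are
demultiplexed by a 20-nt sample barcode (hamming distance <= 1), low-quality
base calls are masked to ``N`` (Phred < 30), and reads are discarded when they
are too ambiguous near the edit site (> 10% ``N`` within +/- 40 bp) or when
their first 40 bases (the "seed region") diverge from the wild-type amplicon
(< 90% identity).  The pipeline order is fixed:

    demultiplex -> mask -> ambiguity filter -> seed filter

Every input read ends up in exactly one bin (assigned-and-kept, discarded with
a reason, or unassigned), so bin counts always sum to the input count.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")

#: Default Phred threshold below which base calls are masked to 'N'.
DEFAULT_QUALITY_THRESHOLD = 30
#: Default half-width (bp) of the ambiguity window around the edit site.
DEFAULT_AMBIGUITY_RADIUS = 40
#: Default maximum tolerated 'N' fraction inside the ambiguity window.
DEFAULT_MAX_N_FRACTION = 0.10
#: Default seed-region length (first bases of the read).
DEFAULT_SEED_LENGTH = 40
#: Default minimum ungapped identity of the seed region to the amplicon.
DEFAULT_MIN_SEED_IDENTITY = 0.90

#: Sanger/Illumina 1.8+ FASTQ quality encoding offset (the only one accepted).
PHRED_OFFSET = 33
#: Quality above which we assume the file is not Phred+33 encoded.
_MAX_PLAUSIBLE_PHRED = 60


class ConfigurationError(ValueError):
    """Raised when a target specification or parameter set is inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """The programmed prime edit at a target locus.

    Parameters
    ----------
    kind:
        One of ``"substitution"``, ``"deletion"`` or ``"insertion"``.
    offset:
        Offset of the edited position from the pegRNA nick, in reference
        coordinates (e.g. ``5`` for a "+5" edit).
    ref:
        Reference allele.  Empty for insertions.
    alt:
        Alternate allele.  Empty for deletions.
    """

    kind: str
    offset: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise ConfigurationError(f"unknown edit kind: {self.kind!r}")
        if self.kind == "substitution" and (
            not self.ref or not self.alt or len(self.ref) != len(self.alt)
        ):
            raise ConfigurationError("substitution requires equal-length ref/alt")
        if self.kind == "deletion" and (not self.ref or self.alt):
            raise ConfigurationError("deletion requires non-empty ref, empty alt")
        if self.kind == "insertion" and (self.ref or not self.alt):
            raise ConfigurationError("insertion requires empty ref, non-empty alt")

    def apply(self, amplicon: str, nick_pos: int) -> str:
        """Return the amplicon sequence with this edit installed."""
        pos = nick_pos + self.offset
        if self.kind == "insertion":
            return amplicon[:pos] + self.alt + amplicon[pos:]
        if amplicon[pos : pos + len(self.ref)] != self.ref:
            raise ConfigurationError(
                f"edit ref allele {self.ref!r} does not match amplicon at {pos}"
            )
        return amplicon[:pos] + self.alt + amplicon[pos + len(self.ref) :]


@dataclass(frozen=True)
class TargetSpec:
    """Specification of one edited locus and its sequencing design.

    Parameters
    ----------
    name:
        Locus label (e.g. ``"Chd2_plus5_GtoA"``).
    amplicon:
        Wild-type reference sequence of the sequenced region.
    nick_pos:
        0-based index of the first reference base 3' of the pegRNA nick.
    intended_edit:
        The programmed edit.
    secondary_nick_pos:
        0-based index of the complementary-strand nick (PE3/PE5 designs),
        or ``None`` when no secondary nick was used.
    barcode_map:
        Mapping ``sample_id -> barcode`` (equal-length barcodes, pairwise
        hamming distance >= 3 so distance-<=1 assignment is unambiguous).
    """

    name: str
    amplicon: str
    nick_pos: int
    intended_edit: Edit
    secondary_nick_pos: int | None = None
    barcode_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        amp = self.amplicon.upper()
        object.__setattr__(self, "amplicon", amp)
        if not set(amp) <= set("ACGT"):
            raise ConfigurationError("amplicon must be over {A,C,G,T}")
        if not (0 <= self.nick_pos < len(amp)):
            raise ConfigurationError("nick_pos outside amplicon")
        if self.secondary_nick_pos is not None and not (
            0 <= self.secondary_nick_pos < len(amp)
        ):
            raise ConfigurationError("secondary_nick_pos outside amplicon")
        if not (0 <= self.edit_pos < len(amp)):
            raise ConfigurationError("edit position outside amplicon")
        if self.intended_edit.apply(amp, self.nick_pos) == amp:
            raise ConfigurationError("intended edit does not change the amplicon")
        self._validate_barcodes()

    def _validate_barcodes(self) -> None:
        barcodes = list(self.barcode_map.values())
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("duplicate barcodes in barcode_map")
        if barcodes and len({len(b) for b in barcodes}) != 1:
            raise ConfigurationError("barcodes must all have the same length")
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                if hamming_distance(a, b) < 3:
                    raise ConfigurationError(
                        f"barcodes {a!r} and {b!r} are within hamming distance 2; "
                        "distance-<=1 demultiplexing would be ambiguous"
                    )

    @property
    def edit_pos(self) -> int:
        """0-based reference index of the (first) edited base."""
        return self.nick_pos + self.intended_edit.offset

    @property
    def edited_amplicon(self) -> str:
        """The amplicon with the intended edit installed."""
        return self.intended_edit.apply(self.amplicon, self.nick_pos)


@dataclass
class ReadRecord:
    """One sequencing read with per-base qualities and masking state."""

    read_id: str
    bases: str
    quals: np.ndarray
    barcode: str | None = None
    sample_id: str | None = None
    masked: bool = False

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != self.quals.size:
            raise ValueError("bases and quals must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FilterDecision:
    """Keep/discard decision for a single read, with the measured statistic."""

    keep: bool
    reason: str | None = None
    value: float | None = None


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33 only)
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_barcode(description: str) -> str | None:
    """Extract a ``BC:<seq>`` barcode tag from a FASTQ header description."""
    for token in description.split():
        if token.startswith("BC:"):
            return token[3:]
    return None


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a (optionally gzipped) Phred+33 FASTQ file.

    The sample barcode is parsed from a ``BC:<seq>`` token in the header
    description when present.  Files whose quality scores exceed Phred 60 are
    rejected as not Phred+33 encoded (e.g. legacy Phred+64 data).
    """
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = np.asarray(
                rec.letter_annotations["phred_quality"], dtype=np.int16
            )
            if quals.size and int(quals.max()) > _MAX_PLAUSIBLE_PHRED:
                raise ConfigurationError(
                    f"{path}: quality {int(quals.max())} exceeds Phred+33 range; "
                    "only Phred+33 (Sanger/Illumina 1.8+) FASTQ is supported"
                )
            yield ReadRecord(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                quals=quals,
                barcode=parse_barcode(rec.description),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_maybe_gzip(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(
                Seq(read.bases),
                id=read.read_id,
                description=f"BC:{read.barcode}" if read.barcode else "",
            )
            rec.letter_annotations["phred_quality"] = [int(q) for q in read.quals]
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n


def load_target_spec(path: str | Path) -> TargetSpec:
    """Load a :class:`TargetSpec` from a YAML/JSON config file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    edit = Edit(**raw["intended_edit"])
    return TargetSpec(
        name=raw["name"],
        amplicon=raw["amplicon"],
        nick_pos=int(raw["nick_pos"]),
        intended_edit=edit,
        secondary_nick_pos=(
            int(raw["secondary_nick_pos"])
            if raw.get("secondary_nick_pos") is not None
            else None
        ),
        barcode_map=dict(raw.get("barcode_map", {})),
    )


def dump_target_spec(spec: TargetSpec, path: str | Path) -> None:
    """Write a :class:`TargetSpec` to YAML (inverse of :func:`load_target_spec`)."""
    raw = {
        "name": spec.name,
        "amplicon": spec.amplicon,
        "nick_pos": spec.nick_pos,
        "intended_edit": {
            "kind": spec.intended_edit.kind,
            "offset": spec.intended_edit.offset,
            "ref": spec.intended_edit.ref,
            "alt": spec.intended_edit.alt,
        },
        "secondary_nick_pos": spec.secondary_nick_pos,
        "barcode_map": dict(spec.barcode_map),
    }
    with open(path, "w") as handle:
        yaml.safe_dump(raw, handle, sort_keys=False)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def hamming_distance(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[ReadRecord], spec: TargetSpec
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to samples by barcode at hamming distance <= 1.

    A read is assigned to the unique sample whose barcode is within hamming
    distance 1 of the read barcode.  Reads matching no barcode at distance
    <= 1, or two or more barcodes at distance <= 1 (which cannot happen when
    barcodes satisfy the pairwise-distance >= 3 invariant, but is guarded
    against anyway), go to the unassigned bin.
    """
    if not spec.barcode_map:
        raise ConfigurationError("spec has an empty barcode_map")
    barcode_len = len(next(iter(spec.barcode_map.values())))
    assigned: dict[str, list[ReadRecord]] = {s: [] for s in spec.barcode_map}
    unassigned: list[ReadRecord] = []
    for read in reads:
        if read.barcode is None or len(read.barcode) != barcode_len:
            if read.barcode is not None and len(read.barcode) != barcode_len:
                raise ConfigurationError(
                    f"read {read.read_id}: barcode length {len(read.barcode)} "
                    f"!= reference barcode length {barcode_len}"
                )
            unassigned.append(read)
            continue
        hits = [
            sample
            for sample, bc in spec.barcode_map.items()
            if hamming_distance(read.barcode, bc) <= 1
        ]
        if len(hits) == 1:
            read.sample_id = hits[0]
            assigned[hits[0]].append(read)
        else:
            unassigned.append(read)
    counts = {s: len(v) for s, v in assigned.items()}
    logger.info(
        "demultiplexed %d reads: %s assigned, %d unassigned",
        sum(counts.values()) + len(unassigned),
        counts,
        len(unassigned),
    )
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Quality masking and filters
# ---------------------------------------------------------------------------


def mask_low_quality(
    read: ReadRecord, q_threshold: int = DEFAULT_QUALITY_THRESHOLD
) -> ReadRecord:
    """Replace base calls with Phred quality strictly below ``q_threshold`` by 'N'.

    Qualities are retained alongside the masked sequence, and the returned
    record carries ``masked=True``.  Masking is idempotent.
    """
    bases = np.frombuffer(read.bases.encode("ascii"), dtype="S1").copy()
    bases[read.quals < q_threshold] = b"N"
    return replace(
        read, bases=bases.tobytes().decode("ascii"), quals=read.quals, masked=True
    )


def filter_ambiguity(
    read: ReadRecord,
    spec: TargetSpec,
    radius_bp: int = DEFAULT_AMBIGUITY_RADIUS,
    max_n_frac: float = DEFAULT_MAX_N_FRACTION,
) -> FilterDecision:
    """Discard reads with too many ambiguous calls near the edit site.

    The read is assumed to start at amplicon position 0 (amplicon-primer
    design guarantees this), so the reference interval
    ``[edit_pos - radius_bp, edit_pos + radius_bp]`` maps ungapped onto read
    coordinates.  The 'N' fraction over those positions is computed and the
    read is discarded iff it strictly exceeds ``max_n_frac``.  A read too
    short to cover the interval is discarded with reason ``"no_coverage"``.
    """
    lo = max(0, spec.edit_pos - radius_bp)
    hi = min(len(spec.amplicon) - 1, spec.edit_pos + radius_bp)
    if len(read.bases) < hi + 1:
        return FilterDecision(keep=False, reason="no_coverage")
    window = read.bases[lo : hi + 1]
    frac = window.count("N") / len(window)
    if frac > max_n_frac:
        return FilterDecision(keep=False, reason="ambiguous", value=frac)
    return FilterDecision(keep=True, value=frac)


def seed_filter(
    read: ReadRecord,
    spec: TargetSpec,
    seed_len: int = DEFAULT_SEED_LENGTH,
    min_identity: float = DEFAULT_MIN_SEED_IDENTITY,
) -> FilterDecision:
    """Discard reads whose seed region diverges from the wild-type amplicon.

    The first ``seed_len`` read bases are compared ungapped to the first
    ``seed_len`` amplicon bases.  Identity is computed over non-'N' read
    positions ('N' is non-informative, not a mismatch); a read is discarded
    iff identity falls strictly below ``min_identity``, or when more than half
    the seed is 'N'.  Reads shorter than the seed are discarded with reason
    ``"short_read"``.

    The seed region must not overlap the nick or edit sites; the target spec
    is validated against this (amplicon designs place these >= 75 bp from the
    read start).
    """
    sites = [spec.nick_pos, spec.edit_pos]
    if spec.secondary_nick_pos is not None:
        sites.append(spec.secondary_nick_pos)
    if seed_len > min(sites):
        raise ConfigurationError(
            f"seed region (len {seed_len}) overlaps a nick/edit site at "
            f"{min(sites)}; seed filtering would reject true edits"
        )
    if len(read.bases) < seed_len:
        return FilterDecision(keep=False, reason="short_read")
    seed = read.bases[:seed_len]
    ref = spec.amplicon[:seed_len]
    informative = [(s, r) for s, r in zip(seed, ref) if s != "N"]
    if len(informative) < seed_len / 2:
        return FilterDecision(keep=False, reason="seed_masked")
    matches = sum(s == r for s, r in informative)
    identity = matches / len(informative)
    if identity < min_identity:
        return FilterDecision(keep=False, reason="seed_mismatch", value=identity)
    return FilterDecision(keep=True, value=identity)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessResult:
    """Per-sample kept reads and a full accounting of every input read."""

    kept: dict[str, list[ReadRecord]]
    n_input: int
    n_unassigned: int
    discarded: dict[str, dict[str, int]]  # sample -> reason -> count

    def report_frame(self):
        """Filtering report as a tidy table (one row per sample)."""
        import pandas as pd

        rows = []
        for sample, reads in self.kept.items():
            reasons = self.discarded.get(sample, {})
            rows.append(
                {
                    "sample_id": sample,
                    "n_input": len(reads) + sum(reasons.values()),
                    "n_kept": len(reads),
                    **{f"n_discarded_{r}": c for r, c in sorted(reasons.items())},
                }
            )
        return pd.DataFrame(rows)


def preprocess(
    reads: Iterable[ReadRecord],
    spec: TargetSpec,
    q_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    radius_bp: int = DEFAULT_AMBIGUITY_RADIUS,
    max_n_frac: float = DEFAULT_MAX_N_FRACTION,
    seed_len: int = DEFAULT_SEED_LENGTH,
    min_identity: float = DEFAULT_MIN_SEED_IDENTITY,
) -> PreprocessResult:
    """Run the fixed preprocessing pipeline on a stream of reads.

    Order: demultiplex -> quality masking -> ambiguity filter -> seed filter.
    Every input read ends in exactly one of {assigned-and-kept,
    discarded(reason), unassigned}.
    """
    reads = list(reads)
    assigned, unassigned = demultiplex(reads, spec)
    kept: dict[str, list[ReadRecord]] = {}
    discarded: dict[str, dict[str, int]] = {}
    for sample, sample_reads in assigned.items():
        kept[sample] = []
        reasons: dict[str, int] = {}
        for read in sample_reads:
            masked = mask_low_quality(read, q_threshold)
            decision = filter_ambiguity(masked, spec, radius_bp, max_n_frac)
            if decision.keep:
                decision = seed_filter(masked, spec, seed_len, min_identity)
            if decision.keep:
                kept[sample].append(masked)
            else:
                reasons[decision.reason] = reasons.get(decision.reason, 0) + 1
        discarded[sample] = reasons
    return PreprocessResult(
        kept=kept,
        n_input=len(reads),
        n_unassigned=len(unassigned),
        discarded=discarded,
    )
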