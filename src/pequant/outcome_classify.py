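"""Nick-anchored read classification and per-embryo summaries.

Aligned reads are binned into three exhaustive categories within the
classification windows anchored at the nick site(s):

* ``WT`` — exactly matching the reference within the considered region(s);
* ``PRECISE`` — containing only the intended edit and nothing else;
* ``ERROR`` — any other unintended sequence change (inter-nick deletions,
  "combined" edit-plus-deletion outcomes, unintended substitutions/indels).

Method 1 considers a 40-nt window around the pegRNA nick (18 nt 5', 22 nt 3')
plus a 34-nt window around the secondary sgRNA nick (17 nt each side), with
union semantics: a PRECISE call requires the secondary window to be
event-free.  Method 2 considers only the 40-nt pegRNA-nick window (used when
no secondary nick was employed).  Changes strictly outside all considered
windows are ignored, which suppresses the effect of spontaneous background
SNPs on error rates.

Per-embryo error fractions can be background-adjusted by subtracting the mean
error fraction measured in unedited control embryos ("adjusted errors").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

from .amplicon_io import ConfigurationError, ReadRecord, TargetSpec
from .pairwise_align import (
    DEFAULT_SCORING,
    Alignment,
    AlignmentScoring,
    VariantEvent,
    event_in_window,
    global_align,
    normalize_event,
)

if TYPE_CHECKING:  # pragma: no cover
    from .edit_stats import BackgroundModel

#: 5' and 3' extents of the primary (pegRNA nick) window.
PRIMARY_5P = 18
PRIMARY_3P = 22
#: Half-width of the secondary (nicking sgRNA) window.
SECONDARY_HALF = 17


class ReadClass(enum.Enum):
    WT = "WT"
    PRECISE = "PRECISE"
    ERROR = "ERROR"


@dataclass(frozen=True)
class ClassificationWindows:
    """Reference windows considered during classification (0-based, half-open)."""

    method: int
    primary: tuple[int, int]
    secondary: tuple[int, int] | None = None

    def intervals(self) -> list[tuple[int, int]]:
        out = [self.primary]
        if self.secondary is not None:
            out.append(self.secondary)
        return out


@dataclass
class EmbryoSummary:
    """Per-embryo classification counts and fractions over kept reads."""

    embryo_id: str
    method: int
    n_total_kept: int
    n_wt: int
    n_precise: int
    n_error: int
    frac_wt: float
    frac_precise: float
    frac_error: float
    frac_error_adjusted: float | None = None
    n_discarded: int = 0
    target: str | None = None
    flag: str | None = None


def build_windows(spec: TargetSpec, method: int) -> ClassificationWindows:
    """Build the nick-anchored classification windows for a method.

    Method 1: 40-nt primary window ``[nick−18, nick+22)`` plus 34-nt secondary
    window ``[secondary_nick−17, secondary_nick+17)``.  Method 2: primary
    window only.
    """
    if method not in (1, 2):
        raise ConfigurationError(f"method must be 1 or 2, got {method!r}")
    primary = (spec.nick_pos - PRIMARY_5P, spec.nick_pos + PRIMARY_3P)
    secondary: tuple[int, int] | None = None
    if method == 1:
        if spec.secondary_nick_pos is None:
            raise ConfigurationError(
                "method 1 requires a secondary_nick_pos in the target spec"
            )
        secondary = (
            spec.secondary_nick_pos - SECONDARY_HALF,
            spec.secondary_nick_pos + SECONDARY_HALF,
        )
    for lo, hi in [primary] + ([secondary] if secondary else []):
        if lo < 0 or hi > len(spec.amplicon):
            raise ConfigurationError(
                f"classification window [{lo}, {hi}) extends past the amplicon"
            )
    if not primary[0] <= spec.edit_pos < primary[1]:
        raise ConfigurationError("intended edit lies outside the primary window")
    return ClassificationWindows(method=method, primary=primary, secondary=secondary)


_EDIT_KIND_TO_EVENT = {"substitution": "sub", "deletion": "del", "insertion": "ins"}


def intended_edit_event(spec: TargetSpec) -> VariantEvent:
    """The intended edit as a left-normalized alignment event."""
    edit = spec.intended_edit
    pos = spec.edit_pos
    kind = _EDIT_KIND_TO_EVENT[edit.kind]
    if kind == "sub":
        ev = VariantEvent("sub", pos, pos + 1, edit.ref, edit.alt)
    elif kind == "del":
        ev = VariantEvent("del", pos, pos + len(edit.ref), edit.ref, "")
    else:
        ev = VariantEvent("ins", pos, pos, "", edit.alt)
    return normalize_event(ev, spec.amplicon)


def classify_read(
    aln: Alignment,
    windows: ClassificationWindows,
    intended: VariantEvent,
) -> ReadClass:
    """Classify one aligned read within the considered window(s).

    Events are collected over the union of windows.  No events: ``WT``.
    Exactly the intended edit and nothing else: ``PRECISE``.  Any other
    non-empty event set: ``ERROR``.  Columns where the read holds 'N' are
    non-informative and never produce events.
    """
    in_window = [
        ev
        for ev in aln.events
        if any(event_in_window(ev, lo, hi) for lo, hi in windows.intervals())
    ]
    if not in_window:
        return ReadClass.WT
    if len(in_window) == 1 and in_window[0] == intended:
        return ReadClass.PRECISE
    return ReadClass.ERROR


def summarize_embryo(
    classes: Sequence[ReadClass],
    embryo_id: str,
    method: int,
    n_discarded: int = 0,
    target: str | None = None,
) -> EmbryoSummary:
    """Counts and fractions over kept reads (discarded reads excluded).

    An embryo with zero kept reads is flagged ``"no_data"`` and should be
    excluded from group statistics.
    """
    n = len(classes)
    if n == 0:
        return EmbryoSummary(
            embryo_id=embryo_id,
            method=method,
            n_total_kept=0,
            n_wt=0,
            n_precise=0,
            n_error=0,
            frac_wt=math.nan,
            frac_precise=math.nan,
            frac_error=math.nan,
            n_discarded=n_discarded,
            target=target,
            flag="no_data",
        )
    n_wt = sum(c is ReadClass.WT for c in classes)
    n_precise = sum(c is ReadClass.PRECISE for c in classes)
    n_error = n - n_wt - n_precise
    return EmbryoSummary(
        embryo_id=embryo_id,
        method=method,
        n_total_kept=n,
        n_wt=n_wt,
        n_precise=n_precise,
        n_error=n_error,
        frac_wt=n_wt / n,
        frac_precise=n_precise / n,
        frac_error=n_error / n,
        n_discarded=n_discarded,
        target=target,
    )


def adjust_errors(summary: EmbryoSummary, background: "BackgroundModel") -> EmbryoSummary:
    """Subtract the control-group mean error fraction, clipping at zero."""
    if summary.method != background.method:
        raise ConfigurationError(
            f"background model is for method {background.method}, "
            f"summary for method {summary.method}"
        )
    if (
        summary.target is not None
        and background.target is not None
        and summary.target != background.target
    ):
        raise ConfigurationError(
            f"background model is for target {background.target!r}, "
            f"summary for target {summary.target!r}"
        )
    adjusted = max(0.0, summary.frac_error - background.mean)
    return replace(summary, frac_error_adjusted=adjusted)


def classify_embryo(
    reads: Iterable[ReadRecord],
    spec: TargetSpec,
    method: int,
    embryo_id: str,
    n_discarded: int = 0,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    return_classes: bool = False,
):
    """Align and classify a set of kept reads; return an :class:`EmbryoSummary`.

    Alignments are cached by (masked) read sequence — amplicon reads are
    highly redundant, so most reads reuse a previously computed alignment.
    """
    windows = build_windows(spec, method)
    intended = intended_edit_event(spec)
    cache: dict[str, ReadClass] = {}
    classes: list[ReadClass] = []
    for read in reads:
        cls = cache.get(read.bases)
        if cls is None:
            aln = global_align(read.bases, spec.amplicon, scoring)
            cls = classify_read(aln, windows, intended)
            cache[read.bases] = cls
        classes.append(cls)
    summary = summarize_embryo(
        classes, embryo_id, method, n_discarded=n_discarded, target=spec.name
    )
    if return_classes:
        return summary, classes
    return summary
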