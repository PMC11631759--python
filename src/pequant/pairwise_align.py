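"""Global pairwise alignment (Needleman–Wunsch with Gotoh's affine gaps).

Each kept read is aligned globally (end gaps penalized) to the wild-type
amplicon under the scoring +1 match, 0 mismatch, −3 gap initiation, −1 gap
extension: a gap of length L costs ``gap_open + (L−1)·gap_extend``, the open
cost being charged to the first gapped position.

The dynamic program is the three-matrix Gotoh recurrence; the fill runs in a
numba-compiled kernel and the traceback is resolved in Python with a fixed
tie-breaking priority (diagonal > vertical/insertion > horizontal/deletion) so
that the reported alignment — and therefore downstream read classification —
is deterministic even when several alignments share the optimal score.

Masked read bases ('N') score as mismatches during the DP but are flagged
non-informative: an aligned column whose read base is 'N' never becomes a
substitution event.  Indel events are left-normalized against the reference so
that equivalent placements of the same molecule compare equal.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


_N_BYTE = ord("N")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring parameters.

    ``gap_open`` is the score of the first position of a gap; each additional
    gapped position scores ``gap_extend``.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -3.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (
            self.gap_open <= self.gap_extend <= 0.0 <= self.match
            and self.mismatch <= self.match
        ):
            raise ValueError(
                "scoring must satisfy gap_open <= gap_extend <= 0 <= match "
                "and mismatch <= match"
            )

    def gap_cost(self, length: int) -> float:
        """Total score contribution of a gap of the given length."""
        return self.gap_open + (length - 1) * self.gap_extend if length else 0.0


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class VariantEvent:
    """One sequence change of the read relative to the reference.

    ``ref_start``/``ref_end`` is the half-open reference interval the event
    occupies; insertions have ``ref_start == ref_end`` and sit between
    reference bases ``ref_start − 1`` and ``ref_start``.
    """

    kind: str  # 'sub' | 'ins' | 'del'
    ref_start: int
    ref_end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in ("sub", "ins", "del"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def size(self) -> int:
        """Signed length change (insertions positive, deletions negative)."""
        return len(self.alt) - len(self.ref)


@dataclass
class Alignment:
    """A global alignment of a read against the reference amplicon."""

    ref_aligned: str
    read_aligned: str
    score: float
    events: list[VariantEvent]

    @property
    def ref(self) -> str:
        return self.ref_aligned.replace("-", "")

    @property
    def read(self) -> str:
        return self.read_aligned.replace("-", "")


@dataclass(frozen=True)
class WindowView:
    """Alignment columns and events restricted to a reference window."""

    ref_start: int
    ref_end: int
    ref_aligned: str
    read_aligned: str
    events: tuple[VariantEvent, ...]


# ---------------------------------------------------------------------------
# Gotoh fill
# ---------------------------------------------------------------------------

_NEG_INF = -1.0e18


@njit(cache=True)
def _gotoh_fill(read, ref, match, mismatch, gap_open, gap_extend):
    """Fill the H (best), E (gap-in-read) and F (gap-in-ref) matrices.

    read indexes rows (i), ref indexes columns (j).  E holds alignments whose
    last column consumes a reference base against a read gap (a deletion from
    the read's perspective); F the converse (an insertion).
    """
    n = read.shape[0]
    m = ref.shape[0]
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    E = np.empty((n + 1, m + 1), dtype=np.float64)
    F = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, 0] = 0.0
    E[0, 0] = _NEG_INF
    F[0, 0] = _NEG_INF
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_extend
        H[0, j] = E[0, j]
        F[0, j] = _NEG_INF
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
        E[i, 0] = _NEG_INF
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            e_open = H[i, j - 1] + gap_open
            if e_open > e:
                e = e_open
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            f_open = H[i - 1, j] + gap_open
            if f_open > f:
                f = f_open
            F[i, j] = f
            if ri == ref[j - 1] and ri != _N_BYTE:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h
    return H, E, F


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _traceback(
    read: str, ref: str, H, E, F, scoring: AlignmentScoring
) -> tuple[str, str]:
    """Recover one optimal alignment with deterministic tie-breaking.

    At each H cell the priority is diagonal, then vertical (read base against
    a reference gap), then horizontal.  Inside a gap state, ties between
    opening and extending resolve toward opening (the shorter gap); indel
    left-normalization downstream makes the choice immaterial for
    classification.
    """
    i, j = len(read), len(ref)
    rcols: list[str] = []
    qcols: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                a, b = read[i - 1], ref[j - 1]
                s = (
                    scoring.match
                    if (a == b and a != "N")
                    else scoring.mismatch
                )
                if H[i, j] == H[i - 1, j - 1] + s:
                    rcols.append(b)
                    qcols.append(a)
                    i -= 1
                    j -= 1
                    continue
            if i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
            continue
        if state == "F":  # read base against reference gap (insertion)
            rcols.append("-")
            qcols.append(read[i - 1])
            closes = i == 1 or F[i, j] == H[i - 1, j] + scoring.gap_open
            i -= 1
            if closes:
                state = "H"
            continue
        # state == "E": reference base against read gap (deletion)
        rcols.append(ref[j - 1])
        qcols.append("-")
        closes = j == 1 or E[i, j] == H[i, j - 1] + scoring.gap_open
        j -= 1
        if closes:
            state = "H"
    return "".join(reversed(rcols)), "".join(reversed(qcols))


# ---------------------------------------------------------------------------
# Event extraction and normalization
# ---------------------------------------------------------------------------


def _extract_events(ref_aligned: str, read_aligned: str) -> list[VariantEvent]:
    events: list[VariantEvent] = []
    ref_i = 0
    gap_kind: str | None = None
    gap_start = 0
    gap_seq: list[str] = []

    def flush() -> None:
        nonlocal gap_kind, gap_seq
        if gap_kind == "ins":
            events.append(
                VariantEvent("ins", gap_start, gap_start, "", "".join(gap_seq))
            )
        elif gap_kind == "del":
            events.append(
                VariantEvent(
                    "del", gap_start, gap_start + len(gap_seq), "".join(gap_seq), ""
                )
            )
        gap_kind = None
        gap_seq = []

    for r, q in zip(ref_aligned, read_aligned):
        if r == "-":  # insertion column
            if gap_kind != "ins":
                flush()
                gap_kind = "ins"
                gap_start = ref_i
            gap_seq.append(q)
        elif q == "-":  # deletion column
            if gap_kind != "del":
                flush()
                gap_kind = "del"
                gap_start = ref_i
            gap_seq.append(r)
            ref_i += 1
        else:
            flush()
            if q != r and q != "N":  # read 'N' columns are non-informative
                events.append(VariantEvent("sub", ref_i, ref_i + 1, r, q))
            ref_i += 1
    flush()
    return events


def normalize_event(
    event: VariantEvent, ref_seq: str, lower_bound: int = 0
) -> VariantEvent:
    """Left-align an indel event against the reference.

    The event is shifted left one base at a time while the base preceding it
    equals the last base of the deleted/inserted sequence, stopping at
    ``lower_bound`` (used to avoid sliding one event into its left neighbour).
    Substitutions are returned unchanged.
    """
    if event.kind == "sub":
        return event
    start, end = event.ref_start, event.ref_end
    if event.kind == "del":
        allele = list(event.ref)
        while start > lower_bound and ref_seq[start - 1] == ref_seq[end - 1]:
            start -= 1
            end -= 1
            allele = [ref_seq[start]] + allele[:-1]
        return replace(event, ref_start=start, ref_end=end, ref="".join(allele))
    # insertion
    allele = list(event.alt)
    while start > lower_bound and allele and ref_seq[start - 1] == allele[-1]:
        allele = [ref_seq[start - 1]] + allele[:-1]
        start -= 1
    return replace(event, ref_start=start, ref_end=start, alt="".join(allele))


def normalize_events(
    events: Sequence[VariantEvent], ref_seq: str
) -> list[VariantEvent]:
    """Left-normalize all indels, preventing overlap with the left neighbour."""
    out: list[VariantEvent] = []
    prev_end = 0
    for ev in sorted(events, key=lambda e: (e.ref_start, e.ref_end)):
        norm = normalize_event(ev, ref_seq, lower_bound=prev_end)
        out.append(norm)
        prev_end = max(prev_end, norm.ref_end, norm.ref_start + 1)
    return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def global_align(
    read_seq: str,
    ref_seq: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> Alignment:
    """Optimal global alignment of ``read_seq`` against ``ref_seq``.

    End gaps are penalized (true global mode).  Raises ``ValueError`` on an
    empty sequence.
    """
    if not read_seq or not ref_seq:
        raise ValueError("global_align requires non-empty sequences")
    read_seq = read_seq.upper()
    ref_seq = ref_seq.upper()
    H, E, F = _gotoh_fill(
        _encode(read_seq),
        _encode(ref_seq),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    ref_aligned, read_aligned = _traceback(read_seq, ref_seq, H, E, F, scoring)
    events = normalize_events(_extract_events(ref_aligned, read_aligned), ref_seq)
    return Alignment(
        ref_aligned=ref_aligned,
        read_aligned=read_aligned,
        score=float(H[len(read_seq), len(ref_seq)]),
        events=events,
    )


def alignment_score(aln: Alignment, scoring: AlignmentScoring = DEFAULT_SCORING) -> float:
    """Recompute the score of an alignment from its columns (for invariants)."""
    total = 0.0
    gap_kind = None
    for r, q in zip(aln.ref_aligned, aln.read_aligned):
        if r == "-" or q == "-":
            kind = "r" if r == "-" else "q"
            total += scoring.gap_extend if gap_kind == kind else scoring.gap_open
            gap_kind = kind
        else:
            gap_kind = None
            total += scoring.match if (r == q and q != "N") else scoring.mismatch
    return total


def event_in_window(event: VariantEvent, ref_start: int, ref_end: int) -> bool:
    """Whether an event belongs to the half-open window ``[ref_start, ref_end)``.

    Substitutions and deletions belong iff they overlap the window; an
    insertion belongs iff its left-flanking reference base lies inside the
    window (half-open convention).
    """
    if event.kind == "ins":
        left_flank = event.ref_start - 1
        return ref_start <= left_flank <= ref_end - 1
    return event.ref_start < ref_end and event.ref_end > ref_start


def project_window(aln: Alignment, ref_start: int, ref_end: int) -> WindowView:
    """Restrict an alignment to reference window ``[ref_start, ref_end)``.

    Returns the alignment columns whose reference coordinate lies in the
    window, plus insertion columns whose left-flanking reference base does,
    and the contained variant events.
    """
    n_ref = len(aln.ref)
    if not (0 <= ref_start < ref_end <= n_ref):
        raise ValueError(
            f"window [{ref_start}, {ref_end}) outside reference of length {n_ref}"
        )
    rcols: list[str] = []
    qcols: list[str] = []
    ref_i = 0
    for r, q in zip(aln.ref_aligned, aln.read_aligned):
        if r == "-":
            # insertion column between ref_i-1 and ref_i
            if ref_start <= ref_i - 1 <= ref_end - 1:
                rcols.append(r)
                qcols.append(q)
        else:
            if ref_start <= ref_i < ref_end:
                rcols.append(r)
                qcols.append(q)
            ref_i += 1
    events = tuple(
        ev for ev in aln.events if event_in_window(ev, ref_start, ref_end)
    )
    return WindowView(
        ref_start=ref_start,
        ref_end=ref_end,
        ref_aligned="".join(rcols),
        read_aligned="".join(qcols),
        events=events,
    )
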