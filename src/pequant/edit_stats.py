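"""Background-noise modeling, per-embryo statistical calls and group tests.

Unedited control embryos carry a background of reads classifying as errors
(PCR/sequencing artifacts, somatic SNPs), typically 1–6% depending on target
and method.  Their error fractions are modeled as normal; a treated embryo is
called error-significant by a one-sided (upper-tail) z-test against that
model at a Bonferroni-adjusted p-value cutoff of 0.001.  A separate strict
threshold of 1% precise-edit reads calls an embryo edited.

Group comparisons use two-sided two-sample t-tests (pooled-variance Student
or Welch), and predicted-vs-observed editing efficiencies are compared by
Pearson correlation with the usual t-based two-sided p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .amplicon_io import ConfigurationError
from .outcome_classify import EmbryoSummary

logger = logging.getLogger(__name__)

#: Precise-edit calling threshold (strict: frac_precise must exceed it).
DEFAULT_PRECISE_CUTOFF = 0.01
#: Family-wise alpha for the error z-test before Bonferroni division.
DEFAULT_ALPHA = 0.001
#: Floor applied to a degenerate (zero) control standard deviation.
SD_FLOOR = 1e-6


@dataclass(frozen=True)
class BackgroundModel:
    """Normal model of control-embryo error fractions for one target/method."""

    target: str | None
    method: int
    n_controls: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ConfigurationError("insufficient_controls: need >= 2 controls")
        if not (0.0 <= self.mean <= 1.0) or self.sd < 0.0:
            raise ConfigurationError("background model mean/sd out of range")


@dataclass(frozen=True)
class EditingCall:
    """Statistical editing calls for one embryo."""

    embryo_id: str
    frac_precise: float
    precise_positive: bool
    frac_error: float
    error_z: float
    error_p: float
    error_significant: bool
    m_tests: int


def fit_background(control_summaries: Sequence[EmbryoSummary]) -> BackgroundModel:
    """Fit the normal background model from unedited control embryos.

    Requires at least two controls from the same target and method; the
    standard deviation uses the n−1 denominator.
    """
    usable = [s for s in control_summaries if s.flag != "no_data"]
    if len(usable) < 2:
        raise ConfigurationError("insufficient_controls: need >= 2 control embryos")
    targets = {s.target for s in usable}
    methods = {s.method for s in usable}
    if len(targets) > 1 or len(methods) > 1:
        raise ConfigurationError(
            f"controls mix targets/methods: targets={targets}, methods={methods}"
        )
    fracs = np.array([s.frac_error for s in usable], dtype=float)
    return BackgroundModel(
        target=targets.pop(),
        method=methods.pop(),
        n_controls=len(usable),
        mean=float(fracs.mean()),
        sd=float(fracs.std(ddof=1)),
    )


def call_precise(
    summary: EmbryoSummary, cutoff: float = DEFAULT_PRECISE_CUTOFF
) -> bool:
    """Strict precise-edit call: positive iff ``frac_precise > cutoff``.

    The threshold is applied to the raw (unadjusted) precise fraction; the
    boundary value itself is assigned to unedited.
    """
    return summary.frac_precise > cutoff


def test_errors(
    summary: EmbryoSummary,
    model: BackgroundModel,
    alpha: float = DEFAULT_ALPHA,
    m_tests: int = 1,
) -> EditingCall:
    """One-sided upper-tail z-test of an embryo's error fraction.

    ``z = (frac_error − mean) / sd`` against the control background model;
    significance requires ``p < alpha / m_tests`` (Bonferroni).  A degenerate
    control sd is floored at ``SD_FLOOR`` with a warning.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if summary.method != model.method or (
        summary.target is not None
        and model.target is not None
        and summary.target != model.target
    ):
        raise ConfigurationError("background model target/method mismatch")
    sd = model.sd
    if sd <= 0.0:
        logger.warning(
            "control sd is zero for target %s; flooring at %g", model.target, SD_FLOOR
        )
        sd = SD_FLOOR
    z = (summary.frac_error - model.mean) / sd
    p = float(stats.norm.sf(z))
    return EditingCall(
        embryo_id=summary.embryo_id,
        frac_precise=summary.frac_precise,
        precise_positive=call_precise(summary),
        frac_error=summary.frac_error,
        error_z=float(z),
        error_p=p,
        error_significant=p < alpha / m_tests,
        m_tests=m_tests,
    )


def _floored_var(values: np.ndarray) -> float:
    var = float(values.var(ddof=1))
    return max(var, SD_FLOOR**2)


def compare_groups(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test (``"student"`` pooled or ``"welch"``).

    Implemented in closed form with the group variances floored at
    ``SD_FLOOR**2`` so degenerate zero-variance groups remain testable;
    on non-degenerate inputs this agrees with ``scipy.stats.ttest_ind``.
    Returns ``(t, p)``.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = _floored_var(a), _floored_var(b)
    diff = a.mean() - b.mean()
    if variant == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        se2 = va / na + vb / nb
        t = diff / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def prediction_correlation(
    predicted: Sequence[float], observed: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of predicted scores vs observed editing fractions.

    The p-value is the two-sided t-test ``t = r·sqrt((n−2)/(1−r²))`` on n−2
    degrees of freedom; the least-squares slope/intercept are returned for
    plotting.  Zero variance in either vector is an error.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size != y.size:
        raise ValueError("predicted and observed must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in predicted or observed values")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def call_embryos(
    summaries: Sequence[EmbryoSummary],
    model: BackgroundModel,
    alpha: float = DEFAULT_ALPHA,
    m_tests: int | None = None,
    cutoff: float = DEFAULT_PRECISE_CUTOFF,
) -> list[EditingCall]:
    """Run precise/error calls over a batch of treated embryos.

    The Bonferroni family size defaults to the number of embryos evaluated in
    the batch; pass ``m_tests`` to override.
    """
    usable = [s for s in summaries if s.flag != "no_data"]
    if m_tests is None:
        m_tests = max(1, len(usable))
    calls = []
    for s in usable:
        call = test_errors(s, model, alpha=alpha, m_tests=m_tests)
        if cutoff != DEFAULT_PRECISE_CUTOFF:
            call = EditingCall(
                embryo_id=call.embryo_id,
                frac_precise=call.frac_precise,
                precise_positive=call.frac_precise > cutoff,
                frac_error=call.frac_error,
                error_z=call.error_z,
                error_p=call.error_p,
                error_significant=call.error_significant,
                m_tests=call.m_tests,
            )
        calls.append(call)
    return calls
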