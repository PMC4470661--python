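"""Epoch labelling, agreement statistics and longitudinal comparisons.

Movement presence is scored in fixed 10-s epochs; two labelings are
compared with the prevalence-adjusted bias-adjusted kappa, PABAK = 2*po - 1,
where po is the observed proportion of agreeing epochs.  Per-hour counts
across gestational-week sessions are compared with a one-way
repeated-measures ANOVA followed by Scheffé post-hoc contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .artifact_rejection import TIME_EXCLUDING_REASONS, AnalysisMask
from .detection import SignalEvent, accepted
from .errors import DegenerateSessionError, IncompleteDesignError, InputError

#: Landis-Koch strength-of-agreement categories, upper-inclusive.
_KAPPA_CATEGORIES = (
    (0.00, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class EpochLabels:
    """Binary per-epoch movement labels; dropped epochs are excluded wholesale."""

    epoch_s: float
    labels: np.ndarray
    dropped: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        dropped = np.asarray(self.dropped, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "dropped", dropped)
        if not np.all(np.isin(labels, (0, 1))):
            raise InputError("labels must be binary")
        if np.any(dropped < 0) or np.any(dropped >= len(labels)):
            raise InputError("dropped indices out of range")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.n_epochs, dtype=bool)
        mask[self.dropped] = False
        return mask


@dataclass(frozen=True)
class AgreementResult:
    po: float
    pabak: float
    kappa: float
    label: str
    n_epochs: int


@dataclass(frozen=True)
class SessionSummary:
    subject_id: str
    gestational_week: int
    n_movements: int
    analysis_time_h: float
    movements_per_hour: float
    n_hiccup_bouts: int
    flags: dict[str, bool]


@dataclass(frozen=True)
class RMAnovaResult:
    """One-way repeated-measures ANOVA by the classical SS decomposition."""

    f_condition: float
    df_condition: int
    df_error: int
    p_condition: float
    f_subject: float
    df_subject: int
    p_subject: float
    ms_error: float
    ss_total: float
    ss_subjects: float
    ss_conditions: float
    ss_error: float
    n_subjects: int
    n_conditions: int


@dataclass(frozen=True)
class PairwiseComparison:
    session_a: int
    session_b: int
    mean_diff: float
    f_contrast: float
    p_value: float
    significant: bool


def epoch_labels(
    fm_events: list[SignalEvent],
    mask: AnalysisMask,
    total_s: float,
    epoch_s: float = 10.0,
) -> EpochLabels:
    """Label each epoch 1 iff any accepted FM event intersects it.

    Epochs intersecting wake/restroom/edge-transient mask intervals are
    dropped entirely (not truncated).
    """
    if epoch_s <= 0:
        raise InputError("epoch_s must be positive")
    n = int(total_s // epoch_s)
    labels = np.zeros(n, dtype=np.int8)
    for ev in accepted(fm_events):
        first = max(int(ev.start_s // epoch_s), 0)
        last = min(int(math.ceil(ev.end_s / epoch_s)), n)
        labels[first:last] = 1
    dropped = set()
    for iv in mask.intervals:
        if iv.reason not in TIME_EXCLUDING_REASONS:
            continue
        first = max(int(iv.start_s // epoch_s), 0)
        last = min(int(math.ceil(iv.end_s / epoch_s)), n)
        dropped.update(range(first, last))
    return EpochLabels(
        epoch_s=epoch_s, labels=labels, dropped=np.array(sorted(dropped), dtype=int)
    )


def kappa_label(k: float) -> str:
    """Landis-Koch strength-of-agreement category for a kappa-type statistic."""
    if not -1.0 <= k <= 1.0:
        raise InputError(f"kappa {k} outside [-1, 1]")
    if k <= 0.0:
        return "poor"
    for upper, name in _KAPPA_CATEGORIES[1:]:
        if k <= upper:
            return name
    raise AssertionError("unreachable")


def pabak(a: EpochLabels, b: EpochLabels) -> AgreementResult:
    """Agreement of two labelings over their common non-dropped epochs.

    PABAK is exactly ``2*po - 1``; Cohen's kappa is computed from the 2x2
    table and defined as ``po`` when chance agreement equals 1.
    """
    if a.epoch_s != b.epoch_s or a.n_epochs != b.n_epochs:
        raise InputError("labelings must share the same epoch grid")
    common = a.valid_mask & b.valid_mask
    n = int(common.sum())
    if n == 0:
        raise InputError("no common non-dropped epochs to compare")
    la = a.labels[common].astype(float)
    lb = b.labels[common].astype(float)
    po = float(np.mean(la == lb))
    pa, pb = la.mean(), lb.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    kappa = po if pe == 1.0 else (po - pe) / (1 - pe)
    value = 2.0 * po - 1.0
    return AgreementResult(
        po=po, pabak=value, kappa=float(kappa), label=kappa_label(value), n_epochs=n
    )


def session_summary(
    fm_events: list[SignalEvent],
    mask: AnalysisMask,
    subject_id: str,
    gestational_week: int,
    flags: dict[str, bool] | None = None,
) -> SessionSummary:
    """Accepted-movement count and per-hour rate over the analysis time."""
    analysis_s = mask.analysis_time_s
    if analysis_s <= 0:
        raise DegenerateSessionError("session has zero analysis time")
    n = len(accepted(fm_events))
    hours = analysis_s / 3600.0
    return SessionSummary(
        subject_id=subject_id,
        gestational_week=gestational_week,
        n_movements=n,
        analysis_time_h=hours,
        movements_per_hour=n / hours,
        n_hiccup_bouts=len(mask.by_reason("hiccup_bout")),
        flags=dict(flags or {}),
    )


def aggregate_mean_sd(values: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator); SD is NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot aggregate an empty list")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    return mean, sd


def rm_anova(table: np.ndarray, drop_incomplete: bool = False) -> RMAnovaResult:
    """One-way within-subject ANOVA on a subjects-by-sessions matrix.

    The classical decomposition SS_total = SS_subjects + SS_conditions +
    SS_error is used; ``F_condition = MS_cond / MS_error`` with degrees of
    freedom ``(s-1, (s-1)(n-1))``.  Missing cells raise unless
    ``drop_incomplete`` removes the affected subjects (no imputation).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise InputError("table must be 2-D (subjects x sessions)")
    incomplete = np.any(np.isnan(x), axis=1)
    if np.any(incomplete):
        if not drop_incomplete:
            raise IncompleteDesignError(
                f"{int(incomplete.sum())} subject(s) have missing sessions; "
                "pass drop_incomplete=True to analyse complete cases only"
            )
        x = x[~incomplete]
    n, s = x.shape
    if n < 2 or s < 2:
        raise InputError("need at least 2 subjects and 2 sessions")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    ss_subjects = float(s * np.sum((row_means - grand) ** 2))
    ss_conditions = float(n * np.sum((col_means - grand) ** 2))
    ss_error = ss_total - ss_subjects - ss_conditions
    df_cond = s - 1
    df_subj = n - 1
    df_err = df_cond * df_subj
    ms_cond = ss_conditions / df_cond
    ms_subj = ss_subjects / df_subj
    ms_err = ss_error / df_err

    def _f_and_p(ms_effect: float, df_effect: int) -> tuple[float, float]:
        if ms_err <= 0:
            if ms_effect <= 0:
                return 0.0, 1.0
            return float("inf"), 0.0
        f = ms_effect / ms_err
        return f, float(stats.f.sf(f, df_effect, df_err))

    f_cond, p_cond = _f_and_p(ms_cond, df_cond)
    f_subj, p_subj = _f_and_p(ms_subj, df_subj)
    return RMAnovaResult(
        f_condition=f_cond,
        df_condition=df_cond,
        df_error=df_err,
        p_condition=p_cond,
        f_subject=f_subj,
        df_subject=df_subj,
        p_subject=p_subj,
        ms_error=ms_err,
        ss_total=ss_total,
        ss_subjects=ss_subjects,
        ss_conditions=ss_conditions,
        ss_error=ss_error,
        n_subjects=n,
        n_conditions=s,
    )


def scheffe_posthoc(
    table: np.ndarray,
    anova: RMAnovaResult,
    alpha: float = 0.05,
    drop_incomplete: bool = False,
) -> list[PairwiseComparison]:
    """Scheffé-adjusted pairwise session contrasts using the RM-ANOVA error term.

    For sessions i, j the contrast F is ``n * diff^2 / (2 * MS_error)``;
    the pair is significant when ``F >= (s-1) * F_crit(alpha, s-1, df_error)``,
    equivalently when ``F / (s-1)`` exceeds the alpha quantile, which also
    yields the adjusted p-value.
    """
    x = np.asarray(table, dtype=float)
    if drop_incomplete:
        x = x[~np.any(np.isnan(x), axis=1)]
    n, s = x.shape
    if (n, s) != (anova.n_subjects, anova.n_conditions):
        raise InputError("table shape does not match the ANOVA result")
    col_means = x.mean(axis=0)
    out = []
    for i in range(s):
        for j in range(i + 1, s):
            diff = float(col_means[i] - col_means[j])
            if anova.ms_error <= 0:
                f_contrast = float("inf") if diff != 0 else 0.0
            else:
                f_contrast = n * diff**2 / (2.0 * anova.ms_error)
            scaled = f_contrast / anova.df_condition
            p = float(stats.f.sf(scaled, anova.df_condition, anova.df_error))
            out.append(
                PairwiseComparison(
                    session_a=i,
                    session_b=j,
                    mean_diff=diff,
                    f_contrast=f_contrast,
                    p_value=p,
                    significant=bool(p < alpha),
                )
            )
    return out
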