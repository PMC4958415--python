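"""Precision/accuracy statistics, t-quantile multipliers and effective dose.

Precision is summarised from double-examination differences d_prec (two
acquisitions with unchanged cup-to-pelvis pose): per component the
reported figure is ``t * SD`` where SD is computed about zero (the true
difference), so n differences carry n degrees of freedom and the
two-sided 95% multiplier for n = 6 is 2.45.

Accuracy is summarised from the differences d_accur = gold - method of
pairwise migrations against a gold standard: per component ``t * RMS``
with RMS = sqrt(mean(d^2)) and the multiplier at n - 1 d.o.f. (2.57 for
n = 6).  Both tables also report the mean, min and max of the raw
differences, component-wise, never as vector norms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, PairingError, ValidationError
from .migration import COMPONENTS, MigrationResult

COMPONENT_LABELS = (
    "translation_x_mm",
    "translation_y_mm",
    "translation_z_mm",
    "rotation_x_deg",
    "rotation_y_deg",
    "rotation_z_deg",
)


def t_quantile(p: float, dof: int, two_sided: bool = True) -> float:
    """Student-t quantile used as a precision/accuracy multiplier.

    With ``two_sided=True`` (default) returns the quantile bounding the
    central probability-``p`` interval, i.e. ``t_{(1+p)/2, dof}``; this is
    the convention behind the 2.45 (p=0.95, dof=6) and 2.57 (p=0.95,
    dof=5) multipliers.  With ``two_sided=False`` returns the plain
    one-sided quantile (so p=0.5 gives 0).
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"probability must be in (0, 1), got {p}")
    if dof < 1:
        raise ValidationError(f"degrees of freedom must be >= 1, got {dof}")
    q = (1.0 + p) / 2.0 if two_sided else p
    return float(sps.t.ppf(q, dof))


def _component_matrix(migrations: Sequence[MigrationResult]) -> np.ndarray:
    return np.array([m.components for m in migrations], dtype=float)


@dataclass(frozen=True)
class PrecisionSummary:
    """Component-wise precision table (multiplier*SD | mean | min | max)."""

    table: pd.DataFrame
    multiplier: float
    dof: int
    n: int

    @property
    def translations(self) -> pd.DataFrame:
        return self.table.iloc[:3]

    @property
    def rotations(self) -> pd.DataFrame:
        return self.table.iloc[3:]


@dataclass(frozen=True)
class AccuracySummary:
    """Component-wise accuracy table (multiplier*RMS | mean | min | max)."""

    table: pd.DataFrame
    multiplier: float
    dof: int
    n: int


def precision_summary(
    double_exam_migrations: Sequence[MigrationResult],
    p: float = 0.95,
    center: str = "zero",
) -> PrecisionSummary:
    """Precision from within-position double-examination differences.

    ``center="zero"`` (default) computes SD about the true value zero,
    sqrt(sum(d^2)/n), carrying n d.o.f.; ``center="mean"`` subtracts the
    sample mean and uses n - 1 d.o.f.
    """
    if len(double_exam_migrations) < 2:
        raise InsufficientDataError(
            f"precision needs >= 2 double-examination differences, "
            f"got {len(double_exam_migrations)}"
        )
    diffs = _component_matrix(double_exam_migrations)
    n = diffs.shape[0]
    if center == "zero":
        sd = np.sqrt(np.mean(diffs**2, axis=0))
        dof = n
    elif center == "mean":
        sd = np.std(diffs, axis=0, ddof=1)
        dof = n - 1
    else:
        raise ValidationError(f"center must be 'zero' or 'mean', got {center!r}")
    mult = t_quantile(p, dof)
    table = pd.DataFrame(
        {
            f"{mult:.2f}*SD": mult * sd,
            "Mean": diffs.mean(axis=0),
            "Min": diffs.min(axis=0),
            "Max": diffs.max(axis=0),
        },
        index=list(COMPONENT_LABELS),
    )
    return PrecisionSummary(table=table, multiplier=mult, dof=dof, n=n)


def _check_paired(
    method: Sequence[MigrationResult], gold: Sequence[MigrationResult]
) -> None:
    if len(method) != len(gold):
        raise PairingError(
            f"method has {len(method)} migrations but gold has {len(gold)}"
        )
    for m, g in zip(method, gold):
        key_m = (m.position_a, m.position_b, m.series)
        key_g = (g.position_a, g.position_b, g.series)
        if None not in key_m and None not in key_g and key_m != key_g:
            raise PairingError(
                f"migration pairing mismatch: method {key_m} vs gold {key_g}"
            )


def accuracy_summary(
    method_migrations: Sequence[MigrationResult],
    gold_migrations: Sequence[MigrationResult],
    p: float = 0.95,
) -> AccuracySummary:
    """Accuracy of a method against a gold standard, d = gold - method."""
    if len(method_migrations) < 2:
        raise InsufficientDataError(
            f"accuracy needs >= 2 paired migrations, got {len(method_migrations)}"
        )
    _check_paired(method_migrations, gold_migrations)
    diffs = _component_matrix(gold_migrations) - _component_matrix(method_migrations)
    n = diffs.shape[0]
    rms = np.sqrt(np.mean(diffs**2, axis=0))
    mult = t_quantile(p, n - 1)
    table = pd.DataFrame(
        {
            f"{mult:.2f}*RMS": mult * rms,
            "Mean": diffs.mean(axis=0),
            "Min": diffs.min(axis=0),
            "Max": diffs.max(axis=0),
        },
        index=list(COMPONENT_LABELS),
    )
    return AccuracySummary(table=table, multiplier=mult, dof=n - 1, n=n)


@dataclass(frozen=True)
class DoseEstimate:
    """Effective dose from a CT dose-length product."""

    dlp: float  # mGy*cm
    k: float  # mSv / (mGy*cm)

    @property
    def effective_dose(self) -> float:
        return self.dlp * self.k


def effective_dose(dlp: float, k: float) -> float:
    """Effective dose (mSv) = DLP (mGy*cm) x body-region factor k (mSv/(mGy*cm))."""
    if dlp < 0 or k < 0:
        raise ValidationError(f"dlp and k must be non-negative, got dlp={dlp}, k={k}")
    return DoseEstimate(dlp=dlp, k=k).effective_dose


@dataclass(frozen=True)
class NormalityReport:
    """Advisory Gaussianity diagnostics of a difference sample."""

    n: int
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    shapiro_p: float
    qq_r2: float
    degenerate: bool
    departure_flagged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def normality_check(
    differences: Sequence[float],
    plot_path=None,
    qq_r2_limit: float = 0.95,
    shapiro_alpha: float = 0.01,
) -> NormalityReport:
    """Histogram/quantile-quantile style normality diagnostics (advisory only).

    A departure is flagged when the normal quantile-quantile correlation
    drops below ``qq_r2_limit`` or the Shapiro-Wilk p-value below
    ``shapiro_alpha``; constant samples are reported as degenerate.  When
    ``plot_path`` is given and matplotlib is available, a histogram + Q-Q
    figure is saved there.
    """
    x = np.asarray(differences, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"normality check needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        return NormalityReport(
            n=x.size, mean=float(x.mean()), sd=0.0, skewness=0.0,
            excess_kurtosis=0.0, shapiro_p=float("nan"), qq_r2=float("nan"),
            degenerate=True, departure_flagged=False,
        )
    (osm, osr), (slope, intercept, r) = sps.probplot(x, dist="norm")
    shapiro_p = float(sps.shapiro(x).pvalue)
    qq_r2 = float(r**2)
    report = NormalityReport(
        n=x.size,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=float(sps.skew(x)),
        excess_kurtosis=float(sps.kurtosis(x)),
        shapiro_p=shapiro_p,
        qq_r2=qq_r2,
        degenerate=False,
        departure_flagged=(qq_r2 < qq_r2_limit) or (shapiro_p < shapiro_alpha),
    )
    if plot_path is not None:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:
            return report
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].hist(x, bins="auto")
        axes[0].set_title("differences")
        axes[1].plot(osm, osr, "o", ms=3)
        axes[1].plot(osm, slope * osm + intercept, "-")
        axes[1].set_title(f"normal Q-Q (r^2={qq_r2:.3f})")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return report
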