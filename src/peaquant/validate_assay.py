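"""Analytical-validation metrics for the quantified panel.

* Linearity of dilution: a high- and a low-concentration native sample are
  mixed at equally spaced ratios; each mixture's theoretical concentration
  is ``r * high + (1 - r) * low`` and the relative error is
  ``(measured - theoretical) / theoretical``.
* QC accuracy and intra-assay precision: for each QC pool, accuracy is the
  replicate mean over the reference value (as a percent, accepted within
  75-125%) and the CV is the replicate SD over the mean.
* Dynamic-range coverage: per-assay fractions of samples below LLOQ, in
  range and above ULOQ.
* Method comparison against a reference assay on the log2 scale: Spearman
  correlation, least-squares r^2, and Bland-Altman mean / SD / limits of
  agreement (mean +/- 1.96 SD of the paired log2 differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_model import ValidationError
from .quantify import FLAG_ABOVE_ULOQ, FLAG_BELOW_LLOQ, FLAG_BELOW_LOD, FLAG_IN_RANGE

QC_ACCEPT_LO = 75.0
QC_ACCEPT_HI = 125.0


@dataclass(frozen=True)
class LinearitySet:
    """One assay's sample-in-sample dilution linearity experiment."""

    assay_id: str
    high_conc: float
    low_conc: float
    ratios: tuple[float, ...]
    measured: tuple[float, ...]
    theoretical: tuple[float, ...]
    relative_error: tuple[float, ...]

    @property
    def max_abs_relative_error(self) -> float:
        return max(abs(e) for e in self.relative_error)

    @property
    def mean_relative_error(self) -> float:
        return sum(self.relative_error) / len(self.relative_error)

    def to_row(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "high_conc": self.high_conc,
            "low_conc": self.low_conc,
            "n_mixtures": len(self.ratios),
            "max_abs_relative_error": self.max_abs_relative_error,
            "mean_relative_error": self.mean_relative_error,
        }


def linearity_analysis(
    high_conc: float,
    low_conc: float,
    mixtures,
    ratios,
    assay_id: str = "",
) -> LinearitySet:
    """Relative error of mixed samples against their mixing-theoretical value."""
    if not (high_conc > low_conc > 0):
        raise ValidationError("need high_conc > low_conc > 0")
    ratios = tuple(float(r) for r in ratios)
    measured = tuple(float(m) for m in mixtures)
    if len(ratios) != len(measured):
        raise ValidationError("ratios and measured values must be paired")
    if any(r < 0 or r > 1 for r in ratios):
        raise ValidationError("mixing ratios must lie in [0, 1]")
    theoretical = tuple(r * high_conc + (1.0 - r) * low_conc for r in ratios)
    if any(t <= 0 for t in theoretical):
        raise ValidationError("theoretical concentration must be positive")
    rel = tuple((m - t) / t for m, t in zip(measured, theoretical))
    return LinearitySet(
        assay_id=assay_id, high_conc=high_conc, low_conc=low_conc,
        ratios=ratios, measured=measured, theoretical=theoretical, relative_error=rel,
    )


@dataclass(frozen=True)
class QCReport:
    """Accuracy and intra-assay precision of one QC pool."""

    plate_id: str
    assay_id: str
    pool: str
    accuracy_pct: float
    cv_pct: float
    n_replicates: int

    @property
    def passed(self) -> bool:
        return QC_ACCEPT_LO <= self.accuracy_pct <= QC_ACCEPT_HI

    def to_row(self) -> dict:
        return {
            "plate_id": self.plate_id, "assay_id": self.assay_id, "pool": self.pool,
            "accuracy_pct": self.accuracy_pct, "cv_pct": self.cv_pct,
            "n_replicates": self.n_replicates, "pass": self.passed,
        }


def qc_metrics(
    replicates, reference: float, plate_id: str = "", assay_id: str = "", pool: str = "qc1"
) -> QCReport:
    """Accuracy % = replicate mean / reference * 100; CV % = SD / mean * 100.

    Sample (n-1) standard deviation.  Replicates may be the 3 wells of one
    plate or the 6 of a chip's plate pair, per the caller's pooling choice.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValidationError("need >=2 QC replicates")
    if reference <= 0:
        raise ValidationError("reference concentration must be positive")
    if np.any(reps <= 0):
        raise ValidationError("QC replicate concentrations must be positive")
    mean = float(np.mean(reps))
    sd = float(np.std(reps, ddof=1))
    return QCReport(
        plate_id=plate_id, assay_id=assay_id, pool=pool,
        accuracy_pct=mean / reference * 100.0, cv_pct=sd / mean * 100.0,
        n_replicates=int(reps.size),
    )


def dynamic_range_report(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-assay fractions of samples below LLOQ, in range and above ULOQ.

    Below-LOD counts toward below-LLOQ (a sample invisible to the assay is
    a fortiori not quantifiable).  Fractions sum to 1 per assay.
    """
    rows = []
    for aid, grp in quant.groupby("assay_id", sort=False):
        flags = grp["flag"]
        n = len(grp)
        n_below = int(flags.isin([FLAG_BELOW_LLOQ, FLAG_BELOW_LOD]).sum())
        n_above = int((flags == FLAG_ABOVE_ULOQ).sum())
        n_in = int((flags == FLAG_IN_RANGE).sum())
        rows.append({
            "assay_id": aid, "n": n,
            "n_below_lloq": n_below, "n_in_range": n_in, "n_above_uloq": n_above,
            "frac_below_lloq": n_below / n, "frac_in_range": n_in / n,
            "frac_above_uloq": n_above / n,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MethodComparison:
    """Agreement of PEA quantification with a reference method (log2 scale)."""

    assay_id: str
    n: int
    spearman_rho: float
    r2: float
    ba_mean: float
    ba_sd: float

    @property
    def ba_limits(self) -> tuple[float, float]:
        return (self.ba_mean - 1.96 * self.ba_sd, self.ba_mean + 1.96 * self.ba_sd)

    def to_row(self) -> dict:
        lo, hi = self.ba_limits
        return {
            "assay_id": self.assay_id, "n": self.n, "spearman_rho": self.spearman_rho,
            "r2": self.r2, "ba_mean": self.ba_mean, "ba_sd": self.ba_sd,
            "ba_lo": lo, "ba_hi": hi,
        }


def method_comparison(pea, reference, assay_id: str = "") -> MethodComparison:
    """Spearman rho, regression r^2 and Bland-Altman stats on log2 values.

    The Bland-Altman difference is log2(pea) - log2(reference), so a method
    reading systematically high has a positive mean difference.
    """
    pea = np.asarray(pea, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pea.shape != ref.shape or pea.size < 3:
        raise ValidationError("need >=3 paired measurements")
    if np.any(pea <= 0) or np.any(ref <= 0):
        raise ValidationError("concentrations must be positive for the log2 scale")
    lp, lr = np.log2(pea), np.log2(ref)
    rho = float(stats.spearmanr(lp, lr).statistic)
    if np.ptp(lp) == 0 or np.ptp(lr) == 0:
        r2 = 1.0 if np.allclose(lp - lp.mean(), lr - lr.mean()) else 0.0
    else:
        r2 = float(stats.pearsonr(lp, lr).statistic ** 2)
    diff = lp - lr
    ba_sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    return MethodComparison(
        assay_id=assay_id, n=int(pea.size), spearman_rho=rho, r2=r2,
        ba_mean=float(np.mean(diff)), ba_sd=ba_sd,
    )
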