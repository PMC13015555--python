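"""Autoantibody ELISA analysis.

Seropositivity thresholding by ROC / Youden's J, quantification of antibody
levels against monoclonal standard curves (four-parameter logistic), and the
correlation / multiple-testing utilities used alongside them.

Conventions
-----------
* A sample is called seropositive when its background-corrected OD is
  greater than **or equal to** the threshold (the dashed-line convention:
  a point lying on the line is positive).
* Youden ties are broken toward the *lowest* candidate threshold, which
  maximises sensitivity for a screening biomarker and is deterministic.
* Percentages are rounded half-away-from-zero to one decimal place.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

GROUPS = ("HS", "UC")
ISOTYPES = ("IgG", "IgA")
ANTIGENS = ("avb6_human", "avb6_mouse", "avb3")

__all__ = [
    "RocCurve",
    "SeroThreshold",
    "StandardCurve",
    "QuantResult",
    "compute_roc",
    "youden_threshold",
    "classify_seropositive",
    "seropositivity_rates",
    "fit_standard_curve",
    "interpolate_concentration",
    "spearman_correlation",
    "fdr_adjust",
]


@dataclass(frozen=True)
class RocCurve:
    """ROC curve over candidate OD cutoffs.

    ``thresholds`` are sorted ascending and include a sentinel below the
    minimum observed OD (everything called positive) and one above the
    maximum (nothing positive).  ``tpr``/``fpr`` are aligned with
    ``thresholds`` under the rule *positive iff od >= threshold*, so both
    are monotone non-increasing in the threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class SeroThreshold:
    """An OD cutoff with its Youden index and operating characteristics."""

    value: float
    j: float
    sensitivity: float
    specificity: float


def compute_roc(
    measurements: pd.DataFrame,
    positive_group: str = "UC",
    od_col: str = "od",
    group_col: str = "group",
) -> RocCurve:
    """ROC curve discriminating ``positive_group`` from everyone else.

    The table should hold a single isotype/antigen combination; the OD of
    each subject is the classifier score.  AUC is the trapezoid area over
    (fpr, tpr), which for this threshold sweep equals the pairwise
    probability that a positive-group OD exceeds a control OD (ties
    counted 1/2).
    """
    od = np.asarray(measurements[od_col], dtype=float)
    bad = np.flatnonzero(~np.isfinite(od))
    if bad.size:
        raise ValueError(f"non-finite OD at row index {bad[0]}")
    grp = np.asarray(measurements[group_col])
    pos = od[grp == positive_group]
    neg = od[grp != positive_group]
    if pos.size == 0:
        raise ValueError(f"group {positive_group!r} has no measurements")
    if neg.size == 0:
        raise ValueError("comparison (non-positive) group has no measurements")

    uniq = np.unique(od)
    thresholds = np.concatenate(([uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]))
    # positive iff od >= threshold
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    # thresholds ascending -> fpr descending; integrate in fpr-ascending order
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def youden_threshold(roc: RocCurve) -> SeroThreshold:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the lowest threshold.  If no threshold does
    better than chance (max J == 0) a warning is emitted and the lowest
    candidate is returned with j = 0.
    """
    j = roc.tpr - roc.fpr
    jmax = j.max()
    idx = int(np.flatnonzero(j == jmax)[0])  # thresholds sorted ascending
    if jmax <= 0:
        warnings.warn(
            "no threshold separates the groups (max Youden J = 0)",
            stacklevel=2,
        )
    return SeroThreshold(
        value=float(roc.thresholds[idx]),
        j=float(jmax),
        sensitivity=float(roc.tpr[idx]),
        specificity=float(1.0 - roc.fpr[idx]),
    )


def classify_seropositive(od: float, threshold: SeroThreshold | float) -> bool:
    """Seropositive iff od >= threshold (boundary inclusive)."""
    if not np.isfinite(od):
        raise ValueError("od must be finite")
    value = threshold.value if isinstance(threshold, SeroThreshold) else float(threshold)
    return bool(od >= value)


def _round_half_away(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5 + 1e-9), x) / scale


def seropositivity_rates(
    measurements: pd.DataFrame,
    threshold: SeroThreshold | float,
    od_col: str = "od",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group positive counts and percentages at a fixed threshold.

    Percentages are 100*count/n rounded half-away-from-zero to 1 decimal
    place (the convention under which 173/194 prints as 89.2).  Empty
    groups get n = 0 and a NaN percentage.
    """
    value = threshold.value if isinstance(threshold, SeroThreshold) else float(threshold)
    rows = []
    for group, sub in measurements.groupby(group_col, sort=True):
        od = np.asarray(sub[od_col], dtype=float)
        n = int(od.size)
        n_pos = int((od >= value).sum())
        pct = _round_half_away(100.0 * n_pos / n, 1) if n else float("nan")
        rows.append({"group": group, "n": n, "n_positive": n_pos, "percent": pct})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# monoclonal standard curves (four-parameter logistic)
# ---------------------------------------------------------------------------


def _fourpl(conc, lower, upper, inflection, hill):
    conc = np.asarray(conc, dtype=float)
    return lower + (upper - lower) / (1.0 + (conc / inflection) ** (-hill))


@dataclass(frozen=True)
class StandardCurve:
    """Fitted 4PL calibration curve for a monoclonal antibody standard.

    ``od(conc)`` and ``concentration(od)`` are exact inverses on
    ``fit_range``; the curve is monotone increasing there (hill > 0).
    ``lloq`` is the lower limit of quantification in concentration units.
    """

    lower: float
    upper: float
    inflection: float
    hill: float
    fit_range: tuple[float, float]
    lloq: float

    def od(self, conc):
        return _fourpl(conc, self.lower, self.upper, self.inflection, self.hill)

    def concentration(self, od):
        ratio = (self.upper - self.lower) / (od - self.lower) - 1.0
        return self.inflection * ratio ** (-1.0 / self.hill)


def fit_standard_curve(
    standards: pd.DataFrame,
    conc_col: str = "concentration",
    od_col: str = "od",
    blank_ods=None,
) -> StandardCurve:
    """Least-squares 4PL fit of OD on standard concentration.

    Requires >= 5 distinct concentrations spanning >= 2 logs.  Replicates
    are averaged per concentration before checks; the fit itself uses all
    wells.  The LLOQ is the lowest standard concentration whose *fitted*
    OD exceeds blank mean + 3*blank SD when ``blank_ods`` are supplied,
    otherwise the lowest standard concentration.
    """
    conc = np.asarray(standards[conc_col], dtype=float)
    od = np.asarray(standards[od_col], dtype=float)
    if not (np.isfinite(conc).all() and np.isfinite(od).all()):
        raise ValueError("non-finite standards")
    if (conc <= 0).any():
        raise ValueError("standard concentrations must be positive")
    levels = np.unique(conc)
    if levels.size < 5:
        raise ValueError("need >= 5 distinct standard concentrations")
    if levels.max() / levels.min() < 100.0:
        raise ValueError("standards must span >= 2 logs of concentration")

    mean_od = np.array([od[conc == c].mean() for c in levels])
    if np.ptp(mean_od) < 1e-6 * max(1.0, np.abs(mean_od).max()):
        raise ValueError("flat standard curve: ODs do not vary with concentration")
    rho = stats.spearmanr(levels, mean_od).statistic
    if rho < 0.9:
        raise ValueError(
            f"standards are non-monotone beyond noise tolerance (rho={rho:.2f})"
        )

    p0 = [mean_od.min(), mean_od.max(), float(np.sqrt(levels.min() * levels.max())), 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 50.0])
    try:
        params, _ = optimize.curve_fit(
            _fourpl, conc, od, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        resid = od - _fourpl(conc, *p0)
        raise RuntimeError(
            f"4PL fit did not converge (initial residual SS={np.sum(resid ** 2):.4g})"
        ) from exc
    lower, upper, inflection, hill = (float(v) for v in params)

    fit_range = (float(levels.min()), float(levels.max()))
    if blank_ods is not None:
        blank_ods = np.asarray(blank_ods, dtype=float)
        cut = blank_ods.mean() + 3.0 * blank_ods.std(ddof=1)
        fitted = _fourpl(levels, lower, upper, inflection, hill)
        ok = np.flatnonzero(fitted > cut)
        if ok.size == 0:
            raise ValueError("no standard concentration exceeds blank mean + 3 SD")
        lloq = float(levels[ok[0]])
    else:
        lloq = fit_range[0]
    return StandardCurve(lower, upper, inflection, hill, fit_range, lloq)


@dataclass(frozen=True)
class QuantResult:
    """Interpolated antibody level for one sample.

    ``concentration`` is in monoclonal-equivalent binding units and is
    ``None`` exactly when ``below_lloq``; ``above_range`` marks ODs at or
    above the upper end of the calibrated range, which are clamped to the
    maximum standard concentration rather than extrapolated.
    """

    subject_id: str | None
    concentration: float | None
    below_lloq: bool
    above_range: bool = False


def interpolate_concentration(
    od: float, curve: StandardCurve, subject_id: str | None = None
) -> QuantResult:
    """Inverse-4PL quantification of one OD against a fitted curve."""
    if not np.isfinite(od):
        raise ValueError("od must be finite")
    if od <= float(curve.od(curve.lloq)):
        return QuantResult(subject_id, None, below_lloq=True)
    if od >= float(curve.od(curve.fit_range[1])) or od >= curve.upper:
        return QuantResult(subject_id, curve.fit_range[1], below_lloq=False, above_range=True)
    conc = float(curve.concentration(od))
    return QuantResult(subject_id, conc, below_lloq=False)


# ---------------------------------------------------------------------------
# correlation and multiple-testing plumbing
# ---------------------------------------------------------------------------


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Mid-ranks handle ties.  For n <= 10 the p-value is an exact
    permutation tail over all n! pairings; for larger n the usual
    t-approximation with n-2 df is used.  Zero rank variance in either
    variable yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance: rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = _rank_corr(rx, ry)

    n = x.size
    if n <= 10:
        obs = abs(rho)
        count = 0
        total = 0
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = np.sqrt((cx @ cx) * (cy @ cy))
        for perm in itertools.permutations(range(n)):
            r = abs(float(cx @ cy[list(perm)]) / denom)
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    else:
        with np.errstate(divide="ignore"):
            t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, float(min(1.0, p))


def fdr_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Two-stage Benjamini-Krieger-Yekutieli step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_tsbky")[1]
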