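"""Function-blocking assay statistics.

Cell adhesion to latent TGF-beta (or fibronectin) is read out as adherent
cells per well; serum that blocks integrin binding lowers adherence.  This
module normalises plates to their untreated wells, computes the percent
inhibition of each serum relative to the healthy-subject (HS) mean,

    percent inhibition = (1 - sample mean adherence / HS mean adherence) * 100,

tests each sample against the HS wells with a one-sided Welch t test
(alternative: sample adherence *below* the HS mean -- blocking can only
reduce adherence), and classifies a serum as inhibitory when percent
inhibition >= 30 and p <= 0.05, both boundaries inclusive.

TGF-beta reporter assays (SEAP OD620 readout) are summarised per sample as
the ratio to the mean reporter activity across HS controls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InhibitionResult",
    "DilutionCurve",
    "normalize_adherence",
    "percent_inhibition",
    "welch_one_sided",
    "exact_permutation_p",
    "classify_inhibitory",
    "classify_samples",
    "reporter_activation",
    "dilution_series",
]


@dataclass(frozen=True)
class InhibitionResult:
    sample_id: str
    pct_inhibition: float
    p_one_sided: float
    inhibitory: bool
    n_sample: int
    n_hs: int


@dataclass(frozen=True)
class DilutionCurve:
    """Percent inhibition of one serum across a serial dilution.

    ``dilutions`` are strictly increasing fold-dilutions; ``monotone_flag``
    is set when inhibition *increases* with further dilution beyond
    ``tolerance`` percentage points (a physically implausible pattern that
    is flagged rather than rejected).
    """

    sample_id: str
    dilutions: np.ndarray
    pct_inhibition: np.ndarray
    monotone_flag: bool


def normalize_adherence(
    plate: pd.DataFrame,
    condition_col: str = "condition",
    value_col: str = "adherent",
    untreated_label: str = "untreated",
) -> pd.Series:
    """Per-well adherence as a fraction of the plate's untreated mean."""
    values = pd.to_numeric(plate[value_col])
    untreated = values[plate[condition_col] == untreated_label]
    if untreated.empty:
        raise ValueError("plate has no untreated wells")
    ref = float(untreated.mean())
    if ref <= 0:
        raise ValueError("untreated mean adherence must be > 0")
    return values / ref


def percent_inhibition(sample_mean_adherence: float, hs_mean_adherence: float) -> float:
    """(1 - sample/HS) * 100; negative when adherence exceeds the HS mean."""
    if hs_mean_adherence <= 0:
        raise ValueError("HS mean adherence must be > 0")
    return (1.0 - sample_mean_adherence / hs_mean_adherence) * 100.0


def welch_one_sided(sample_reps, hs_reps) -> float:
    """One-sided Welch t test of sample adherence below the HS mean.

    Welch t with Satterthwaite degrees of freedom; returns the one-sided
    p-value for the alternative ``mean(sample) < mean(hs)``.
    """
    s = np.asarray(sample_reps, dtype=float)
    h = np.asarray(hs_reps, dtype=float)
    if s.size < 2 or h.size < 2:
        raise ValueError("need >= 2 replicates per arm")
    if not (np.isfinite(s).all() and np.isfinite(h).all()):
        raise ValueError("non-finite replicate values")
    if s.var(ddof=1) == 0 and h.var(ddof=1) == 0:
        if s.mean() == h.mean():
            warnings.warn("zero variance in both arms with equal means; p = 0.5",
                          stacklevel=2)
            return 0.5
        return 0.0 if s.mean() < h.mean() else 1.0
    return float(stats.ttest_ind(s, h, equal_var=False, alternative="less").pvalue)


def _welch_t(s: np.ndarray, h: np.ndarray) -> float:
    vs = s.var(ddof=1) / s.size
    vh = h.var(ddof=1) / h.size
    denom = np.sqrt(vs + vh)
    if denom == 0:
        return 0.0
    return float((s.mean() - h.mean()) / denom)


def exact_permutation_p(sample_reps, hs_reps) -> float:
    """Exhaustive permutation p-value for the one-sided Welch comparison.

    Relabels the pooled replicates over every split of the observed arm
    sizes, using the Welch t statistic, and reports a leave-observed-out
    mid-p: the fraction of *other* labelings with t below the observed
    (ties counted 1/2).  The mid-p convention makes the discrete
    permutation tail comparable to a continuous parametric p-value.
    """
    s = np.asarray(sample_reps, dtype=float)
    h = np.asarray(hs_reps, dtype=float)
    pooled = np.concatenate([s, h])
    n, n1 = pooled.size, s.size
    t_obs = _welch_t(s, h)
    below = ties = total = 0
    identity = tuple(range(n1))
    for idx in itertools.combinations(range(n), n1):
        if idx == identity:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        t = _welch_t(pooled[mask], pooled[~mask])
        if t < t_obs - 1e-12:
            below += 1
        elif t <= t_obs + 1e-12:
            ties += 1
        total += 1
    return (below + 0.5 * ties) / total


def classify_inhibitory(pct: float, p: float,
                        min_inhibition: float = 30.0, alpha: float = 0.05) -> bool:
    """Inhibitory iff pct >= 30 and p <= 0.05 (boundaries inclusive)."""
    if not (np.isfinite(pct) and np.isfinite(p)):
        raise ValueError("inputs must be finite")
    return bool(pct >= min_inhibition and p <= alpha)


def classify_samples(
    wells: pd.DataFrame,
    hs_sample_ids,
    plate_col: str = "plate_id",
    condition_col: str = "condition",
    sample_col: str = "sample_id",
    value_col: str = "adherent",
    serum_label: str = "serum",
    min_inhibition: float = 30.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-sample classification over one or more plates.

    Each plate is normalised to its own untreated wells; the HS reference
    is the pooled mean of all HS serum wells *on the same plate* (same-
    plate pooling controls batch effects).  Every non-HS serum sample on
    the plate is then scored and tested against those HS wells.
    """
    hs_ids = set(hs_sample_ids)
    rows = []
    for plate_id, plate in wells.groupby(plate_col, sort=True):
        frac = normalize_adherence(plate, condition_col, value_col)
        serum = plate[plate[condition_col] == serum_label]
        hs_mask = serum[sample_col].isin(hs_ids)
        hs_frac = frac[serum.index[hs_mask]].to_numpy()
        if hs_frac.size == 0:
            raise ValueError(f"plate {plate_id!r} has no HS serum wells")
        for sid, sub in serum[~hs_mask].groupby(sample_col, sort=True):
            s_frac = frac[sub.index].to_numpy()
            pct = percent_inhibition(s_frac.mean(), hs_frac.mean())
            p = welch_one_sided(s_frac, hs_frac)
            rows.append(
                {
                    "plate_id": plate_id,
                    "sample_id": sid,
                    "pct_inhibition": pct,
                    "p_one_sided": p,
                    "inhibitory": classify_inhibitory(pct, p, min_inhibition, alpha),
                    "n_sample": s_frac.size,
                    "n_hs": hs_frac.size,
                }
            )
    return pd.DataFrame(rows)


def reporter_activation(
    reporter: pd.DataFrame,
    hs_sample_ids,
    sample_col: str = "sample_id",
    od_col: str = "od620",
) -> pd.DataFrame:
    """Per-sample reporter activity relative to the HS control mean.

    Returns one row per sample with its mean OD620 and the ratio to the
    mean of per-sample HS means (so HS ratios average to exactly 1).
    """
    hs_ids = set(hs_sample_ids)
    means = reporter.groupby(sample_col, sort=True)[od_col].mean()
    hs_means = means[means.index.isin(hs_ids)]
    if hs_means.empty:
        raise ValueError("no HS control samples present")
    ref = float(hs_means.mean())
    if ref <= 0:
        raise ValueError("HS mean reporter activity must be > 0")
    out = means.rename("mean_od620").to_frame()
    out["ratio_to_hs"] = means / ref
    out["is_hs"] = out.index.isin(hs_ids)
    return out


def dilution_series(
    sample_id: str,
    dilutions,
    sample_mean_adherence,
    hs_mean_adherence,
    tolerance: float = 5.0,
) -> DilutionCurve:
    """Percent inhibition across a serial dilution of one serum.

    ``hs_mean_adherence`` may be a scalar (shared reference) or
    per-dilution.  Inhibition is expected to be non-increasing as the
    serum is diluted out; violations beyond ``tolerance`` percentage
    points set ``monotone_flag`` (flagged, not rejected).
    """
    dil = np.asarray(dilutions, dtype=float)
    if dil.size < 3:
        raise ValueError("need >= 3 dilutions")
    if np.unique(dil).size != dil.size:
        raise ValueError("duplicate dilutions")
    order = np.argsort(dil)  # increasing fold = more dilute
    adh = np.asarray(sample_mean_adherence, dtype=float)[order]
    hs = np.broadcast_to(np.asarray(hs_mean_adherence, dtype=float), dil.shape)[order]
    pct = np.array([percent_inhibition(a, h) for a, h in zip(adh, hs)])
    flag = bool((np.diff(pct) > tolerance).any())
    return DilutionCurve(sample_id, dil[order], pct, flag)
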