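"""NanoSIMS C₂⁻ dimer counts → δ¹³C, enrichment statistics, outliers.

NanoSIMS measures mat carbon as diatomic secondary ions.  Under
binomial pairing of carbon atoms with ¹³C atom fraction f, the
measured count ratio m = ¹³C¹²C/¹²C¹²C satisfies

    m = 2f(1−f)/(1−f)² = 2f/(1−f) = 2r,

so the atom ratio r = ¹³C/¹²C is recovered exactly as m/2 (the ¹³C₂
dimer never enters this particular ratio).  δ¹³C is then expressed in
permil against VPDB (R = 0.0112372).

Group comparisons follow a normality-gated protocol: Shapiro–Wilk on
each group, Student's t-test when both pass, Wilcoxon rank-sum
(Mann–Whitney) otherwise.  Tukey-fence outliers (1.5×IQR) are flagged
but always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_VPDB",
    "IsotopeSpot",
    "DeltaValue",
    "GatedTestResult",
    "EnrichmentSummary",
    "delta_from_ratio",
    "ratio_from_delta",
    "dimer_to_ratio",
    "spot_deltas",
    "enrichment_vs_control",
    "gated_test",
    "flag_outliers",
]

#: ¹³C/¹²C of the Vienna Pee Dee Belemnite standard.
R_VPDB = 0.0112372


@dataclass(frozen=True)
class IsotopeSpot:
    """Ion counts for one NanoSIMS spot measurement."""

    region_id: str
    probe: str
    treatment: str
    counts_12C12C: float
    counts_13C12C: float

    def __post_init__(self) -> None:
        if self.counts_12C12C < 0 or self.counts_13C12C < 0:
            raise ValueError("ion counts must be non-negative")


@dataclass(frozen=True)
class DeltaValue:
    """A ¹³C composition in its three equivalent representations."""

    delta13C_permil: float
    atom_ratio: float
    atom_fraction: float


def delta_from_ratio(r: float) -> float:
    """δ¹³C (permil vs VPDB) from the atom ratio r = ¹³C/¹²C."""
    return (r / R_VPDB - 1.0) * 1000.0


def ratio_from_delta(delta_permil: float) -> float:
    """Atom ratio r from δ¹³C; δ must exceed −1000 ‰ (r > 0)."""
    if delta_permil <= -1000.0:
        raise ValueError("delta must exceed -1000 permil (atom ratio > 0)")
    return R_VPDB * (1.0 + delta_permil / 1000.0)


def dimer_to_ratio(counts_12C12C: float, counts_13C12C: float) -> DeltaValue:
    """Dimer-corrected isotope composition from C₂⁻ ion counts.

    The ¹³C¹²C/¹²C¹²C count ratio is twice the atom ratio under
    binomial pairing; halving it recovers r, from which the atom
    fraction and δ¹³C follow.
    """
    if counts_12C12C <= 0:
        raise ValueError("counts_12C12C must be positive to form a ratio")
    if counts_13C12C < 0:
        raise ValueError("counts_13C12C must be non-negative")
    m = counts_13C12C / counts_12C12C
    r = m / 2.0
    f = r / (1.0 + r)
    return DeltaValue(delta13C_permil=delta_from_ratio(r),
                      atom_ratio=r, atom_fraction=f)


def spot_deltas(spots: Sequence[IsotopeSpot]) -> np.ndarray:
    """δ¹³C (permil) for each spot."""
    return np.array([
        dimer_to_ratio(s.counts_12C12C, s.counts_13C12C).delta13C_permil
        for s in spots
    ])


@dataclass(frozen=True)
class GatedTestResult:
    test_name: str  # "t-test" | "wilcoxon"
    statistic: float
    pvalue: float
    significant: bool
    shapiro_p_a: float
    shapiro_p_b: float


def gated_test(group_a: Sequence[float], group_b: Sequence[float],
               alpha: float = 0.05) -> GatedTestResult:
    """Normality-gated two-sample test.

    Shapiro–Wilk is run on each group; if either rejects normality at
    ``alpha`` the comparison falls back to the two-sided Wilcoxon
    rank-sum (Mann–Whitney U) test, otherwise an unpaired two-tailed
    Student's t-test is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group for normality gating")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:  # constant group: Shapiro undefined, treat as non-normal
            return 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    p_a, p_b = _shapiro_p(a), _shapiro_p(b)
    if p_a < alpha or p_b < alpha:
        if np.array_equal(np.sort(a), np.sort(b)):
            # identical samples: no evidence of difference
            return GatedTestResult("wilcoxon", 0.0, 1.0, False, p_a, p_b)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
        name = "wilcoxon"
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        name = "t-test"
    return GatedTestResult(test_name=name, statistic=float(stat),
                           pvalue=float(p), significant=bool(p < alpha),
                           shapiro_p_a=p_a, shapiro_p_b=p_b)


@dataclass(frozen=True)
class EnrichmentSummary:
    """δ¹³C enrichment of a labeled spot group over its control."""

    labeled_mean: float
    labeled_median: float
    control_mean: float
    control_median: float
    mean_difference: float
    median_difference: float
    n_labeled: int
    n_control: int
    test: GatedTestResult
    labeled_outliers: np.ndarray
    control_outliers: np.ndarray


def enrichment_vs_control(labeled: Sequence[IsotopeSpot],
                          control: Sequence[IsotopeSpot],
                          alpha: float = 0.05) -> EnrichmentSummary:
    """Compare δ¹³C of a labeled spot group against unlabeled controls.

    Controls are typically PFA-fixed (killed) or unlabeled material;
    significance uses the normality-gated test.  Outliers are flagged
    per group but retained in all statistics.
    """
    if len(labeled) < 2 or len(control) < 2:
        raise ValueError("need >= 2 spots per group")
    d_lab = spot_deltas(labeled)
    d_ctl = spot_deltas(control)
    test = gated_test(d_lab, d_ctl, alpha=alpha)
    return EnrichmentSummary(
        labeled_mean=float(np.mean(d_lab)),
        labeled_median=float(np.median(d_lab)),
        control_mean=float(np.mean(d_ctl)),
        control_median=float(np.median(d_ctl)),
        mean_difference=float(np.mean(d_lab) - np.mean(d_ctl)),
        median_difference=float(np.median(d_lab) - np.median(d_ctl)),
        n_labeled=len(d_lab), n_control=len(d_ctl), test=test,
        labeled_outliers=flag_outliers(d_lab),
        control_outliers=flag_outliers(d_ctl))


def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Tukey 1.5×IQR outlier flags (quartiles by linear interpolation).

    Values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are flagged; nothing is
    ever removed.  With fewer than 4 values quartiles are unstable, so
    all points are left unflagged with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 values: outlier flags not computed",
                      stacklevel=2)
        return np.zeros(len(values), dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (values < lo) | (values > hi)
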