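"""Group statistics: pixel-wise map comparisons and scalar tests.

Pixel-wise comparisons follow the study's map statistics: per-pixel group
mean, SD, difference and two-sided p-value (Welch t-test by default,
Mann-Whitney optional), thresholded at p < 0.05 with no multiple-testing
correction; the fraction of significant pixels is reported so users can
gauge inflation.  Scalar tests run Grubbs outlier exclusion, then a
Shapiro-Wilk normality gate that selects t-test/ANOVA versus
Mann-Whitney/Kruskal-Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .projection import ProjectionMap

__all__ = [
    "GroupMapStack", "ComparisonMaps", "DispersionSummary", "ScalarTestResult",
    "pixelwise_compare", "dispersion_summary", "grubbs_outliers", "scalar_test",
    "correlate",
]

ALPHA = 0.05


@dataclass
class GroupMapStack:
    """Aligned projection maps of one group at one timepoint (one per animal)."""

    group: str
    maps: list
    timepoint: str = ""

    def __post_init__(self):
        shapes = {m.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError(f"maps in stack have differing shapes: {shapes}")

    @property
    def n_animals(self) -> int:
        return len(self.maps)

    def values(self) -> np.ndarray:
        """(n_animals, n_z, n_theta) with NaN at invalid cells."""
        return np.stack([np.where(m.valid, m.values, np.nan) for m in self.maps])

    def valid_all(self) -> np.ndarray:
        """Cells valid in every animal of the stack."""
        return np.all([m.valid for m in self.maps], axis=0)


@dataclass
class ComparisonMaps:
    """Per-pixel group comparison (a vs b).

    ``p_map`` is NaN at zero-variance or invalid pixels (an undefined
    sentinel, never 0 or 1); ``sig_mask`` is True iff p < alpha.
    """

    mean_a: np.ndarray
    mean_b: np.ndarray
    sd_a: np.ndarray
    sd_b: np.ndarray
    difference: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    valid: np.ndarray
    test: str = "unpaired_t"
    sig_fraction: float = field(default=np.nan)


@dataclass
class DispersionSummary:
    """Spatial median and quartiles of the per-pixel inter-animal SD."""

    median_sd: float
    lower_quartile_sd: float
    upper_quartile_sd: float


def pixelwise_compare(a: GroupMapStack, b: GroupMapStack,
                      test: str = "unpaired_t", alpha: float = ALPHA
                      ) -> ComparisonMaps:
    """Per-pixel mean/SD/difference/p-value between two aligned stacks.

    Pixels invalid in either group are invalid in all outputs.  The default
    test is the unpaired two-sided Welch t-test; ``test="mann_whitney"``
    selects the Mann-Whitney U test.
    """
    if a.maps[0].shape != b.maps[0].shape:
        raise ValueError("stack grid shapes differ")
    if a.n_animals < 2 or b.n_animals < 2:
        raise ValueError("each group needs at least 2 animals")
    va, vb = a.values(), b.values()
    valid = a.valid_all() & b.valid_all()

    mean_a, mean_b = va.mean(axis=0), vb.mean(axis=0)
    sd_a = va.std(axis=0, ddof=1)
    sd_b = vb.std(axis=0, ddof=1)
    diff = mean_a - mean_b

    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "unpaired_t":
            res = stats.ttest_ind(va, vb, axis=0, equal_var=False,
                                  nan_policy="propagate")
            p = np.asarray(res.pvalue, dtype=float)
        elif test == "mann_whitney":
            res = stats.mannwhitneyu(va, vb, axis=0, alternative="two-sided")
            p = np.asarray(res.pvalue, dtype=float)
        else:
            raise ValueError(f"unknown test {test!r}")

    zero_var = (sd_a == 0) & (sd_b == 0)
    p = np.where(valid & ~zero_var, p, np.nan)
    for arr in (mean_a, mean_b, sd_a, sd_b, diff):
        arr[~valid] = np.nan
    sig = np.where(np.isfinite(p), p < alpha, False)
    n_valid_p = int(np.isfinite(p).sum())
    frac = float(sig.sum() / n_valid_p) if n_valid_p else np.nan
    return ComparisonMaps(mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
                          difference=diff, p_map=p, sig_mask=sig, valid=valid,
                          test=test, sig_fraction=frac)


def dispersion_summary(stack: GroupMapStack) -> DispersionSummary:
    """Per-pixel inter-animal SD, summarized by its spatial median/quartiles."""
    if stack.n_animals < 2:
        raise ValueError("need at least 2 animals")
    v = stack.values()
    valid = stack.valid_all()
    if not valid.any():
        raise ValueError("no valid pixels")
    sd = v.std(axis=0, ddof=1)[valid]
    q25, q50, q75 = np.percentile(sd, [25, 50, 75])
    return DispersionSummary(median_sd=float(q50), lower_quartile_sd=float(q25),
                             upper_quartile_sd=float(q75))


def _grubbs_critical(n: int, alpha: float) -> float:
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_outliers(x, alpha: float = ALPHA, max_removals: int = 2):
    """Iterative two-sided Grubbs test; returns (kept, removed_indices).

    Capped at ``max_removals`` removals to protect small groups.
    """
    x = np.asarray(x, dtype=float)
    idx = np.arange(len(x))
    removed = []
    for _ in range(max_removals):
        n = len(x)
        if n < 3:
            break
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        g = dev[i] / s
        if g > _grubbs_critical(n, alpha):
            removed.append(int(idx[i]))
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            x, idx = x[keep], idx[keep]
        else:
            break
    return x, removed


@dataclass
class ScalarTestResult:
    """Outcome of a gated scalar test (audit trail included)."""

    test: str
    statistic: float
    p: float
    normal: bool
    removed_outliers: list


def scalar_test(groups, design: str = None, alpha: float = ALPHA
                ) -> ScalarTestResult:
    """Grubbs-cleaned, normality-gated comparison of 2+ groups of scalars.

    Shapiro-Wilk at alpha gates every group; if all pass, an unpaired
    (Welch) t-test or one-way ANOVA is used, otherwise Mann-Whitney U or
    Kruskal-Wallis.  Groups too small for the gate (n < 3) fall back to the
    non-parametric branch.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if design is None:
        design = "two_group" if len(groups) == 2 else "multi_group"
    if design == "two_group" and len(groups) != 2:
        raise ValueError("two_group design needs exactly 2 groups")

    cleaned, removed = [], []
    for gi, g in enumerate(groups):
        kept, rem = grubbs_outliers(g, alpha=alpha)
        cleaned.append(kept)
        removed.extend([(gi, r) for r in rem])

    gateable = all(len(g) >= 3 for g in cleaned)
    if gateable:
        normal = all(
            (g.std(ddof=1) == 0) or (stats.shapiro(g).pvalue >= alpha)
            for g in cleaned
        )
    else:
        normal = False

    if len(cleaned) == 2:
        a, b = cleaned
        if normal:
            if np.array_equal(a, b) or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0
                                        and a.mean() == b.mean()):
                return ScalarTestResult("unpaired_t", 0.0, 1.0, True, removed)
            r = stats.ttest_ind(a, b, equal_var=False)
            return ScalarTestResult("unpaired_t", float(r.statistic),
                                    float(r.pvalue), True, removed)
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ScalarTestResult("mann_whitney", float(r.statistic),
                                float(r.pvalue), False, removed)
    if normal:
        r = stats.f_oneway(*cleaned)
        return ScalarTestResult("anova", float(r.statistic), float(r.pvalue),
                                True, removed)
    r = stats.kruskal(*cleaned)
    return ScalarTestResult("kruskal_wallis", float(r.statistic),
                            float(r.pvalue), False, removed)


def correlate(x, y):
    """Pearson r and two-sided p with listwise deletion of missing pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)
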