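"""Test-retest consistency statistics.

Intra- and inter-cast agreement is summarised by the coefficient of
variation (CoV), the intraclass correlation coefficient ICC(2,1), a
Shapiro–Wilk-gated paired comparison (paired t when the differences look
normal, Wilcoxon signed-rank otherwise), Bland–Altman bias and 1.96·SD
limits of agreement, and a clinical-significance procedure that compares
intra-cast volume and shape differences against the volume of one prosthetic
sock (7.94 % of limb volume by water displacement).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger("limbcast")

#: One-sock clinical-significance threshold, percent of limb volume.
DEFAULT_SOCK_PCT = 7.94


# ---------------------------------------------------------------------------
# Coefficient of variation
# ---------------------------------------------------------------------------

def cov_pct(values, ddof: int = 1) -> float:
    """100 x sample SD / mean; warns when the mean is near zero (|mean| < SD/10)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cov_pct needs at least two values")
    m = v.mean()
    sd = v.std(ddof=ddof)
    if m == 0:
        raise ZeroDivisionError("cov_pct undefined for zero mean")
    if abs(m) < sd / 10.0:
        warnings.warn("CoV is unstable: |mean| < SD/10")
    return 100.0 * sd / m


def cov_pct_from_stats(mean: float, sd: float) -> float:
    """CoV from summary statistics (as printed in study tables)."""
    if mean == 0:
        raise ZeroDivisionError("cov undefined for zero mean")
    return 100.0 * sd / mean


def series_with_stats(mean: float, sd: float, n: int = 12,
                      seed: int = 0) -> np.ndarray:
    """A length-n series whose sample mean and SD (ddof=1) equal exactly the
    given values — useful for reconstructing printed table rows."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def icc(ratings: np.ndarray, form: str = "icc2") -> float:
    """ICC from the two-way ANOVA decomposition of a subjects x repetitions
    matrix.

    The default (and study-standard test-retest) form is ICC(2,1): two-way
    random effects, absolute agreement, single measure.  ``form="icc3"``
    gives the consistency variant ICC(3,1).  Returns NaN when there is no
    variance at all to apportion.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n>=3 subjects) x (k>=2 repetitions) matrix")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Paired comparison with a normality gate
# ---------------------------------------------------------------------------

@dataclass
class PairedResult:
    normality_p: float
    test_used: str  # "t" | "wilcoxon"
    statistic: float
    p_value: float
    mean_diff: float
    sd_diff: float
    degenerate: bool = False


def paired_compare(x, y, alpha: float = 0.05) -> PairedResult:
    """Shapiro–Wilk on the paired differences, then paired t (if normality
    not rejected at ``alpha``) or Wilcoxon signed-rank.

    The gate is applied to the differences, not the raw arms, because the
    differences are what the paired tests assess.  All-zero differences are
    reported as a degenerate comparison with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired_compare needs matched series of length >= 3")
    d = x - y
    if np.allclose(d, 0.0):
        return PairedResult(1.0, "t", 0.0, 1.0, 0.0, 0.0, degenerate=True)
    if np.ptp(d) == 0:  # constant non-zero offset: SW undefined, t is exact
        sw_p = 1.0
    else:
        sw_p = float(sps.shapiro(d).pvalue)
    if sw_p >= alpha:
        stat, p = sps.ttest_rel(x, y)
        used = "t"
    else:
        stat, p = sps.wilcoxon(x, y)
        used = "wilcoxon"
    return PairedResult(sw_p, used, float(stat), float(p),
                        float(d.mean()), float(d.std(ddof=1)))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(x, y) -> dict:
    """Bias and 1.96·SD limits of agreement plus per-subject plot points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("bland_altman needs matched series of length >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd,
            "mean": (x + y) / 2.0, "diff": d}


def bland_altman_plot(x, y, ax=None, title: str = ""):
    """Optional matplotlib rendering of the Bland-Altman summary."""
    import matplotlib.pyplot as plt

    ba = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba["mean"], ba["diff"], s=18)
    for yv, stl in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(yv, linestyle=stl, color="k", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# One-sock clinical significance
# ---------------------------------------------------------------------------

def sock_volume_pct(with_sock: float, without_sock: float) -> float:
    """Percentage volume of one sock: 100 (V_with − V_without) / V_without."""
    if without_sock <= 0:
        raise ValueError("baseline (without-sock) volume must be positive")
    if with_sock < without_sock:
        raise ValueError("with-sock volume must be >= without-sock volume")
    return 100.0 * (with_sock - without_sock) / without_sock


@dataclass
class ClinicalTest:
    mean_diff: float
    sd_diff: float
    p_value: float
    verdict: str  # "below_sock" | "at_or_above_sock"
    test: PairedResult | None = None


def clinical_significance(rep1, rep2, sock_pct: float = DEFAULT_SOCK_PCT,
                          shape_diffs=None, mean_volumes=None,
                          alpha: float = 0.05) -> dict:
    """One-sock clinical-significance tests.

    ``volume_test``: one sock's worth of volume is removed from the first
    repetition ((1 − sock_pct/100) x rep1) and the result compared to the
    second repetition with a paired test.  A significant difference means the
    intra-cast volume change is smaller than one sock (verdict
    ``below_sock``) — the inference direction is unconventional but kept, and
    exposed as an explicit verdict label.

    ``shape_test`` (when ``shape_diffs`` and ``mean_volumes`` are given):
    per-subject intra-cast shape difference compared to sock_pct % of the
    subject's four-scan mean volume.  Shape differences significantly below
    the sock volume give ``below_sock``; otherwise ``at_or_above_sock``.
    """
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if rep1.shape != rep2.shape:
        raise ValueError("mismatched subjects between repetitions")
    scaled = (1.0 - sock_pct / 100.0) * rep1
    vt = paired_compare(scaled, rep2, alpha=alpha)
    v_verdict = "below_sock" if (vt.p_value < alpha and not vt.degenerate) else "at_or_above_sock"
    out = {"volume_test": ClinicalTest(vt.mean_diff, vt.sd_diff, vt.p_value,
                                       v_verdict, vt)}
    if shape_diffs is not None:
        if mean_volumes is None:
            raise ValueError("shape_test needs mean_volumes alongside shape_diffs")
        sd_arr = np.asarray(shape_diffs, dtype=float)
        mv = np.asarray(mean_volumes, dtype=float)
        if sd_arr.shape != mv.shape:
            raise ValueError("mismatched subjects between shape_diffs and mean_volumes")
        thresh = sock_pct / 100.0 * mv
        st = paired_compare(sd_arr, thresh, alpha=alpha)
        s_verdict = ("below_sock"
                     if (st.p_value < alpha and st.mean_diff < 0 and not st.degenerate)
                     else "at_or_above_sock")
        out["shape_test"] = ClinicalTest(st.mean_diff, st.sd_diff, st.p_value,
                                         s_verdict, st)
    return out


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Per-metric/region consistency summaries of one study run."""

    rows: list = field(default_factory=list)

    def add(self, metric: str, region: str, comparison: str, **stats) -> None:
        self.rows.append({"metric": metric, "region": region,
                          "comparison": comparison, **stats})

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)
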