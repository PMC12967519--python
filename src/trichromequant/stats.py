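"""Normality-gated two-group comparisons, regression and cohort summaries.

Comparison framework: each feature is tested for normality in both stain
groups with Shapiro-Wilk (normal iff p > 0.05).  If both groups pass, an
independent-samples pooled-variance t-test compares them; if at least one
fails, the two-sided Mann-Whitney U test is used instead.  Groups are
summarised as mean +/- SD when normal, median [IQR] otherwise.  No
multiple-testing correction is applied across features.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSample,
    DegenerateVariance,
    DegenerateX,
    SampleTooSmall,
    TooFewImages,
)

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class FeatureSample:
    """One feature's observations for one group (stain)."""

    feature_name: str
    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64).ravel()
        )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation, via scipy).

    Valid for 3 <= n <= 5000; a constant sample has no defined W.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 3:
        raise SampleTooSmall(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk approximation unreliable for n > 5000")
    if np.ptp(x) == 0:
        raise DegenerateSample("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def students_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise SampleTooSmall("t-test needs n >= 2 in each group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            raise DegenerateVariance("both groups constant and equal")
        return float("inf") if a[0] > b[0] else float("-inf"), 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Uses midranks so ties are handled; the two-sided p is the probability,
    under exchangeability, of a U at least as extreme (in either tail) as
    observed.
    """
    n1, n2 = a.size, b.size
    z = np.concatenate([a, b])
    ranks = sps.rankdata(z)  # midranks
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    m = n1 * n2
    u_lo = min(u_obs, m - u_obs)
    u_hi = m - u_lo
    eps = 1e-9
    n_lo = n_hi = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - offset)
        total += 1
        if u <= u_lo + eps:
            n_lo += 1
        if u >= u_hi - eps:
            n_hi += 1
    return u_obs, min(1.0, (n_lo + n_hi) / total)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact by full enumeration when the combined sample size is at most 12;
    otherwise the tie- and continuity-corrected normal approximation.  The
    statistic reported is U of the first sample.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size < 1 or b.size < 1:
        raise SampleTooSmall("Mann-Whitney needs n >= 1 in each group")
    if np.ptp(np.concatenate([a, b])) == 0:
        # every pairwise comparison ties: U is its null mean, no evidence
        return a.size * b.size / 2.0, 1.0
    if a.size + b.size <= 12:
        return _mann_whitney_exact(a, b)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive summary: mean +/- SD if normal, median [IQR]."""

    label: str
    n: int
    normal: bool
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    @property
    def text(self) -> str:
        if self.normal:
            return f"{self.mean:.3g} ± {self.sd:.3g}"
        return f"{self.median:.3g} [{self.q1:.3g}–{self.q3:.3g}]"


def _summarize_group(label: str, x: np.ndarray, normal: bool) -> GroupSummary:
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation between ranks
    return GroupSummary(
        label=label,
        n=int(x.size),
        normal=normal,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        q1=float(q1),
        q3=float(q3),
    )


@dataclass(frozen=True)
class ComparisonResult:
    feature_name: str
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    group_summaries: tuple[GroupSummary, GroupSummary]
    significant: bool
    alpha: float


def _is_normal(x: np.ndarray) -> bool:
    """Normality gate: Shapiro-Wilk p strictly greater than 0.05."""
    try:
        _, p = shapiro_wilk(x)
    except DegenerateSample:
        return False
    return p > 0.05


def compare_feature(
    a: FeatureSample,
    b: FeatureSample,
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
) -> ComparisonResult:
    """Normality-gated two-group comparison of one feature.

    Both groups normal (Shapiro-Wilk p > 0.05 each) -> pooled t-test; at
    least one non-normal (a boundary p of exactly 0.05 counts as
    non-normal) -> Mann-Whitney U.
    """
    xa, xb = a.values, b.values
    na, nb = _is_normal(xa), _is_normal(xb)
    if na and nb:
        stat, p = students_t(xa, xb, equal_var=equal_var)
        test = "t_test"
    else:
        stat, p = mann_whitney_u(xa, xb)
        test = "mann_whitney"
    return ComparisonResult(
        feature_name=a.feature_name,
        test_used=test,
        statistic=stat,
        p_value=p,
        group_summaries=(
            _summarize_group(a.group_label, xa, na),
            _summarize_group(b.group_label, xb, nb),
        ),
        significant=bool(p < alpha),
        alpha=alpha,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with R^2 and the slope's p-value."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateX("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateX("regressor has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
    )


# --- cohort summary table ---------------------------------------------------

#: (features-CSV column, human-readable row label) in report order.
TABLE_FEATURES = [
    ("thresh_area_mm2", "Thresholded area (mm²)"),
    ("thresh_to_mask_pct", "Thresholded to mask area ratio (%)"),
    ("mean", "Mean intensity"),
    ("median", "Median intensity"),
    ("min", "Minimum intensity"),
    ("max", "Maximum intensity"),
    ("skewness", "Skewness"),
    ("kurtosis", "Kurtosis"),
]


def summarize_table(
    features: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Cohort summary: one row per feature, per-stain summaries, test, p.

    ``features`` is the tidy per-image-per-stain table (see
    ``features.FEATURE_COLUMNS``); the two stains present are compared
    feature by feature with the normality-gated procedure.
    """
    stains = sorted(features["stain"].unique())
    if len(stains) != 2:
        raise ValueError(f"expected exactly two stains, got {stains}")
    if "blue_green" in stains and stains[0] != "blue_green":
        stains = stains[::-1]  # conventional order: collagen first
    g1 = features[features["stain"] == stains[0]]
    g2 = features[features["stain"] == stains[1]]
    n_images = features["image_id"].nunique()
    if n_images < 3:
        raise TooFewImages(f"cohort comparison needs >= 3 images, got {n_images}")

    rows = []
    for col, label in TABLE_FEATURES:
        xa = g1[col].to_numpy(dtype=float)
        xb = g2[col].to_numpy(dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if xa.size < 3 or xb.size < 3:
            rows.append({
                "feature": label, f"{stains[0]}": "n/a", f"{stains[1]}": "n/a",
                "test": "none", "statistic": float("nan"),
                "p_value": float("nan"), "significant": False,
            })
            continue
        res = compare_feature(
            FeatureSample(label, stains[0], xa),
            FeatureSample(label, stains[1], xb),
            alpha=alpha,
        )
        sa, sb = res.group_summaries
        rows.append({
            "feature": label,
            f"{stains[0]}": sa.text,
            f"{stains[1]}": sb.text,
            "test": res.test_used,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> str:
    """Markdown rendering of a `summarize_table` result."""
    cols = list(table.columns)
    lines = ["# Stain comparison", ""]
    header = "| " + " | ".join(cols) + " |"
    sep = "|" + "|".join(["---"] * len(cols)) + "|"
    lines += [header, sep]
    for _, row in table.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append("nan" if not math.isfinite(v) else f"{v:.4g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    lines += [
        "",
        "Data are mean ± SD for normally distributed features "
        "(Shapiro–Wilk p > 0.05 in that group) or median [IQR] otherwise; "
        "p-values from a pooled-variance independent t-test when both groups "
        "are normal, else a two-sided Mann–Whitney U test. "
        f"Significance at α = {alpha:g}; no multiple-testing correction "
        "is applied across features.",
    ]
    return "\n".join(lines) + "\n"
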