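"""Statistical machinery: Scheirer–Ray–Hare test, BH correction, and a
uniform wrapper over the standard nonparametric battery.

The Scheirer–Ray–Hare test is a nonparametric two-way ANOVA: all
observations are ranked jointly (midranks for ties), two-way ANOVA sums
of squares are computed on the ranks, and each effect's statistic
H = SS_effect / MS_total is referred to a chi-square distribution with
the effect's degrees of freedom.  Using MS_total = SS_total/(N−1)
computed from midranks applies the standard tie correction
automatically (it equals the untied rank variance N(N+1)/12 divided by
the usual tie-correction factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "scheirer_ray_hare",
    "bh_correct",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "ks_two_sample",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class TestResult:
    """Uniform record of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    sided: str  # "one" or "two"
    df: float | None = None
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def scheirer_ray_hare(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
) -> dict[str, TestResult]:
    """Scheirer–Ray–Hare nonparametric two-way ANOVA.

    Returns results keyed ``"A"``, ``"B"``, ``"interaction"``.  Requires at
    least two levels per factor and at least one observation per cell.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (values.shape == factor_a.shape == factor_b.shape) or values.ndim != 1:
        raise ValueError("values and factors must be equal-length vectors")
    levels_a = np.unique(factor_a)
    levels_b = np.unique(factor_b)
    if levels_a.size < 2 or levels_b.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((factor_a == la) & (factor_b == lb)):
                raise ValueError(f"empty cell: A={la!r}, B={lb!r}")

    n = values.size
    ranks = sps.rankdata(values)  # midranks for ties
    grand = ranks.mean()
    ss_total = float(((ranks - grand) ** 2).sum())
    if ss_total == 0:  # all values tied: no information, H = 0
        zero = {
            "A": (levels_a.size - 1),
            "B": (levels_b.size - 1),
            "interaction": (levels_a.size - 1) * (levels_b.size - 1),
        }
        return {
            k: TestResult(0.0, 1.0, "scheirer-ray-hare", "two", df=df)
            for k, df in zero.items()
        }
    ms_total = ss_total / (n - 1)

    def group_ss(keys: np.ndarray) -> float:
        ss = 0.0
        for k in np.unique(keys):
            sel = keys == k
            ss += sel.sum() * (ranks[sel].mean() - grand) ** 2
        return ss

    ss_a = group_ss(factor_a)
    ss_b = group_ss(factor_b)
    cells = np.char.add(
        np.char.add(factor_a.astype(str), "\x1f"), factor_b.astype(str)
    )
    ss_cells = group_ss(cells)
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)

    out: dict[str, TestResult] = {}
    for key, ss, df in (
        ("A", ss_a, levels_a.size - 1),
        ("B", ss_b, levels_b.size - 1),
        ("interaction", ss_ab, (levels_a.size - 1) * (levels_b.size - 1)),
    ):
        h = ss / ms_total
        p = float(sps.chi2.sf(h, df))
        out[key] = TestResult(float(h), p, "scheirer-ray-hare", "two", df=df)
    return out


def bh_correct(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR correction.

    Returns (adjusted p-values, rejection flags at level ``alpha``).
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.reshape(-1)
    reject, p_adj, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    return p_adj.reshape(p.shape), reject.reshape(p.shape)


def _rank_biserial_from_u(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation from a Mann–Whitney U statistic."""
    return 2.0 * u / (n1 * n2) - 1.0


def mann_whitney(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test for two independent samples."""
    res = sps.mannwhitneyu(x, y, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mann-whitney-u",
        sided="two" if alternative == "two-sided" else "one",
        effect_size=_rank_biserial_from_u(float(res.statistic), len(x), len(y)),
    )


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples (or one sample vs 0).

    The direction of a one-sided test must be stated explicitly via
    ``alternative`` ("greater"/"less"); there is no auto-detection.
    """
    d = np.asarray(x, dtype=float) - (0 if y is None else np.asarray(y, dtype=float))
    res = sps.wilcoxon(d, alternative=alternative)
    n = np.count_nonzero(d)
    # matched-pairs rank-biserial: W+ and W- share n(n+1)/2
    total = n * (n + 1) / 2.0
    effect = float((2 * res.statistic - total) / total) if total else 0.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon-signed-rank",
        sided="two" if alternative == "two-sided" else "one",
        effect_size=effect,
    )


def ks_two_sample(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test."""
    res = sps.ks_2samp(x, y, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="ks-two-sample",
        sided="two" if alternative == "two-sided" else "one",
        effect_size=float(res.statistic),
    )


def kruskal_wallis(*groups: np.ndarray) -> TestResult:
    """Kruskal–Wallis H test for two or more independent groups."""
    res = sps.kruskal(*groups)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kruskal-wallis",
        sided="two",
        df=len(groups) - 1,
    )
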