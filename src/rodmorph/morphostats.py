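"""Statistical comparison of two cell-dimension populations.

Cell length and width distributions in micrograph data are typically
right-skewed (stressed cells filament), so the comparison protocol is:
summarise each sample (mean, median, sample SD), gate with Shapiro–Wilk
and D'Agostino–Pearson normality tests, compare conditions with the
two-sided Mann–Whitney U test, and report the percent change of medians
and the SD ratio.  Agreement between two measurement routes (for example,
automated versus manual) is quantified as RMSE over cells paired by id.

Percent change of medians is reported as a floor'd integer percent — the
convention that reproduces the printed 41% for medians 53 -> 75 (41.5%
exact) and 39% for 51 -> 71 (39.2% exact).  No multiple-testing correction
is applied; p-values are reported per dimension as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "DimensionSummary",
    "NormalityResult",
    "MannWhitneyResult",
    "AgreementResult",
    "ComparisonReport",
    "summarize",
    "percent_increase_of_medians",
    "mann_whitney_u",
    "normality_gate",
    "agreement",
    "compare_conditions",
    "histogram_export",
]


@dataclass(frozen=True)
class DimensionSummary:
    n: int
    mean: float
    median: float
    sd: float  # sample SD, n-1 denominator


@dataclass(frozen=True)
class NormalityResult:
    shapiro_wilk_p: Optional[float]
    dagostino_pearson_p: Optional[float]
    verdict: str  # normal | non_normal | not_applicable


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # exact | asymptotic
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementResult:
    n_pairs: int
    rmse_length: float
    rmse_width: float
    unmatched_ids: tuple = ()


@dataclass(frozen=True)
class DimensionComparison:
    summary_control: DimensionSummary
    summary_treated: DimensionSummary
    normality_control: NormalityResult
    normality_treated: NormalityResult
    test: MannWhitneyResult
    median_increase_pct: int
    sd_ratio: float


@dataclass(frozen=True)
class ComparisonReport:
    length: DimensionComparison
    width: Optional[DimensionComparison] = None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(values) -> DimensionSummary:
    """Mean, median and sample SD of a dimension sample (n >= 2)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    return DimensionSummary(n=int(x.size), mean=float(x.mean()),
                            median=float(np.median(x)),
                            sd=float(x.std(ddof=1)))


def percent_increase_of_medians(control_median: float,
                                treated_median: float) -> int:
    """Integer percent change of medians, floored.

    Floor (not round-half-up) is the convention: 53 -> 75 gives
    floor(41.5) = 41 and 51 -> 71 gives floor(39.2) = 39.
    """
    if control_median <= 0:
        raise ValueError("control median must be positive")
    return math.floor(100.0 * (treated_median - control_median) / control_median)


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    U comes from rank sums with midranks for ties.  The p-value uses exact
    enumeration when n_x * n_y <= 400, otherwise the normal approximation
    with tie and continuity corrections.  Fully degenerate data (all values
    identical across both samples) is flagged and reported with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(np.concatenate([x, y])) == 0:
        return MannWhitneyResult(u=x.size * y.size / 2.0, p=1.0,
                                 method="degenerate", degenerate=True)
    exact = x.size * y.size <= 400 and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             method=method)


def _has_ties(x, y) -> bool:
    allv = np.concatenate([x, y])
    return np.unique(allv).size < allv.size


def normality_gate(x, alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk + D'Agostino–Pearson normality check.

    The verdict is ``non_normal`` if either test rejects at ``alpha``.  It
    only selects which test is *reported* as decisive downstream; the
    Mann–Whitney comparison is always computed regardless.  D'Agostino–
    Pearson needs n >= 20 and Shapiro–Wilk n >= 3 (and non-constant data);
    a test that does not apply is reported as None.
    """
    x = np.asarray(x, dtype=float)
    sw = dp = None
    if x.size >= 3 and np.ptp(x) > 0:
        sw = float(sps.shapiro(x).pvalue)
    if x.size >= 20 and np.ptp(x) > 0:
        dp = float(sps.normaltest(x).pvalue)
    if sw is None and dp is None:
        return NormalityResult(None, None, "not_applicable")
    ps = [p for p in (sw, dp) if p is not None]
    verdict = "non_normal" if any(p < alpha for p in ps) else "normal"
    return NormalityResult(sw, dp, verdict)


def agreement(auto: dict, reference: dict) -> AgreementResult:
    """RMSE between two measurement tables paired by cell id.

    ``auto`` and ``reference`` map cell_id -> (length_px, width_px).
    Unmatched ids are logged, not fatal; zero matched pairs is an error.
    """
    ids = sorted(set(auto) & set(reference))
    unmatched = tuple(sorted((set(auto) ^ set(reference))))
    if not ids:
        raise ValueError("no matched pairs between tables")
    dl = np.array([auto[i][0] - reference[i][0] for i in ids])
    dw = np.array([auto[i][1] - reference[i][1] for i in ids])
    return AgreementResult(n_pairs=len(ids),
                           rmse_length=float(np.sqrt(np.mean(dl ** 2))),
                           rmse_width=float(np.sqrt(np.mean(dw ** 2))),
                           unmatched_ids=unmatched)


def _compare_dimension(control, treated) -> DimensionComparison:
    sc, st = summarize(control), summarize(treated)
    return DimensionComparison(
        summary_control=sc,
        summary_treated=st,
        normality_control=normality_gate(control),
        normality_treated=normality_gate(treated),
        test=mann_whitney_u(control, treated),
        median_increase_pct=percent_increase_of_medians(sc.median, st.median),
        sd_ratio=float(st.sd / sc.sd) if sc.sd > 0 else float("inf"),
    )


def compare_conditions(meas_control, meas_treated) -> ComparisonReport:
    """Full two-condition report for length (and width when present).

    Inputs are tables (pandas DataFrame or dict of columns) with a
    ``length_px`` column and optionally ``width_px``.
    """
    import pandas as pd

    a = pd.DataFrame(meas_control)
    b = pd.DataFrame(meas_treated)
    if a.empty or b.empty:
        raise ValueError("both measurement tables must be non-empty")
    if "length_px" not in a.columns or "length_px" not in b.columns:
        raise ValueError("missing required column 'length_px'")
    length = _compare_dimension(a["length_px"].to_numpy(),
                                b["length_px"].to_numpy())
    width = None
    if "width_px" in a.columns and "width_px" in b.columns:
        width = _compare_dimension(a["width_px"].to_numpy(),
                                   b["width_px"].to_numpy())
    return ComparisonReport(length=length, width=width)


def histogram_export(control, treated, n_bins: int = 30):
    """Shared-bin histogram counts for plotting the two conditions.

    Returns a DataFrame with columns bin_left, bin_right, count_control,
    count_treated; bin edges span the pooled range so the two histograms
    are directly comparable.
    """
    import pandas as pd

    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    pooled = np.concatenate([c, t])
    edges = np.histogram_bin_edges(pooled, bins=n_bins)
    hc, _ = np.histogram(c, bins=edges)
    ht, _ = np.histogram(t, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count_control": hc, "count_treated": ht})
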