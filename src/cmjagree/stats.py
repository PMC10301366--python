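"""Method-agreement and group-difference statistics for jump-height tables.

Implements the battery used in measurement-agreement studies of jump
height: single-measure absolute-agreement intraclass correlation (the
two-way model, McGraw & Wong's ICC(A,1), with the F-based 95% CI that
SPSS reports), a between-tool coefficient of variation, the standard
error of measurement SD_diff / sqrt(2), Bland–Altman bias and 95% limits
of agreement, Friedman (or Kruskal–Wallis) omnibus tests with
Bonferroni-corrected Wilcoxon post hocs, and Mann–Whitney U with the
rank-biserial-style effect size r = |Z| / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "GroupTestResult",
    "icc_absolute_single",
    "between_tool_cv",
    "sem_between_tools",
    "bland_altman",
    "loa_from_bias_sd",
    "friedman_with_posthoc",
    "kruskal_wallis",
    "mann_whitney_with_r",
    "interpret_icc",
    "interpret_r",
    "agreement_pair",
    "agreement_table",
    "METHOD_COLUMNS",
]

#: jump-height columns of a JumpRecordTable, in report order
METHOD_COLUMNS = ("jh_tia_cm", "jh_tov_cm", "jh_mj_cm")


@dataclass(frozen=True)
class AgreementResult:
    """Agreement statistics for one method pair (units: cm unless noted)."""

    method_pair: tuple[str, str]
    icc: float
    icc_ci: tuple[float, float]
    icc_p: float
    cv_pct: float
    sem_cm: float
    bias_cm: float
    bias_sd_cm: float
    loa: tuple[float, float]
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    """A rank test with its standard-normal deviate and effect size."""

    statistic: float
    p_value: float
    z: float
    effect_r: float
    interpretation: str


# --------------------------------------------------------------------------
# ICC


def icc_absolute_single(data: np.ndarray) -> tuple[float, float, float, float]:
    """Single-measure absolute-agreement ICC from an n-subjects x k-methods matrix.

    Two-way mean squares (rows MSR, columns MSC, error MSE) give

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the 95% confidence interval and the p-value for ICC = 0 from the
    standard F-based procedure (Satterthwaite degrees of freedom for the
    column/error mixture).  Rows with missing cells must be dropped first.

    Returns ``(icc, ci_low, ci_high, p)``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x methods matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 methods")
    if np.isnan(x).any():
        raise ValueError("missing cells; drop incomplete rows before calling")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # F test of ICC = 0 (between-subjects vs residual)
    if mse == 0:
        p = 0.0
        ci = (icc, 1.0) if icc < 1 else (1.0, 1.0)
        return float(icc), ci[0], ci[1], p
    f_obs = msr / mse
    p = float(sps.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))

    # McGraw & Wong CI for ICC(A,1)
    alpha = 0.05
    r = icc
    if r >= 1.0:
        return float(icc), float(icc), 1.0, p
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), float(lower), float(upper), p


def interpret_icc(icc: float) -> str:
    """Qualitative agreement band: poor / moderate / good / excellent.

    Bands: poor below 0.5, moderate below 0.75, good up to and including
    0.9, excellent above 0.9 (the boundary 0.9 itself is classed good).
    """
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


# --------------------------------------------------------------------------
# CV / SEM / Bland-Altman


def _pair_arrays(table: pd.DataFrame, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    a, b = pair
    sub = table[[a, b]].dropna()
    return sub[a].to_numpy(dtype=float), sub[b].to_numpy(dtype=float)


def between_tool_cv(table: pd.DataFrame, pair: tuple[str, str]) -> float:
    """Mean between-tool coefficient of variation (%), over jumps.

    Per jump, the two tools' values (a, b) give SD = |a - b| / sqrt(2)
    and mean (a + b) / 2; the jump's CV is their ratio x 100 and the
    reported CV is the mean over jumps.  Jumps whose pair mean is zero
    are excluded with a warning.
    """
    a, b = _pair_arrays(table, pair)
    mean = (a + b) / 2.0
    ok = mean != 0
    if not ok.all():
        warn(f"{(~ok).sum()} jump(s) with zero pair mean excluded from CV",
             stacklevel=2)
    if not ok.any():
        raise ValueError("no jumps with non-zero pair mean")
    sd = np.abs(a - b) / math.sqrt(2.0)
    return float(np.mean(sd[ok] / mean[ok]) * 100.0)


def sem_between_tools(
    table: pd.DataFrame,
    pair: tuple[str, str],
    mode: str = "pooled",
) -> float:
    """Standard error of measurement between two tools: SD_diff / sqrt(2).

    ``pooled`` (default) takes the SD of all between-tool differences;
    ``per_participant_mean`` computes SD_diff / sqrt(2) within each
    participant's trials and averages the per-participant values (needs
    at least two trials per participant).
    """
    if mode == "pooled":
        a, b = _pair_arrays(table, pair)
        if a.size < 2:
            raise ValueError("need at least 2 paired rows for the pooled SEM")
        return float(np.std(a - b, ddof=1) / math.sqrt(2.0))
    if mode == "per_participant_mean":
        diffs = table[pair[0]] - table[pair[1]]
        per = diffs.groupby(table["participant_id"]).agg(["std", "count"])
        usable = per[per["count"] >= 2]["std"].dropna()
        if usable.empty:
            raise ValueError(
                "per_participant_mean SEM needs >= 2 trials for some participant"
            )
        return float((usable / math.sqrt(2.0)).mean())
    raise ValueError(f"unknown SEM mode {mode!r}")


def bland_altman(
    table: pd.DataFrame, pair: tuple[str, str]
) -> tuple[float, float, float, float]:
    """Bland–Altman bias and 95% limits of agreement for a method pair.

    Differences are ``pair[0] - pair[1]`` per jump; returns
    ``(bias, sd, loa_low, loa_high)`` with LoA = bias +- 1.96 sd (sample SD).
    """
    a, b = _pair_arrays(table, pair)
    if a.size < 2:
        raise ValueError("need at least 2 paired rows")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = loa_from_bias_sd(bias, sd)
    return bias, sd, lo, hi


def loa_from_bias_sd(bias: float, sd: float) -> tuple[float, float]:
    """95% limits of agreement from a (bias, SD-of-differences) summary."""
    half = 1.96 * sd
    return bias - half, bias + half


def bland_altman_points(
    table: pd.DataFrame, pair: tuple[str, str]
) -> pd.DataFrame:
    """Per-jump (mean, difference) points for a Bland–Altman plot."""
    a, b = _pair_arrays(table, pair)
    return pd.DataFrame({"mean_cm": (a + b) / 2.0, "diff_cm": a - b})


# --------------------------------------------------------------------------
# Group tests


def interpret_r(r: float) -> str:
    """Effect-size band for r: trivial / small (>0.1) / medium (>0.3) / large (>0.5)."""
    r = abs(r)
    if r > 1:
        raise ValueError("|r| cannot exceed 1")
    if r > 0.5:
        return "large"
    if r > 0.3:
        return "medium"
    if r > 0.1:
        return "small"
    return "trivial"


def _wilcoxon_group_result(a: np.ndarray, b: np.ndarray) -> GroupTestResult:
    d = a - b
    if np.all(d == 0):
        return GroupTestResult(0.0, 1.0, 0.0, 0.0, "trivial")
    res = sps.wilcoxon(a, b, method="approx")
    z = float(res.zstatistic)
    r = abs(z) / math.sqrt(a.size)
    return GroupTestResult(float(res.statistic), float(res.pvalue), z, r,
                           interpret_r(r))


def friedman_with_posthoc(
    table: pd.DataFrame,
    methods: tuple[str, ...] = METHOD_COLUMNS,
    alpha: float = 0.05,
    omnibus: str = "friedman",
) -> tuple[GroupTestResult, dict[tuple[str, str], GroupTestResult], int]:
    """Omnibus test across methods with Bonferroni-corrected pairwise post hocs.

    Rows with missing cells are dropped (their count is returned).  The
    omnibus is Friedman's chi-square over within-row ranks by default;
    ``omnibus='kruskal'`` swaps in the unpaired Kruskal–Wallis test.  When
    the omnibus is significant at ``alpha``, each method pair is compared
    with a Wilcoxon signed-rank test and its p-value multiplied by the
    number of comparisons (capped at 1); the effect size r = |Z| / sqrt(n)
    uses the number of pairs.

    Returns ``(omnibus_result, pairwise, n_dropped)``; ``pairwise`` is
    empty when the omnibus is not significant.
    """
    cols = table[list(methods)]
    complete = cols.dropna()
    n_dropped = len(cols) - len(complete)
    if len(complete) < 5:
        raise ValueError("need at least 5 complete rows")
    arrays = [complete[m].to_numpy(dtype=float) for m in methods]

    if omnibus == "friedman":
        if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
            omni = GroupTestResult(0.0, 1.0, 0.0, 0.0, "trivial")
        else:
            stat, p = sps.friedmanchisquare(*arrays)
            omni = GroupTestResult(float(stat), float(p), math.nan, math.nan, "")
    elif omnibus == "kruskal":
        if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
            omni = GroupTestResult(0.0, 1.0, 0.0, 0.0, "trivial")
        else:
            stat, p = sps.kruskal(*arrays)
            omni = GroupTestResult(float(stat), float(p), math.nan, math.nan, "")
    else:
        raise ValueError(f"unknown omnibus {omnibus!r}")

    pairwise: dict[tuple[str, str], GroupTestResult] = {}
    if omni.p_value < alpha:
        pairs = [(methods[i], methods[j])
                 for i in range(len(methods)) for j in range(i + 1, len(methods))]
        m = len(pairs)
        for pa, pb in pairs:
            res = _wilcoxon_group_result(
                complete[pa].to_numpy(dtype=float),
                complete[pb].to_numpy(dtype=float),
            )
            pairwise[(pa, pb)] = GroupTestResult(
                res.statistic, min(1.0, res.p_value * m), res.z,
                res.effect_r, res.interpretation,
            )
    return omni, pairwise, n_dropped


def kruskal_wallis(
    table: pd.DataFrame, methods: tuple[str, ...] = METHOD_COLUMNS
) -> GroupTestResult:
    """Kruskal–Wallis H across method columns (unpaired alternative omnibus)."""
    omni, _, _ = friedman_with_posthoc(table, methods, alpha=-1.0,
                                       omnibus="kruskal")
    return omni


def mann_whitney_with_r(group_a: np.ndarray, group_b: np.ndarray) -> GroupTestResult:
    """Mann–Whitney U with tie-corrected normal Z and effect size r.

    ``r = |Z| / sqrt(n_a + n_b)``; Z is computed from the U statistic
    without continuity correction, while the reported p-value is scipy's
    (exact where available, else corrected-asymptotic).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var == 0 else (u - mu) / math.sqrt(var)
    r = abs(z) / math.sqrt(n)
    return GroupTestResult(u, float(res.pvalue), float(z), r, interpret_r(r))


# --------------------------------------------------------------------------
# Table-level drivers


def agreement_pair(
    table: pd.DataFrame,
    pair: tuple[str, str],
    sem_mode: str = "pooled",
) -> AgreementResult:
    """All agreement statistics for one method pair of a jump-record table."""
    a, b = _pair_arrays(table, pair)
    icc, lo, hi, p = icc_absolute_single(np.column_stack([a, b]))
    bias, sd, loa_lo, loa_hi = bland_altman(table, pair)
    return AgreementResult(
        method_pair=pair,
        icc=icc,
        icc_ci=(lo, hi),
        icc_p=p,
        cv_pct=between_tool_cv(table, pair),
        sem_cm=sem_between_tools(table, pair, mode=sem_mode),
        bias_cm=bias,
        bias_sd_cm=sd,
        loa=(loa_lo, loa_hi),
        n=int(a.size),
    )


def agreement_table(
    table: pd.DataFrame,
    methods: tuple[str, ...] = METHOD_COLUMNS,
    stratify_by_sex: bool = True,
    sem_mode: str = "pooled",
) -> pd.DataFrame:
    """Agreement statistics for every method pair, optionally by sex stratum.

    One row per comparison x stratum (all / M / F), shaped like the summary
    tables of method-comparison reports.
    """
    strata: list[tuple[str, pd.DataFrame]] = [("all", table)]
    if stratify_by_sex and "sex" in table.columns:
        for sex in ("M", "F"):
            sub = table[table["sex"] == sex]
            if len(sub) >= 3:
                strata.append((sex, sub))
    pairs = [(methods[i], methods[j])
             for i in range(len(methods)) for j in range(i + 1, len(methods))]
    rows = []
    for stratum, sub in strata:
        for pair in pairs:
            r = agreement_pair(sub, pair, sem_mode=sem_mode)
            rows.append({
                "stratum": stratum,
                "comparison": f"{pair[0]} vs {pair[1]}",
                "cv_pct": r.cv_pct,
                "sem_cm": r.sem_cm,
                "icc": r.icc,
                "icc_ci_low": r.icc_ci[0],
                "icc_ci_high": r.icc_ci[1],
                "icc_p": r.icc_p,
                "bias_cm": r.bias_cm,
                "bias_sd_cm": r.bias_sd_cm,
                "loa_low_cm": r.loa[0],
                "loa_high_cm": r.loa[1],
                "n": r.n,
            })
    return pd.DataFrame(rows)
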