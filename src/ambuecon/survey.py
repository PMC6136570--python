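"""Survey-side analysis: weighted-rank need scores, pay-service preference
cross-tabulation with an omnibus chi-square, group-wise WTP estimation with
ANOVA / Kruskal-Wallis comparison, and pilot dispatch-log summaries.

Percentages throughout are rounded half-up to one decimal, matching how the
study's tables print rates; internal arithmetic is full precision.
"""

from __future__ import annotations

import dataclasses
import datetime
import decimal
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enums import Group, NeedArea, ReportCategory, ServiceType
from .records import DispatchRecord, SurveyResponse, ValidationError

#: Points awarded per rank place in the weighted need score.
RANK_WEIGHTS = {1: 3, 2: 2, 3: 1}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the tables' convention), not banker's."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def weighted_score(n1: int, n2: int, n3: int) -> int:
    """Weighted rank score: 3 * (1st-place votes) + 2 * (2nd) + 1 * (3rd)."""
    return RANK_WEIGHTS[1] * n1 + RANK_WEIGHTS[2] * n2 + RANK_WEIGHTS[3] * n3


def tally_ranks(responses: list[SurveyResponse]) -> pd.DataFrame:
    """Tally need-area rankings into per-place counts and weighted scores.

    Returns a DataFrame indexed by need area with columns ``n1, n2, n3``
    (rank-place frequencies), ``score`` (3/2/1-weighted), and ``pct1, pct2,
    pct3`` (column percentages; denominator = respondents providing that
    rank place). Sorted by descending score.
    """
    counts = pd.DataFrame(
        0, index=[a.value for a in NeedArea], columns=["n1", "n2", "n3"]
    )
    for r in responses:
        if len(set(r.ranks)) != len(r.ranks):
            raise ValidationError(
                f"respondent {r.respondent_id!r}: duplicate need area in ranks"
            )
        for place, area in enumerate(r.ranks, start=1):
            counts.loc[area.value, f"n{place}"] += 1
    counts = counts.loc[counts.sum(axis=1) > 0]
    counts["score"] = (
        RANK_WEIGHTS[1] * counts["n1"]
        + RANK_WEIGHTS[2] * counts["n2"]
        + RANK_WEIGHTS[3] * counts["n3"]
    )
    for place in (1, 2, 3):
        denom = counts[f"n{place}"].sum()
        counts[f"pct{place}"] = [
            round_half_up(100 * n / denom) if denom else 0.0
            for n in counts[f"n{place}"]
        ]
    counts.index.name = "area"
    return counts.sort_values(["score"], ascending=False)


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Result of one omnibus test across stakeholder groups."""

    service_type: ServiceType | None
    test_used: str  # "anova" | "kruskal_wallis" | "chi_square"
    statistic: float
    p_value: float
    df: int | None = None


def chi_square_from_counts(table: pd.DataFrame | np.ndarray) -> GroupComparison:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(
            f"chi-square needs a table with >= 2 rows and columns, got shape {arr.shape}"
        )
    if np.allclose(arr, arr[0]):  # identical rows: exactly homogeneous
        df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
        return GroupComparison(None, "chi_square", 0.0, 1.0, df)
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return GroupComparison(None, "chi_square", float(chi2), float(p), int(df))


def preference_crosstab(
    responses: list[SurveyResponse],
) -> tuple[pd.DataFrame, GroupComparison]:
    """Group-by-service preference cross-tab with one omnibus chi-square.

    Respondents without a stated preference are excluded (each instrument
    computes its own denominator). Returns the count table with row
    percentages appended (``pct_*`` columns, denominator = group row total)
    and the single omnibus test attached to the whole table — the study
    reports one p-value for the 4 x 3 table, not per-row tests.
    """
    stated = [r for r in responses if r.preferred_service is not None]
    for g in Group:
        n = sum(1 for r in stated if r.group is g)
        if n == 0 and any(r.group is g for r in responses):
            warnings.warn(f"group {g.value!r} has no stated preferences; excluded")
    table = pd.DataFrame(
        0,
        index=[g.value for g in Group],
        columns=[s.value for s in ServiceType],
    )
    for r in stated:
        table.loc[r.group.value, r.preferred_service.value] += 1
    table = table.loc[table.sum(axis=1) > 0]
    if len(table) < 2:
        raise ValidationError(
            f"preference cross-tab needs >= 2 groups with stated preferences, got {len(table)}"
        )
    # a service nobody chose carries no information and would zero the
    # expected frequencies; the omnibus test runs on the informative columns
    comparison = chi_square_from_counts(table.loc[:, table.sum(axis=0) > 0])
    out = table.copy()
    totals = table.sum(axis=1)
    for col in table.columns:
        out[f"pct_{col}"] = [
            round_half_up(100 * table.loc[g, col] / totals[g]) for g in table.index
        ]
    out.index.name = "group"
    return out, comparison


def estimate_wtp(
    responses: list[SurveyResponse], service_type: ServiceType
) -> pd.DataFrame:
    """Per-group open-ended WTP estimates for one service type.

    Returns a DataFrame indexed by group with ``n`` (non-missing responses),
    ``mean`` and ``sd`` (sample standard deviation, n-1 denominator).
    Groups with no stated amount are omitted with a warning.
    """
    rows = {}
    for g in Group:
        values = [
            r.wtp[service_type]
            for r in responses
            if r.group is g and service_type in r.wtp
        ]
        if not values:
            if any(r.group is g for r in responses):
                warnings.warn(
                    f"group {g.value!r}: no stated WTP for {service_type.value}; omitted"
                )
            continue
        arr = np.asarray(values, dtype=float)
        if (arr < 0).any():
            raise ValidationError(f"group {g.value!r}: negative WTP amount")
        rows[g.value] = {
            "n": len(arr),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        }
    if not rows:
        raise ValidationError(f"no stated WTP for service {service_type.value}")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


def compare_samples(
    samples: dict[str, np.ndarray], force_test: str | None = None
) -> GroupComparison:
    """Omnibus location comparison across >= 2 samples.

    Test selection: Shapiro-Wilk normality screen per sample at alpha=0.05;
    one-way ANOVA if every sample passes, Kruskal-Wallis otherwise (constant
    samples count as non-normal). ``force_test`` ("anova" or
    "kruskal_wallis") bypasses the screen.
    """
    if len(samples) < 2:
        raise ValidationError(f"need >= 2 groups to compare, got {len(samples)}")
    arrays = {}
    for name, values in samples.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) < 2:
            raise ValidationError(
                f"group {name!r} has {len(arr)} observation(s); need >= 2"
            )
        arrays[name] = arr
    if force_test is None:
        normal = True
        for arr in arrays.values():
            if np.ptp(arr) == 0:
                normal = False
                break
            if stats.shapiro(arr).pvalue < 0.05:
                normal = False
                break
        test = "anova" if normal else "kruskal_wallis"
    elif force_test in ("anova", "kruskal_wallis"):
        test = force_test
    else:
        raise ValidationError(f"unknown force_test {force_test!r}")
    groups = list(arrays.values())
    if test == "anova":
        res = stats.f_oneway(*groups)
        return GroupComparison(None, "anova", float(res.statistic), float(res.pvalue))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all observations tied: H = 0 by convention
        return GroupComparison(None, "kruskal_wallis", 0.0, 1.0)
    res = stats.kruskal(*groups)
    return GroupComparison(
        None, "kruskal_wallis", float(res.statistic), float(res.pvalue)
    )


def compare_groups(
    responses: list[SurveyResponse],
    service_type: ServiceType,
    force_test: str | None = None,
) -> GroupComparison:
    """Compare WTP for one service across stakeholder groups."""
    samples = {
        g.value: np.asarray(
            [r.wtp[service_type] for r in responses if r.group is g and service_type in r.wtp]
        )
        for g in Group
    }
    samples = {name: arr for name, arr in samples.items() if len(arr) > 0}
    result = compare_samples(samples, force_test=force_test)
    return dataclasses.replace(result, service_type=service_type)


@dataclasses.dataclass(frozen=True)
class PilotSummary:
    """Utilization summary of a dispatch log over an inclusive date window."""

    total_reports: int
    category_counts: dict[ReportCategory, int]
    category_pct: dict[ReportCategory, float]
    hospital_transport_count: int
    hospital_transport_pct: float
    traffic_collision_count: int
    traffic_collision_pct: float
    total_patients: int
    days: int
    mean_patients_per_day: float


def pilot_summary(
    log: list[DispatchRecord],
    period: tuple[datetime.date, datetime.date],
) -> PilotSummary:
    """Summarize pilot utilization over an inclusive date range.

    Besides the exclusive category breakdown, reports the two overlapping
    headline margins: hospital transports (traffic + non-traffic transport
    categories) and traffic collisions, each as a share of all reports.
    Mean patients/day uses the inclusive day span, reported to one decimal.
    """
    start, end = period
    if end < start:
        raise ValidationError(f"period end {end} precedes start {start}")
    days = (end - start).days + 1
    for r in log:
        if not start <= r.date <= end:
            raise ValidationError(
                f"report {r.report_id!r} dated {r.date} outside period {start}..{end}"
            )
        r.validate()
    total = len(log)
    if total == 0:
        warnings.warn("empty dispatch log; returning all-zero summary")
        return PilotSummary(
            0, {c: 0 for c in ReportCategory}, {c: 0.0 for c in ReportCategory},
            0, 0.0, 0, 0.0, 0, days, 0.0,
        )
    counts = {c: sum(1 for r in log if r.category is c) for c in ReportCategory}
    pct = {c: round_half_up(100 * n / total) for c, n in counts.items()}
    transports = (
        counts[ReportCategory.TRAFFIC_TRANSPORT]
        + counts[ReportCategory.NONTRAFFIC_TRANSPORT]
    )
    traffic = counts[ReportCategory.TRAFFIC_TRANSPORT]
    patients = sum(r.n_patients for r in log)
    return PilotSummary(
        total_reports=total,
        category_counts=counts,
        category_pct=pct,
        hospital_transport_count=transports,
        hospital_transport_pct=round_half_up(100 * transports / total),
        traffic_collision_count=traffic,
        traffic_collision_pct=round_half_up(100 * traffic / total),
        total_patients=patients,
        days=days,
        mean_patients_per_day=round_half_up(patients / days),
    )
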