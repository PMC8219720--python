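"""Descriptive summaries: pathway case-mix table, blood-count-class table
for the IDA subgroup, and cumulative blood-count prevalence by look-back
horizon."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    BLOOD_COUNT_CLASSES,
    Cohort,
    CohortError,
    DEFAULT_HB_THRESHOLD,
    DEFAULT_WINDOW_MONTHS,
    PATHWAYS,
    classify_blood_count_history,
)


@dataclass(frozen=True)
class GroupSummary:
    """Counts, percentages and quartile summaries for one group of cases."""

    label: str
    n: int
    percent: float  # of the reference denominator
    sex_ratio_m_f: float
    age_median: float
    age_q1: float
    age_q3: float
    hb_median: float
    hb_q1: float
    hb_q3: float
    early_n: int
    early_percent: float
    right_n: int
    right_percent: float


def _quartiles(values: Sequence[float]):
    # linear-interpolation convention; permutation invariant by construction
    q1, med, q3 = np.percentile(np.asarray(values, float), [25, 50, 75])
    return float(q1), float(med), float(q3)


def _summarise(label: str, df: pd.DataFrame, denominator: int) -> GroupSummary:
    n = len(df)
    n_m = int((df["sex"] == "M").sum())
    n_f = int((df["sex"] == "F").sum())
    q1a, meda, q3a = _quartiles(df["age"])
    q1h, medh, q3h = _quartiles(df["hb_g_l"])
    early_n = int((df["stage_category"] == "early").sum())
    right_n = int((df["side"] == "right").sum())
    return GroupSummary(
        label=label,
        n=n,
        percent=100.0 * n / denominator,
        sex_ratio_m_f=n_m / n_f if n_f else float("inf"),
        age_median=meda,
        age_q1=q1a,
        age_q3=q3a,
        hb_median=medh,
        hb_q1=q1h,
        hb_q3=q3h,
        early_n=early_n,
        early_percent=100.0 * early_n / n,
        right_n=right_n,
        right_percent=100.0 * right_n / n,
    )


def pathway_summary(cohort: Cohort) -> dict[str, GroupSummary]:
    """One summary per presentation pathway; percentages use the whole
    cohort as denominator."""
    if len(cohort) == 0:
        raise CohortError("cannot summarise an empty cohort")
    df = cohort.to_dataframe()
    out = {}
    for p in PATHWAYS:
        sub = df[df["pathway"] == p]
        if len(sub):
            out[p] = _summarise(p, sub, len(df))
    return out


def blood_count_summary(
    ida_cohort: Cohort,
    window_months: float = DEFAULT_WINDOW_MONTHS,
    hb_threshold: float = DEFAULT_HB_THRESHOLD,
) -> dict[str, GroupSummary]:
    """Summaries of the IDA subgroup by outcome of the last prior blood
    count (done with normal Hb / done with low Hb / not done)."""
    for r in ida_cohort:
        if r.pathway != "IDA":
            raise CohortError(f"record {r.id} is not on the IDA pathway")
    if len(ida_cohort) == 0:
        raise CohortError("cannot summarise an empty cohort")
    df = ida_cohort.to_dataframe()
    classes = [
        classify_blood_count_history(r, window_months, hb_threshold) for r in ida_cohort
    ]
    df = df.assign(bc_class=classes)
    out = {}
    for c in BLOOD_COUNT_CLASSES:
        sub = df[df["bc_class"] == c]
        if len(sub):
            out[c] = _summarise(c, sub, len(df))
    return out


def cumulative_prevalence(
    ida_cohort: Cohort,
    horizons_months: Sequence[float] = (12, 24, 36),
    hb_threshold: float = DEFAULT_HB_THRESHOLD,
) -> pd.DataFrame:
    """Cumulative percentage of cases with a blood count within each
    look-back horizon, split by tumour stage and the count's Hb class.

    Returns a long-format frame with one ``overall`` row per horizon plus
    one row per (stage, hb class); the split rows sum to the overall row.
    """
    horizons = list(horizons_months)
    if not horizons:
        raise CohortError("horizons must be non-empty")
    if any(b <= a for a, b in zip(horizons, horizons[1:])):
        raise CohortError("horizons must be strictly increasing")
    n = len(ida_cohort)
    if n == 0:
        raise CohortError("cannot summarise an empty cohort")
    rows = []
    for h in horizons:
        counts: dict[tuple[str, str], int] = {}
        overall = 0
        for r in ida_cohort:
            pbc = r.prior_blood_count
            if pbc is None or pbc.months_before_presentation > h:
                continue
            overall += 1
            hb_class = "low" if pbc.hb_g_l < hb_threshold else "normal"
            key = (r.stage_category, hb_class)
            counts[key] = counts.get(key, 0) + 1
        rows.append(
            {"horizon_months": h, "stage": "all", "hb_class": "all",
             "percent": 100.0 * overall / n}
        )
        for stage in ("early", "late"):
            for hb_class in ("normal", "low"):
                rows.append(
                    {
                        "horizon_months": h,
                        "stage": stage,
                        "hb_class": hb_class,
                        "percent": 100.0 * counts.get((stage, hb_class), 0) / n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt_pct(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}%"


def to_markdown(table: pd.DataFrame) -> str:
    """Pipe-table rendering of a summary table (index as first column)."""
    headers = [""] + [str(c) for c in table.columns]
    lines = ["| " + " | ".join(headers) + " |",
             "|" + "|".join("---" for _ in headers) + "|"]
    for idx, row in table.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |")
    return "\n".join(lines) + "\n"


def summary_table(
    summaries: dict[str, GroupSummary], percent_decimals: int = 1
) -> pd.DataFrame:
    """Case-mix table, one column per group, printed-rounding convention."""
    cols = {}
    for label, s in summaries.items():
        cols[label] = {
            "n (%)": f"{s.n} ({_fmt_pct(s.percent, percent_decimals)})",
            "Sex ratio M/F": f"{s.sex_ratio_m_f:.1f}",
            "Age median (Q1-Q3)": f"{s.age_median:.0f} ({s.age_q1:.0f}-{s.age_q3:.0f})",
            "Hb median (Q1-Q3)": f"{s.hb_median:.0f} ({s.hb_q1:.0f}-{s.hb_q3:.0f})",
            "Early stage n (%)": f"{s.early_n} ({_fmt_pct(s.early_percent, percent_decimals)})",
            "Right-sided n (%)": f"{s.right_n} ({_fmt_pct(s.right_percent, percent_decimals)})",
        }
    return pd.DataFrame(cols)
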