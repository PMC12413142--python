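"""Cohort-level body-composition statistics: decade summaries and one-way ANOVA.

Subjects are grouped by sex and age decade (20-29 ... 60-69, 70+, half-open
bands, ages under 20 excluded).  Per cell we report n, mean, and sample SD;
age trends are tested per metric with classical (equal-variance) one-way
ANOVA computed from sums of squares:

    F = [SSB / (k - 1)] / [SSW / (N - k)],
    SSB = sum_i n_i (xbar_i - xbar)^2,  SSW = sum_i sum_j (x_ij - xbar_i)^2,

with the p value from the F survival function.  The ANOVA is written from
first principles here (it is the analysis under test); scipy provides only
the F distribution.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bodycomp import ValidationError
from .phantom import AGE_BANDS

logger = logging.getLogger("ctcomp")

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "band_of_age",
    "assign_age_bands",
    "summarize",
    "anova_oneway",
    "run_table2_analysis",
    "format_p",
    "round_half_away",
]

DEFAULT_METRICS = ("nama", "lama", "sma", "sma_over_bmi", "imat", "sfat", "vfat")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for printed tables)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def band_of_age(age: float) -> Optional[str]:
    """Decade band label for an age; None below 20 (excluded from analysis)."""
    if age < 20:
        return None
    if age >= 70:
        return "70+"
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def assign_age_bands(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``age_band`` column; drop under-20 rows with a warning."""
    cohort = cohort.copy()
    bands = cohort["age"].map(band_of_age)
    n_drop = int(bands.isna().sum())
    if n_drop:
        warnings.warn(f"excluded {n_drop} subjects aged under 20", stacklevel=2)
    cohort["age_band"] = bands
    return cohort[bands.notna()]


@dataclass
class GroupSummary:
    sex: str
    age_band: str
    metric: str
    n: int
    mean: float
    sd: Optional[float]   # sample SD (n-1); absent when n < 2

    def display(self) -> str:
        mean = round_half_away(self.mean, 1)
        if self.sd is None:
            return f"{mean:g}"
        return f"{mean:g} ({round_half_away(self.sd, 1):g})"


@dataclass
class AnovaResult:
    metric: Optional[str]
    sex: Optional[str]
    k: int
    f: float
    df_between: int
    df_within: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "metric": self.metric, "sex": self.sex, "k": self.k,
            "f": self.f, "df_between": self.df_between,
            "df_within": self.df_within, "p_value": self.p_value,
        }


def summarize(cohort: pd.DataFrame, metric: str) -> list[GroupSummary]:
    """Per sex x age-band n/mean/SD for one metric (non-empty cells only)."""
    if metric not in cohort.columns:
        raise ValidationError(f"metric column {metric!r} absent from cohort")
    df = cohort if "age_band" in cohort.columns else assign_age_bands(cohort)
    out: list[GroupSummary] = []
    for (sex, band), group in df.groupby(["sex", "age_band"], sort=True):
        vals = group[metric].to_numpy(float)
        n = vals.size
        out.append(GroupSummary(
            sex=str(sex), age_band=str(band), metric=metric, n=n,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if n >= 2 else None,
        ))
    out.sort(key=lambda g: (g.sex, AGE_BANDS.index(g.age_band)))
    return out


def anova_oneway(
    groups: Sequence[Sequence[float]],
    metric: Optional[str] = None,
    sex: Optional[str] = None,
) -> AnovaResult:
    """Classical one-way ANOVA from sums of squares.

    Degenerate inputs: SSW = 0 with SSB > 0 gives F = inf, p = 0 (warned);
    SSW = SSB = 0 gives F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValidationError(f"need >= 2 groups, got {k}")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group needs >= 1 value")
    sizes = np.array([g.size for g in groups])
    n_total = int(sizes.sum())
    if n_total <= k:
        raise ValidationError(f"total N={n_total} must exceed k={k}")

    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n_total - k

    if ssw == 0.0:
        if ssb == 0.0:
            f, p = 0.0, 1.0
        else:
            warnings.warn("zero within-group variance with distinct means: p = 0",
                          stacklevel=2)
            f, p = float("inf"), 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(metric=metric, sex=sex, k=k, f=f,
                       df_between=df_b, df_within=df_w, p_value=p)


def format_p(p: float, floor: float = 1e-3) -> str:
    """Display convention: very small p values print as '<.001'."""
    if p < floor:
        return "<.001"
    return f"{round_half_away(p, 2):.2f}".lstrip("0") or ".00"


def run_table2_analysis(
    cohort: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    out_dir=None,
) -> dict:
    """Decade summary + ANOVA for every metric, per sex.

    Returns ``{sex: {"table": DataFrame, "anova": [AnovaResult, ...]}}``;
    the table has one row per metric, one 'mean (SD)' column per band plus a
    formatted P column.  When ``out_dir`` is given, writes per-sex summary
    CSVs, an ANOVA CSV, and a combined JSON.
    """
    missing = [m for m in metrics if m not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort lacks metric columns: {missing}")
    df = assign_age_bands(cohort) if "age_band" not in cohort.columns else cohort

    results: dict = {}
    anova_rows = []
    for sex in sorted(df["sex"].unique()):
        sub = df[df["sex"] == sex]
        table_rows = {}
        anovas = []
        for metric in metrics:
            cells = summarize(sub, metric)
            row = {c.age_band: c.display() for c in cells}
            groups = [
                sub.loc[sub["age_band"] == band, metric].to_numpy(float)
                for band in AGE_BANDS
                if (sub["age_band"] == band).any()
            ]
            res = anova_oneway(groups, metric=metric, sex=str(sex))
            anovas.append(res)
            anova_rows.append(res.as_dict())
            row["P"] = format_p(res.p_value)
            table_rows[metric] = row
        table = pd.DataFrame.from_dict(table_rows, orient="index")
        table = table.reindex(columns=[*AGE_BANDS, "P"])
        results[str(sex)] = {"table": table, "anova": anovas}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sex, payload in results.items():
            payload["table"].to_csv(out_dir / f"summary_{sex}.csv", index_label="metric")
        pd.DataFrame(anova_rows).to_csv(out_dir / "anova.csv", index=False)
        combined = {
            sex: {
                "table": payload["table"].to_dict(orient="index"),
                "anova": [a.as_dict() for a in payload["anova"]],
            }
            for sex, payload in results.items()
        }
        (out_dir / "cohort_stats.json").write_text(json.dumps(combined, indent=2))
        logger.info("wrote cohort statistics to %s", out_dir)
    return results
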