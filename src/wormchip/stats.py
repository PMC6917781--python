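"""Condition × dose aggregation and the reported contrasts.

Per-individual phenotypes are summarized as mean ± SD per (condition, dose,
phenotype) group; treatment arms are contrasted against control as an
integer-rounded percent change of means (the platform's reporting
convention), and group differences are tested with one-way ANOVA for scalar
phenotypes or a mixed (condition between × time within) repeated-measures
ANOVA for area and intensity traces.  The ANOVA machinery is delegated to
scipy/pingouin — the bespoke content here is the contrast/rounding
convention and the design mapping.  No multiple-testing correction is
applied; each phenotype panel is tested on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import PhenotypeTable

__all__ = [
    "ConditionSummary",
    "Contrast",
    "AnovaResult",
    "summarize",
    "percent_change",
    "compare_groups",
    "significance_stars",
]

logger = logging.getLogger(__name__)

#: Figure-style significance thresholds.
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ConditionSummary:
    """Mean ± SD of one phenotype within one (condition, dose) group."""

    condition: str
    dose: int
    phenotype_name: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class Contrast:
    """Percent change of a treated arm versus control, rounded to integer
    percent for reporting, with a two-sample Welch t-test."""

    phenotype_name: str
    treated: str
    control: str
    dose: int
    percent_change: float
    percent_change_rounded: int
    t_statistic: float
    p_value: float


@dataclass
class AnovaResult:
    effect: str
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float
    stars: str
    excluded_subjects: int = 0


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return ""


def summarize(table: PhenotypeTable) -> list[ConditionSummary]:
    """One mean ± SD summary per (condition, dose, phenotype) group.

    ``n`` is the row (individual) count; SD is the sample standard deviation
    and 0 for singleton groups.  Empty groups cannot arise from a tidy table
    and are therefore simply absent (a notice is logged if the table itself
    is empty).
    """
    df = table.df
    if df.empty:
        logger.info("summarize: empty phenotype table, no summaries produced")
        return []
    out = []
    grouped = df.groupby(["condition", "dose", "phenotype_name"], sort=True)
    for (condition, dose, name), grp in grouped:
        values = grp["value"].to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        out.append(
            ConditionSummary(
                condition=str(condition),
                dose=int(dose),
                phenotype_name=str(name),
                n=len(values),
                mean=float(values.mean()),
                sd=sd,
            )
        )
    return out


def percent_change(
    treated: ConditionSummary,
    control: ConditionSummary,
    treated_values: np.ndarray | None = None,
    control_values: np.ndarray | None = None,
) -> Contrast:
    """P = 100 · (mean_T − mean_C) / mean_C, reported rounded to integer
    percent.  When the raw per-individual values are supplied a Welch t-test
    accompanies the contrast (NaN otherwise).
    """
    if treated.phenotype_name != control.phenotype_name:
        raise ValueError("contrast requires matching phenotypes")
    if control.mean == 0:
        raise ValueError("control mean is zero: percent change undefined")
    p = 100.0 * (treated.mean - control.mean) / control.mean
    rounded = int(np.floor(p + 0.5)) if p >= 0 else -int(np.floor(-p + 0.5))
    t_stat = p_val = float("nan")
    if treated_values is not None and control_values is not None:
        t_stat, p_val = sps.ttest_ind(treated_values, control_values, equal_var=False)
        t_stat, p_val = float(t_stat), float(p_val)
    return Contrast(
        phenotype_name=treated.phenotype_name,
        treated=treated.condition,
        control=control.condition,
        dose=treated.dose,
        percent_change=p,
        percent_change_rounded=rounded,
        t_statistic=t_stat,
        p_value=p_val,
    )


def compare_groups(
    df: pd.DataFrame,
    dv: str = "value",
    between: str = "condition",
    within: str | None = None,
    subject: str = "individual_id",
) -> list[AnovaResult]:
    """Omnibus test across condition groups.

    Scalar phenotypes (``within=None``): one-way ANOVA across the levels of
    ``between``.  Trace phenotypes (``within`` naming the time column): mixed
    repeated-measures two-way ANOVA (condition between-subjects × time
    within-subjects) via pingouin; subjects with incomplete time series are
    excluded listwise and the exclusion count logged and reported.
    """
    if df[between].nunique() < 2:
        raise ValueError("need >= 2 groups to compare")
    if within is None:
        groups = [g[dv].to_numpy(dtype=float) for _, g in df.groupby(between)]
        f_stat, p = sps.f_oneway(*groups)
        df_num = len(groups) - 1
        df_den = sum(len(g) for g in groups) - len(groups)
        return [
            AnovaResult(
                effect=between,
                f_statistic=float(f_stat),
                df_num=float(df_num),
                df_den=float(df_den),
                p_value=float(p),
                stars=significance_stars(float(p)),
            )
        ]

    import pingouin  # deferred: heavy import

    n_times = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == n_times].index
    excluded = int(len(counts) - len(complete))
    if excluded:
        logger.info("compare_groups: excluded %d subjects with incomplete series", excluded)
    data = df[df[subject].isin(complete)]
    table = pingouin.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
    out = []
    for _, row in table.iterrows():
        p = float(row[p_col])
        out.append(
            AnovaResult(
                effect=str(row["Source"]),
                f_statistic=float(row["F"]),
                df_num=float(row["DF1"]),
                df_den=float(row["DF2"]),
                p_value=p,
                stars=significance_stars(p),
                excluded_subjects=excluded,
            )
        )
    return out
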