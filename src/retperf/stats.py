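"""Tissue perfusion and group-level statistics.

Tissue perfusion normalizes macular blood flow by the inner-retina
tissue volume it supplies::

    perfusion (nl/s/mm^3) = blood flow (nl/s) / tissue volume (mm^3)

Group comparisons follow the study design: Student two-sample t-tests
(pooled variance by default, Welch optional) for continuous outcomes,
Spearman rank correlation for monotone association, an uncorrected
Pearson chi-square for 2x2 categorical tables, and percent differences
reported relative to the control group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)


@dataclass
class GroupComparison:
    """One two-group contrast: descriptives, test statistic and p."""

    label_a: str
    label_b: str
    n_a: int
    mean_a: float
    sd_a: float
    n_b: int
    mean_b: float
    sd_b: float
    difference: float
    percent_difference: float
    statistic: float
    p_value: float
    df: float
    test_name: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def tissue_perfusion(flow_nl_s: float, inner_volume_mm3: float) -> float:
    """Flow per unit of supplied tissue volume, nl/s/mm³."""
    if inner_volume_mm3 <= 0:
        raise InvalidInputError("inner_volume_mm3 must be positive")
    return flow_nl_s / inner_volume_mm3


def percent_difference(mean_cad: float, mean_cn: float) -> float:
    """Decrease of the case mean relative to the control mean, percent:
    ``(mean_cn - mean_cad) / mean_cn * 100``."""
    if mean_cn == 0:
        raise InvalidInputError("control mean must be nonzero")
    return (mean_cn - mean_cad) / mean_cn * 100.0


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report
    convention for percent differences)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def two_sample_t(
    group_a,
    group_b,
    variant: str = "student_pooled",
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Two-sided two-sample t-test.

    ``student_pooled`` (default) uses the pooled-variance statistic with
    nA + nB - 2 degrees of freedom; ``welch`` uses the unequal-variance
    statistic with Welch–Satterthwaite df. The percent difference is
    reported with group B as the reference (control) arm.
    """
    if variant not in ("student_pooled", "welch"):
        raise InvalidParameterError(f"unknown t-test variant {variant!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    equal_var = variant == "student_pooled"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        n_a=a.size, mean_a=mean_a, sd_a=float(a.std(ddof=1)),
        n_b=b.size, mean_b=mean_b, sd_b=float(b.std(ddof=1)),
        difference=mean_a - mean_b,
        percent_difference=(percent_difference(mean_a, mean_b)
                            if mean_b != 0 else math.nan),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        test_name="Student t (pooled)" if equal_var else "Welch t",
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank-order correlation with mid-rank ties and the
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a constant vector"
        )
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 count table (df = 1)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidInputError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) \
            and not np.allclose(t, np.round(t)):
        raise InvalidInputError("table must hold non-negative integers")
    t = t.astype(float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# subject-table analysis
# ---------------------------------------------------------------------------

#: continuous outcomes compared between arms, with display units
OUTCOME_COLUMNS = {
    "perfusion_nl_s_mm3": "tissue perfusion (nl/s/mm^3)",
    "macular_flow_nl_s": "macular blood flow (nl/s)",
    "inner_volume_mm3": "inner retina volume (mm^3)",
    "gcipl_mm3": "GCIPL volume (mm^3)",
}


def compare_groups(
    subjects: pd.DataFrame,
    columns: dict[str, str] | None = None,
    case_label: str = "CAD",
    control_label: str = "CN",
    variant: str = "student_pooled",
) -> dict[str, GroupComparison]:
    """Case-vs-control t-tests on each outcome column of a subject
    table; the percent difference is relative to the control arm."""
    columns = columns or OUTCOME_COLUMNS
    case = subjects[subjects["group"] == case_label]
    control = subjects[subjects["group"] == control_label]
    if case.empty or control.empty:
        raise InsufficientDataError("both group labels must be present")
    out = {}
    for col in columns:
        out[col] = two_sample_t(
            case[col], control[col], variant=variant,
            label_a=case_label, label_b=control_label,
        )
    return out


def comparison_markdown(
    comparisons: dict[str, GroupComparison],
    columns: dict[str, str] | None = None,
) -> str:
    """Render comparisons as a Markdown table (mean ± SD per arm,
    percent decrease vs control, t and p)."""
    columns = columns or OUTCOME_COLUMNS
    lines = [
        "| Outcome | CAD (mean ± SD) | CN (mean ± SD) | Decrease | t | p |",
        "|---|---|---|---|---|---|",
    ]
    for col, comp in comparisons.items():
        label = columns.get(col, col)
        lines.append(
            f"| {label} "
            f"| {comp.mean_a:.2f} ± {comp.sd_a:.2f} (n={comp.n_a}) "
            f"| {comp.mean_b:.2f} ± {comp.sd_b:.2f} (n={comp.n_b}) "
            f"| {round_half_away(comp.percent_difference)}% "
            f"| {comp.statistic:.2f} | {comp.p_value:.2g} |"
        )
    return "\n".join(lines)
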