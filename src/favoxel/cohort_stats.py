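"""One-way ANOVA across groups from printed summary statistics.

Group-comparison tables in clinical studies report each group as
(n, mean, SD).  The one-way ANOVA F statistic is fully determined by those
triples:

    SS_between = sum_i n_i (mean_i - grand_mean)^2
    SS_within  = sum_i (n_i - 1) sd_i^2
    F = (SS_between / (k - 1)) / (SS_within / (N - k))

so the printed p-value column can be recomputed (and audited) without the
raw measurements.  SDs are taken as sample (n-1) standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and sample standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def anova_oneway(groups: list[GroupSummary]) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA from summaries: returns (F, (df_between, df_within), p).

    With zero within-group variance but distinct means, p is 0 by
    convention (and a warning is logged).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    k = len(groups)
    N = ns.sum()
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df = (k - 1, int(N) - k)
    if ss_within == 0:
        if ss_between > 0:
            logger.warning("zero within-group variance with distinct means; p = 0")
            return np.inf, df, 0.0
        return 0.0, df, 1.0
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(F, *df))
    return float(F), df, p


def summaries_equivalent_data(groups: list[GroupSummary]) -> list[np.ndarray]:
    """Construct raw samples realising each (n, mean, sd) triple exactly.

    A standardised zero-mean unit-sd base vector is scaled and shifted per
    group, so a raw-data ANOVA on the result must agree with
    :func:`anova_oneway` on the summaries.
    """
    out = []
    for g in groups:
        base = np.linspace(-1.0, 1.0, g.n)
        base -= base.mean()
        base /= base.std(ddof=1)
        out.append(g.mean + g.sd * base)
    return out


def anova_table(df: pd.DataFrame) -> pd.DataFrame:
    """ANOVA column for a long table with columns measure, group, n, mean, sd."""
    rows = []
    for measure, sub in df.groupby("measure", sort=False):
        groups = [
            GroupSummary(int(r.n), float(r.mean), float(r.sd))
            for r in sub.itertuples()
        ]
        F, dfree, p = anova_oneway(groups)
        rows.append({"measure": measure, "F": F, "df1": dfree[0], "df2": dfree[1], "p": p})
    return pd.DataFrame(rows)
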