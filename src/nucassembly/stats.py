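"""Normality-gated group comparison scheme and two-group tests.

Replicates the screening statistics convention: every group is first checked
with the D'Agostino–Pearson omnibus normality test; if *all* groups look
normal (p > 0.05) the parametric path runs (one-way ANOVA followed by
Dunnett's many-to-one comparisons against the control), otherwise the
nonparametric path runs (Kruskal–Wallis followed by Dunn's test against the
control, Bonferroni-adjusted over the control comparisons).  Significance is
declared at alpha = 0.001 unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

NORMALITY_ALPHA = 0.05
MIN_N_NORMALITY = 8  # below this the omnibus test is not defined/reliable


@dataclass
class GroupComparisonReport:
    groups: list[str]
    n_per_group: dict[str, int]
    control: str
    family: str                    # "parametric" | "nonparametric"
    normality_p: dict[str, float]
    omnibus_stat: float
    omnibus_p: float
    comparisons: pd.DataFrame      # group, statistic, p_unadjusted, p_adjusted, significant
    alpha: float
    fallback_small_n: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = self.comparisons.copy()
        df.insert(0, "control", self.control)
        df["family"] = self.family
        df["omnibus_stat"] = self.omnibus_stat
        df["omnibus_p"] = self.omnibus_p
        df["alpha"] = self.alpha
        return df


def _dunn_vs_control(samples: dict[str, np.ndarray], control: str) -> pd.DataFrame:
    """Dunn's rank-based many-to-one z tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum over tie groups of (t^3 - t); two-sided p from the normal,
    Bonferroni-adjusted over the number of control comparisons.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_unit = N * (N + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(samples[g])
        mean_ranks[g] = float(ranks[start : start + n].mean())
        sizes[g] = n
        start += n

    others = [g for g in names if g != control]
    k = len(others)
    rows = []
    for g in others:
        se = np.sqrt(var_unit * (1.0 / sizes[control] + 1.0 / sizes[g]))
        z = (mean_ranks[g] - mean_ranks[control]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({
            "group": g,
            "statistic": float(z),
            "p_unadjusted": float(p),
            "p_adjusted": float(min(1.0, p * k)),
        })
    return pd.DataFrame(rows)


def compare_groups(
    values: dict[str, "np.ndarray | list"] | pd.DataFrame,
    control: str,
    alpha: float = 0.001,
    value_col: str = "value",
    group_col: str = "group",
) -> GroupComparisonReport:
    """Normality-gated omnibus + many-to-one comparison against a control.

    ``values`` is either ``{group: samples}`` or a long DataFrame.  The
    parametric path (ANOVA + Dunnett) runs only when every group passes the
    D'Agostino–Pearson test at p > 0.05 with adequate n; otherwise the
    nonparametric path (Kruskal–Wallis + Dunn) runs, and groups too small
    for the normality test force the nonparametric path with a flag.
    """
    if isinstance(values, pd.DataFrame):
        values = {str(g): grp[value_col].to_numpy(dtype=float)
                  for g, grp in values.groupby(group_col)}
    samples = {str(g): np.asarray(v, dtype=float) for g, v in values.items()}
    if control not in samples:
        raise ValueError(f"control group {control!r} not among {sorted(samples)}")
    if len(samples) < 2:
        raise ValueError("need at least two groups")

    normality_p: dict[str, float] = {}
    fallback = False
    all_normal = True
    for g, v in samples.items():
        if len(v) < MIN_N_NORMALITY:
            normality_p[g] = float("nan")
            fallback = True
            all_normal = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns for 8 <= n < 20
            p = float(sps.normaltest(v).pvalue)
        normality_p[g] = p
        if p <= NORMALITY_ALPHA:
            all_normal = False

    names = list(samples)
    others = [g for g in names if g != control]
    if all_normal and not fallback:
        family = "parametric"
        stat, p_omni = sps.f_oneway(*[samples[g] for g in names])
        res = sps.dunnett(*[samples[g] for g in others], control=samples[control])
        comparisons = pd.DataFrame({
            "group": others,
            "statistic": np.asarray(res.statistic, dtype=float),
            "p_unadjusted": np.asarray(res.pvalue, dtype=float),  # already adjusted
            "p_adjusted": np.asarray(res.pvalue, dtype=float),
        })
    else:
        family = "nonparametric"
        stat, p_omni = sps.kruskal(*[samples[g] for g in names])
        comparisons = _dunn_vs_control(samples, control)
    comparisons["significant"] = comparisons["p_adjusted"] < alpha

    return GroupComparisonReport(
        groups=names,
        n_per_group={g: int(len(samples[g])) for g in names},
        control=control,
        family=family,
        normality_p=normality_p,
        omnibus_stat=float(stat),
        omnibus_p=float(p_omni),
        comparisons=comparisons,
        alpha=alpha,
        fallback_small_n=fallback,
    )


def two_group_test(a, b, equal_var: bool = False) -> dict:
    """Two-tailed two-sample t test (Welch by default).

    Returns the statistic and p value; zero variance in both samples with
    equal means leaves the statistic undefined and is flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"statistic": 0.0, "p": 1.0, "flagged": True}
        return {"statistic": float("inf"), "p": 0.0, "flagged": True}
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "flagged": False}
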