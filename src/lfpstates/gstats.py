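"""Normality-gated group comparisons for pipeline outputs.

Groups are first screened with the Shapiro–Wilk test (per group, default
alpha 0.05).  When every group is compatible with normality a parametric
test is used (Student's t, one-way ANOVA with a Holm–Šidák post hoc, or
two-way group × contrast ANOVA); otherwise the rank-based counterpart is
used (Mann–Whitney, Kruskal–Wallis with a Dunn post hoc).  Paired
parameter comparisons (e.g. K_50 before/after a treatment) use the
Wilcoxon signed-rank test.  Every result records the full decision trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "gated_two_group",
    "gated_multi_group",
    "contrast_curve_comparison",
    "paired_fit_comparison",
]


class InsufficientDataError(ValueError):
    """Too few groups or observations for the requested comparison."""


@dataclass
class ComparisonResult:
    """Outcome of a gated comparison plus its decision trail."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple
    normality_p: tuple = ()
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "normality_p": list(self.normality_p),
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        d.update(self.extra)
        return d


def _shapiro_p(x: np.ndarray) -> float:
    # constant samples carry no evidence against normality for the gate's
    # purpose but break Shapiro-Wilk; treat as "not non-normal"
    if np.ptp(x) == 0:
        return 1.0
    return float(stats.shapiro(x).pvalue)


def _check_groups(groups, min_n=3):
    groups = [np.asarray(g, dtype=float).reshape(-1) for g in groups]
    for g in groups:
        if g.size < min_n:
            raise InsufficientDataError(
                f"every group needs at least {min_n} observations")
    return groups


def gated_two_group(a, b, alpha_norm: float = 0.05) -> ComparisonResult:
    """Two-group location comparison with a Shapiro–Wilk gate.

    Both groups normal at ``alpha_norm`` → Student's two-sample t-test;
    otherwise two-sided Mann–Whitney.
    """
    a, b = _check_groups([a, b])
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    normal = pa > alpha_norm and pb > alpha_norm
    if np.ptp(np.concatenate([a, b])) == 0:
        # identical constant data: no location difference by construction
        stat, p, name = 0.0, 1.0, "student_t"
    elif normal:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return ComparisonResult(
        test_name=name, statistic=float(stat), p_value=float(p),
        n_per_group=(a.size, b.size), normality_p=(pa, pb),
        extra={"mean_difference": float(b.mean() - a.mean()),
               "gate_alpha": alpha_norm})


def _dunn_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's z-test on mean ranks after Kruskal–Wallis, Holm-adjusted."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction factor of the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    splits = np.cumsum([g.size for g in groups])[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(tie * n * (n + 1) / 12.0
                         * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            rows.append({"group_i": i, "group_j": j, "z": float(z),
                         "p_raw": float(2 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def _pairwise_t_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, p = stats.ttest_ind(groups[i], groups[j], equal_var=True)
            rows.append({"group_i": i, "group_j": j, "t": float(t),
                         "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm-sidak")[1]
    return out


def gated_multi_group(groups, alpha_norm: float = 0.05) -> ComparisonResult:
    """k-group omnibus comparison (k ≥ 3) with a Shapiro–Wilk gate.

    All groups normal → one-way ANOVA with Holm–Šidák pairwise t post hoc;
    otherwise Kruskal–Wallis with a Holm-adjusted Dunn post hoc.
    """
    if len(groups) < 3:
        raise InsufficientDataError(
            "need >= 3 groups; use gated_two_group for two groups")
    groups = _check_groups(groups)
    norm_p = tuple(_shapiro_p(g) for g in groups)
    if np.ptp(np.concatenate(groups)) == 0:
        stat, p, name, ph = 0.0, 1.0, "anova_oneway", None
    elif all(pv > alpha_norm for pv in norm_p):
        stat, p = stats.f_oneway(*groups)
        name, ph = "anova_oneway", _pairwise_t_posthoc(groups)
    else:
        stat, p = stats.kruskal(*groups)
        name, ph = "kruskal_wallis", _dunn_posthoc(groups)
    return ComparisonResult(
        test_name=name, statistic=float(stat), p_value=float(p),
        n_per_group=tuple(g.size for g in groups), normality_p=norm_p,
        posthoc=ph, extra={"gate_alpha": alpha_norm})


def contrast_curve_comparison(curves_a: pd.DataFrame | np.ndarray,
                              curves_b: pd.DataFrame | np.ndarray,
                              contrasts: np.ndarray | None = None
                              ) -> ComparisonResult:
    """Two-way group × contrast comparison of contrast-response curves.

    Inputs are per-subject amplitude matrices (subjects × contrasts) or
    long DataFrames with ``subject``, ``contrast``, ``amplitude`` columns.
    A two-factor ANOVA (type-III sums of squares, sum-to-zero coding) tests
    the group main effect and the group × contrast interaction; the
    reported ``p_value`` is the group main effect (the interaction p is in
    ``extra`` — testing both without correction would inflate the
    false-positive rate).  Per-contrast two-sample t-tests
    with Holm–Šidák adjustment are attached as the post hoc table.
    """
    def _to_long(c, gname):
        if isinstance(c, pd.DataFrame) and {"contrast", "amplitude"} <= set(c.columns):
            d = c.copy()
            if "subject" not in d.columns:
                d["subject"] = 0
        else:
            m = np.atleast_2d(np.asarray(c, dtype=float))
            if contrasts is None:
                raise ValueError("matrix input requires the contrasts vector")
            d = pd.DataFrame({
                "subject": np.repeat(np.arange(m.shape[0]), m.shape[1]),
                "contrast": np.tile(np.asarray(contrasts, float), m.shape[0]),
                "amplitude": m.ravel(),
            })
        d["group"] = gname
        d["subject"] = gname + "_" + d["subject"].astype(str)
        return d

    da, db = _to_long(curves_a, "A"), _to_long(curves_b, "B")
    shared = sorted(set(da["contrast"]) & set(db["contrast"]))
    if not shared:
        raise ValueError("groups share no contrast levels")
    if len(shared) == 1:
        import warnings
        warnings.warn("single shared contrast: degenerating to a two-group "
                      "comparison", stacklevel=2)
        res = gated_two_group(
            da.loc[da["contrast"] == shared[0], "amplitude"],
            db.loc[db["contrast"] == shared[0], "amplitude"])
        res.extra["degenerate_single_contrast"] = True
        return res
    data = pd.concat([da, db], ignore_index=True)
    data = data[data["contrast"].isin(shared)]
    model = smf.ols(
        "amplitude ~ C(group, Sum) * C(contrast, Sum)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=3)
    p_group = float(table.loc["C(group, Sum)", "PR(>F)"])
    p_inter = float(table.loc["C(group, Sum):C(contrast, Sum)", "PR(>F)"])
    f_group = float(table.loc["C(group, Sum)", "F"])
    rows = []
    for c in shared:
        xa = data.loc[(data.group == "A") & (data.contrast == c), "amplitude"]
        xb = data.loc[(data.group == "B") & (data.contrast == c), "amplitude"]
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        rows.append({"contrast": c, "t": float(t), "p_raw": float(p)})
    ph = pd.DataFrame(rows)
    ph["p_adj"] = multipletests(ph["p_raw"], method="holm-sidak")[1]
    na = da.loc[da["contrast"].isin(shared), "subject"].nunique()
    nb = db.loc[db["contrast"].isin(shared), "subject"].nunique()
    return ComparisonResult(
        test_name="anova_twoway_type3", statistic=f_group,
        p_value=p_group, n_per_group=(na, nb), posthoc=ph,
        extra={"p_group": p_group, "p_interaction": p_inter,
               "shared_contrasts": shared})


def paired_fit_comparison(pre, post) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired parameter vectors.

    Used for within-subject before/after comparisons of fitted parameters
    (e.g. K_50 pre/post a pharmacological manipulation).  All-zero
    differences return p = 1 (no evidence of a shift).
    """
    pre = np.asarray(pre, dtype=float).reshape(-1)
    post = np.asarray(post, dtype=float).reshape(-1)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired (equal length)")
    if pre.size < 3:
        raise InsufficientDataError("need >= 3 pairs for a signed-rank test")
    diffs = post - pre
    if np.all(diffs == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(pre, post, zero_method="wilcox",
                                 method="exact" if pre.size <= 25 else "auto")
    return ComparisonResult(
        test_name="wilcoxon_signed_rank", statistic=float(stat),
        p_value=float(p), n_per_group=(pre.size, post.size),
        extra={"median_difference": float(np.median(diffs))})
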