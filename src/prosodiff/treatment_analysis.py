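"""Within-speaker differencing and three-arm treatment-effect statistics.

The analysis unit is the within-speaker difference value
``diff = value(BEF) - value(AFT)`` per feature: positive diffs mean the
feature was lower after treatment. Differences are compared across the
three treatment arms with a one-way MANOVA per feature family (Wilks'
lambda, Rao's F approximation, multivariate partial eta squared),
univariate one-way ANOVA follow-ups, and pairwise Welch t contrasts with
a configurable multiplicity correction. The study-style significance
threshold defaults to alpha = 0.1.

Degrees of freedom follow the textbook one-way formulas (error df
N - k for univariate tests with N complete pairs and k = 3 arms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .prosody_features import FEATURE_COLUMNS

__all__ = [
    "FeatureFamily",
    "ManovaResult",
    "AnovaResult",
    "ContrastResult",
    "GroupSummary",
    "DEFAULT_FAMILIES",
    "within_speaker_differences",
    "manova_oneway",
    "anova_univariate",
    "pairwise_contrasts",
    "summarize_differences",
]

GROUP_PAIRS = (("VBRO", "MEDI"), ("VBRO", "CONT"), ("MEDI", "CONT"))


@dataclass(frozen=True)
class FeatureFamily:
    """A named, disjoint set of profile features analysed jointly."""

    name: str
    members: tuple


#: The three tested vocal dimensions plus the reported-but-untested
#: timing family. Memberships are editable at call time.
DEFAULT_FAMILIES = (
    FeatureFamily(
        "intonation",
        ("f0_min_hz", "f0_max_hz", "f0_range_st", "f0_sd_hz", "f0_level_hz"),
    ),
    FeatureFamily(
        "vocal_effort", ("h1_h2_db", "h1_a1_db", "h1_a2_db", "h1_a3_db")
    ),
    FeatureFamily("loudness", ("rms_level_db", "rms_sd_db")),
    FeatureFamily(
        "timing", ("n_pauses", "mean_pause_s", "speaking_rate_sps")
    ),
)


@dataclass(frozen=True)
class ManovaResult:
    family: str
    statistic: str  # "wilks" or "pillai"
    value: float  # the multivariate statistic itself
    wilks_lambda: float
    F_stat: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    n_cases: int


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    F_stat: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class ContrastResult:
    feature: str
    group_pair: tuple
    t_stat: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupSummary:
    feature: str
    treatment: str
    mean: float
    se: float
    n: int


def within_speaker_differences(features: pd.DataFrame) -> pd.DataFrame:
    """Compute BEF - AFT difference values per speaker and feature.

    ``features`` is the batch table with ``speaker_id``, ``condition``,
    ``treatment`` (and optionally ``gender``) columns plus feature
    columns. Speakers missing either condition are dropped with a
    warning; a diff is NaN when either condition's value is NaN.
    """
    needed = {"speaker_id", "condition", "treatment"}
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"features table missing column(s): {sorted(missing)}")
    feats = [c for c in FEATURE_COLUMNS if c in features.columns]
    bef = features[features["condition"] == "BEF"].set_index("speaker_id")
    aft = features[features["condition"] == "AFT"].set_index("speaker_id")
    complete = bef.index.intersection(aft.index)
    dropped = sorted(set(bef.index).symmetric_difference(aft.index))
    if dropped:
        warnings.warn(
            f"speaker(s) missing a condition, excluded from pairing: {dropped}"
        )
    if len(complete) == 0:
        raise ValueError("no complete BEF/AFT pairs")
    diffs = bef.loc[complete, feats] - aft.loc[complete, feats]
    diffs.insert(0, "treatment", bef.loc[complete, "treatment"])
    if "gender" in bef.columns:
        diffs.insert(1, "gender", bef.loc[complete, "gender"])
    return diffs.rename_axis("speaker_id").reset_index()


def _family_matrix(diffs: pd.DataFrame, family: FeatureFamily) -> tuple:
    members = [m for m in family.members if m in diffs.columns]
    if not members:
        raise ValueError(f"family {family.name!r} has no columns in the table")
    sub = diffs[["treatment", *members]].dropna()
    groups = [g for _, g in sub.groupby("treatment", sort=True)]
    if len(groups) < 2:
        raise ValueError("need at least two treatment groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 complete cases")
    return sub, members, groups


def scatter_matrices(sub: pd.DataFrame, members: list) -> tuple:
    """Between-group (H) and within-group (E) scatter matrices."""
    X = sub[members].to_numpy(dtype=float)
    grand = X.mean(axis=0)
    H = np.zeros((len(members), len(members)))
    E = np.zeros_like(H)
    for _, g in sub.groupby("treatment", sort=True):
        Xg = g[members].to_numpy(dtype=float)
        mg = Xg.mean(axis=0)
        d = (mg - grand)[:, None]
        H += len(Xg) * (d @ d.T)
        R = Xg - mg
        E += R.T @ R
    return H, E


def manova_oneway(
    diffs: pd.DataFrame,
    family: FeatureFamily,
    statistic: str = "wilks",
) -> ManovaResult:
    """One-way MANOVA of a feature family across treatment arms.

    Wilks' lambda is ``det(E)/det(H + E)`` from the between- and
    within-group scatter matrices of the family's difference columns,
    converted to an F statistic by Rao's approximation; the multivariate
    partial eta squared is ``1 - lambda**(1/s)``. ``statistic="pillai"``
    switches to the Pillai trace (more robust to covariance
    heterogeneity) with its standard F approximation; Wilks' lambda is
    reported in both cases.
    """
    sub, members, groups = _family_matrix(diffs, family)
    N, p, k = len(sub), len(members), len(groups)
    q = k - 1
    H, E = scatter_matrices(sub, members)
    det_E = np.linalg.det(E)
    det_T = np.linalg.det(H + E)
    if det_E <= 0 or det_T <= 0 or not np.isfinite(det_E / det_T):
        raise ValueError(
            f"singular within-group scatter for family {family.name!r}; "
            "reduce the feature family or collect more cases"
        )
    lam = float(det_E / det_T)

    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    w = (N - 1) - (p + q + 1) / 2.0
    df2 = w * s - (p * q - 2) / 2.0
    if df2 <= 0:
        raise ValueError("not enough error degrees of freedom for this family")
    lam_s = lam ** (1.0 / s)
    F = (1 - lam_s) / lam_s * df2 / df1
    eta = 1.0 - lam_s

    if statistic == "wilks":
        value, p_val = lam, float(sps.f.sf(F, df1, df2))
    elif statistic == "pillai":
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        s_p = min(p, q)
        m = (abs(p - q) - 1) / 2.0
        n_p = (N - k - p - 1) / 2.0
        df1 = s_p * (2 * m + s_p + 1)
        df2 = s_p * (2 * n_p + s_p + 1)
        F = (2 * n_p + s_p + 1) / (2 * m + s_p + 1) * (V / s_p) / (1 - V / s_p)
        value, p_val = V, float(sps.f.sf(F, df1, df2))
        eta = V / s_p
    else:
        raise ValueError(f"unknown MANOVA statistic {statistic!r}")

    return ManovaResult(
        family=family.name,
        statistic=statistic,
        value=value,
        wilks_lambda=lam,
        F_stat=float(F),
        df1=float(df1),
        df2=float(df2),
        p=p_val,
        partial_eta_sq=float(eta),
        n_cases=N,
    )


def anova_univariate(diffs: pd.DataFrame, feature: str) -> AnovaResult:
    """One-way fixed-effects ANOVA of one difference column.

    Effect size is ``eta_p^2 = SS_effect / (SS_effect + SS_error)``.
    With zero within-group variance the F ratio is infinite and
    ``eta_p^2 = 1`` is returned flagged by ``p = 0``.
    """
    sub = diffs[["treatment", feature]].dropna()
    groups = [g[feature].to_numpy(float) for _, g in sub.groupby("treatment")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 complete cases")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(feature, 0.0, df1, df2, 1.0, 0.0)
        return AnovaResult(feature, math.inf, df1, df2, 0.0, 1.0)
    F = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(
        feature=feature,
        F_stat=float(F),
        df1=df1,
        df2=df2,
        p=float(sps.f.sf(F, df1, df2)),
        partial_eta_sq=float(ss_between / (ss_between + ss_within)),
    )


def pairwise_contrasts(
    diffs: pd.DataFrame,
    feature: str,
    alpha: float = 0.1,
    correction: str = "holm",
) -> list:
    """Welch two-sample t-tests between each pair of treatment arms.

    ``correction`` is one of {"none", "holm", "bonferroni"}; adjusted
    p-values are never below the raw ones. Pairs with a group of fewer
    than 2 cases are skipped with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("none", "holm", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    sub = diffs[["treatment", feature]].dropna()
    by_group = {t: g[feature].to_numpy(float) for t, g in sub.groupby("treatment")}

    tested, raw_p = [], []
    for g1, g2 in GROUP_PAIRS:
        a, b = by_group.get(g1, np.empty(0)), by_group.get(g2, np.empty(0))
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"pair {g1}-{g2} skipped for {feature}: too few cases")
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
            else:
                t, p, df = math.inf, 0.0, float(len(a) + len(b) - 2)
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        tested.append((g1, g2, t, df))
        raw_p.append(p)

    if not tested:
        return []
    if correction == "none":
        adjusted = list(raw_p)
    else:
        method = {"holm": "holm", "bonferroni": "bonferroni"}[correction]
        adjusted = list(multipletests(raw_p, method=method)[1])
    return [
        ContrastResult(
            feature=feature,
            group_pair=(g1, g2),
            t_stat=t,
            df=df,
            p_raw=p_raw,
            p_adjusted=float(p_adj),
            significant=bool(p_adj <= alpha),
        )
        for (g1, g2, t, df), p_raw, p_adj in zip(tested, raw_p, adjusted)
    ]


def summarize_differences(diffs: pd.DataFrame, feature: str) -> list:
    """Per-arm mean, standard error and n of one difference column.

    ``se = sd / sqrt(n)`` with the sample (n-1) standard deviation; a
    single-case group reports NaN.
    """
    sub = diffs[["treatment", feature]].dropna()
    out = []
    for t, g in sub.groupby("treatment"):
        vals = g[feature].to_numpy(float)
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
        out.append(
            GroupSummary(
                feature=feature, treatment=str(t), mean=float(vals.mean()), se=se, n=len(vals)
            )
        )
    return out
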