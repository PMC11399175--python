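"""Assumption-driven group comparisons for grouped biomarker data.

The decision tree mirrors common ecotoxicological practice:

1. Shapiro-Wilk normality per group.  If any group fails, the data are
   square-root transformed and retested; if they still fail, natural-log
   transformed and tested once more.
2. Data normal (possibly after transform): Levene's test for homogeneity
   of variance.  Homogeneous -> one-way ANOVA with Tukey HSD post hoc;
   heterogeneous -> Welch's ANOVA with Games-Howell post hoc.  Effect
   size: omega squared.
3. Data non-normal after both transforms: Kruskal-Wallis H with
   Dunn-Bonferroni post hoc.  Effect size: epsilon squared.

Every result carries a :class:`DecisionTrail` so the branch taken is
auditable.  Negative effect sizes (omnibus statistic below its null
expectation) are reported as computed, never clipped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DecisionTrail",
    "GroupComparisonResult",
    "InsufficientDataError",
    "assess_normality",
    "transform_cascade",
    "homogeneity",
    "one_way_anova",
    "welch_anova",
    "kruskal_wallis",
    "tukey_hsd",
    "games_howell",
    "dunn_bonferroni",
    "omega_squared",
    "epsilon_squared",
    "compare_groups",
]

ALPHA = 0.05

GroupData = Mapping[str, Sequence[float]]


class InsufficientDataError(ValueError):
    """A biomarker lacks the minimum group structure for any comparison."""


@dataclass
class NormalityResult:
    passed: bool
    per_group_p: dict[str, float | None]  # None = untestable (n < 3)
    degenerate: list[str] = field(default_factory=list)  # constant-valued groups


@dataclass
class DecisionTrail:
    """Audit record of the assumption checks behind a branch choice."""

    normality_raw: bool
    normality_raw_p: dict[str, float | None]
    transform_applied: str  # none | sqrt | ln | untransformable
    normality_final: bool
    levene_stat: float | None
    levene_p: float | None
    levene_degenerate: bool
    branch: str  # anova_tukey | welch_gameshowell | kruskal_dunn


@dataclass
class GroupComparisonResult:
    """Omnibus test, effect size, post-hoc table and the decision trail."""

    biomarker: str
    statistic_kind: str  # F | F_welch | H
    statistic: float
    df1: float
    df2: float | None
    n_total: int
    p: float
    effect_size_kind: str  # omega2 | epsilon2
    effect_size: float
    effect_size_approx: bool
    posthoc: pd.DataFrame
    trail: DecisionTrail
    significant: bool = False
    highly_significant: bool = False

    def __post_init__(self) -> None:
        self.significant = bool(self.p < ALPHA)
        self.highly_significant = bool(self.p < 0.01)


def _as_groups(values_by_group: GroupData) -> dict[str, np.ndarray]:
    out = {}
    for g, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[g] = arr
    return out


def assess_normality(values_by_group: GroupData, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk per group; overall pass iff every testable group passes.

    Groups with n < 3 are flagged untestable (p = None) and do not fail the
    overall assessment; a constant-valued group fails with a degenerate flag.
    """
    per_group: dict[str, float | None] = {}
    degenerate: list[str] = []
    passed = True
    for g, arr in _as_groups(values_by_group).items():
        if arr.size < 3:
            per_group[g] = None
            continue
        if np.ptp(arr) == 0.0:
            per_group[g] = 0.0
            degenerate.append(g)
            passed = False
            continue
        p = float(sps.shapiro(arr).pvalue)
        per_group[g] = p
        if p <= alpha:
            passed = False
    return NormalityResult(passed=passed, per_group_p=per_group, degenerate=degenerate)


def transform_cascade(
    values_by_group: GroupData, alpha: float = ALPHA
) -> tuple[dict[str, np.ndarray], str, NormalityResult]:
    """Try none -> sqrt -> ln, stopping at the first transform that passes.

    sqrt requires all values >= 0 and ln all values > 0; an inapplicable
    transform is skipped.  If nothing passes, the original values are
    returned with ``transform_applied`` recording the failure ("ln" when ln
    was tried last, "untransformable" when neither transform applied).
    """
    groups = _as_groups(values_by_group)
    raw = assess_normality(groups, alpha)
    if raw.passed:
        return groups, "none", raw

    allv = np.concatenate([a for a in groups.values()]) if groups else np.array([])
    tried = "none"
    if allv.size and allv.min() >= 0:
        tried = "sqrt"
        sq = {g: np.sqrt(a) for g, a in groups.items()}
        res = assess_normality(sq, alpha)
        if res.passed:
            return sq, "sqrt", res
    if allv.size and allv.min() > 0:
        tried = "ln"
        ln = {g: np.log(a) for g, a in groups.items()}
        res = assess_normality(ln, alpha)
        if res.passed:
            return ln, "ln", res
        return groups, "ln", res  # both transforms failed; ln was last tried
    return groups, ("untransformable" if tried == "none" else tried), raw


def homogeneity(
    values_by_group: GroupData, center: str = "mean"
) -> tuple[float, float, bool]:
    """Levene's test for equal variances (classical mean-centred by default).

    Returns (statistic, p, degenerate).  Groups with n < 2 are excluded;
    if every group has zero variance the test is undefined and reported as
    p = 1 with the degenerate flag set.
    """
    groups = [a for a in _as_groups(values_by_group).values() if a.size >= 2]
    if len(groups) < 2:
        raise InsufficientDataError("homogeneity test needs >= 2 groups of n >= 2")
    if all(np.ptp(a) == 0.0 for a in groups):
        return float("nan"), 1.0, True
    stat, p = sps.levene(*groups, center=center)
    if not math.isfinite(p):
        return float(stat), 1.0, True
    return float(stat), float(p), False


def one_way_anova(values_by_group: GroupData) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df1 = k-1, df2 = N-k, p)."""
    groups = list(_as_groups(values_by_group).values())
    k = len(groups)
    n_total = sum(a.size for a in groups)
    if k < 2 or n_total <= k:
        raise InsufficientDataError("ANOVA needs >= 2 groups and N > k")
    if all(np.ptp(a) == 0.0 for a in groups):
        raise InsufficientDataError("ANOVA undefined: zero within-group variance everywhere")
    F, p = sps.f_oneway(*groups)
    return float(F), k - 1, n_total - k, float(p)


def welch_anova(values_by_group: GroupData) -> tuple[float, int, float, float]:
    """Welch's heteroscedastic ANOVA: (F_welch, df1 = k-1, df2 adjusted, p).

    The denominator degrees of freedom are the Welch-Satterthwaite
    adjustment and are real-valued (e.g. F(3, 36.2)).
    """
    groups = _as_groups(values_by_group)
    for g, a in groups.items():
        if a.size < 2:
            raise InsufficientDataError(f"Welch ANOVA: group {g!r} has n < 2")
        if np.ptp(a) == 0.0:
            raise InsufficientDataError(f"Welch ANOVA: group {g!r} has zero variance")
    import pingouin as pg

    frames = [pd.DataFrame({"y": a, "g": g}) for g, a in groups.items()]
    df = pd.concat(frames, ignore_index=True)
    res = pg.welch_anova(data=df, dv="y", between="g")
    return (
        float(res["F"].iloc[0]),
        int(res["ddof1"].iloc[0]),
        float(res["ddof2"].iloc[0]),
        float(res["p_unc"].iloc[0]),
    )


def kruskal_wallis(values_by_group: GroupData) -> tuple[float, int, float, int]:
    """Kruskal-Wallis rank test with tie correction: (H, df = k-1, p, N).

    All values identical is a legal degenerate input: H = 0, p = 1.
    """
    groups = list(_as_groups(values_by_group).values())
    k = len(groups)
    if k < 2 or any(a.size < 1 for a in groups):
        raise InsufficientDataError("Kruskal-Wallis needs >= 2 non-empty groups")
    n_total = sum(a.size for a in groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0.0:
        return 0.0, k - 1, 1.0, n_total
    H, p = sps.kruskal(*groups)
    return float(H), k - 1, float(p), n_total


def _posthoc_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["group_i", "group_j", "estimate", "p_adjusted", "significant"])
    return df


def tukey_hsd(values_by_group: GroupData, alpha: float = ALPHA) -> pd.DataFrame:
    """Tukey(-Kramer) HSD pairwise table using pooled within-group variance."""
    groups = _as_groups(values_by_group)
    labels = list(groups)
    arrays = [groups[g] for g in labels]
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        est = float(np.mean(arrays[i]) - np.mean(arrays[j]))
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "estimate": est,
                "p_adjusted": min(max(p, 0.0), 1.0),
                "significant": p < alpha,
            }
        )
    return _posthoc_frame(rows)


def games_howell(values_by_group: GroupData, alpha: float = ALPHA) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal variances.

    Per pair: q = |m_i - m_j| / sqrt((s_i^2/n_i + s_j^2/n_j)/2) with a
    Welch-Satterthwaite per-pair df, referred to the studentized range.
    """
    groups = _as_groups(values_by_group)
    for g, a in groups.items():
        if a.size < 2:
            raise InsufficientDataError(f"Games-Howell: group {g!r} has n < 2")
    import pingouin as pg

    frames = [pd.DataFrame({"y": a, "g": g}) for g, a in groups.items()]
    df = pd.concat(frames, ignore_index=True)
    res = pg.pairwise_gameshowell(data=df, dv="y", between="g")
    rows = []
    for _, r in res.iterrows():
        p = float(min(max(r["pval"], 0.0), 1.0))
        rows.append(
            {
                "group_i": str(r["A"]),
                "group_j": str(r["B"]),
                "estimate": float(r["diff"]),
                "p_adjusted": p,
                "significant": p < alpha,
            }
        )
    return _posthoc_frame(rows)


def dunn_bonferroni(values_by_group: GroupData, alpha: float = ALPHA) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with Bonferroni correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) where
    T = sum(t^3 - t) / (12 (N - 1)) corrects for ties; two-sided p-values
    are multiplied by the number of pairs and capped at 1.
    """
    groups = _as_groups(values_by_group)
    labels = list(groups)
    arrays = [groups[g] for g in labels]
    allv = np.concatenate(arrays)
    n = allv.size
    ranks = sps.rankdata(allv)
    # mean rank per group
    bounds = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [float(np.mean(ranks[bounds[i] : bounds[i + 1]])) for i in range(len(arrays))]
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        ni, nj = arrays[i].size, arrays[j].size
        se = math.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "estimate": float(z),
                "p_adjusted": float(p),
                "significant": p < alpha,
            }
        )
    return _posthoc_frame(rows)


def omega_squared(F: float, df1: float, df2: float) -> float:
    """Omega squared from an F statistic and its degrees of freedom.

    omega^2 = df1 (F - 1) / (df1 (F - 1) + N) with N = df1 + df2 + 1.
    Negative when F < 1, which is reported as computed.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("omega_squared requires df1 >= 1 and df2 >= 1")
    n = df1 + df2 + 1
    num = df1 * (F - 1.0)
    return num / (num + n)


def epsilon_squared(H: float, n_total: int) -> float:
    """Epsilon squared for a Kruskal-Wallis H: H (n+1) / (n^2 - 1) = H / (n - 1)."""
    if n_total < 2:
        raise ValueError("epsilon_squared requires n_total >= 2")
    return H / (n_total - 1)


def compare_groups(
    table: pd.DataFrame,
    biomarker: str,
    group_col: str = "group",
    alpha: float = ALPHA,
    levene_center: str = "mean",
    posthoc: str = "always",
) -> GroupComparisonResult:
    """Run the full decision tree for one biomarker of a tidy table.

    Normality cascade (none/sqrt/ln); then Levene to choose between
    classical ANOVA + Tukey and Welch + Games-Howell; non-normal data go
    to Kruskal-Wallis + Dunn-Bonferroni.  Rank-based tests use the raw
    (untransformed) values since ranks are invariant to the monotone
    transforms of the cascade.  ``posthoc``: "always" (default; pairwise
    tables are reported even alongside a non-significant omnibus),
    "gated" (only when omnibus p < alpha) or "never" (omnibus and effect
    size only, for large simulations).
    """
    if biomarker not in table.columns:
        raise KeyError(f"biomarker column {biomarker!r} not in table")
    sub = table[[group_col, biomarker]].dropna()
    groups_raw = {
        str(g): np.asarray(v[biomarker], dtype=float)
        for g, v in sub.groupby(group_col, sort=False)
    }
    groups_raw = {g: a for g, a in groups_raw.items() if a.size >= 2}
    if len(groups_raw) < 2:
        raise InsufficientDataError(
            f"{biomarker}: need >= 2 groups with >= 2 values each"
        )
    raw_norm = assess_normality(groups_raw, alpha)
    transformed, transform_applied, final_norm = transform_cascade(groups_raw, alpha)

    if posthoc not in ("always", "gated", "never"):
        raise ValueError(f"unknown posthoc mode {posthoc!r}")
    levene_stat: float | None = None
    levene_p: float | None = None
    levene_degenerate = False
    empty = _posthoc_frame([])

    if final_norm.passed:
        levene_stat, levene_p, levene_degenerate = homogeneity(transformed, center=levene_center)
        if levene_p > alpha:
            branch = "anova_tukey"
            F, df1, df2, p = one_way_anova(transformed)
            es = omega_squared(F, df1, df2)
            pairs_fn = lambda: tukey_hsd(transformed, alpha)
            kind, es_kind, approx = "F", "omega2", False
            stat, d1, d2, n_tot = F, float(df1), float(df2), int(df1 + df2 + 1)
        else:
            branch = "welch_gameshowell"
            F, df1, df2w, p = welch_anova(transformed)
            n_tot = sum(a.size for a in transformed.values())
            # omega^2 uses nominal df1 and the actual N; approximate under Welch
            es = omega_squared(F, df1, n_tot - df1 - 1)
            pairs_fn = lambda: games_howell(transformed, alpha)
            kind, es_kind, approx = "F_welch", "omega2", True
            stat, d1, d2 = F, float(df1), float(df2w)
    else:
        branch = "kruskal_dunn"
        H, df1, p, n_tot = kruskal_wallis(groups_raw)
        es = epsilon_squared(H, n_tot)
        pairs_fn = lambda: dunn_bonferroni(groups_raw, alpha)
        kind, es_kind, approx = "H", "epsilon2", False
        stat, d1, d2 = H, float(df1), None

    if posthoc == "always" or (posthoc == "gated" and p < alpha):
        pairs = pairs_fn()
    else:
        pairs = empty

    trail = DecisionTrail(
        normality_raw=raw_norm.passed,
        normality_raw_p=raw_norm.per_group_p,
        transform_applied=transform_applied,
        normality_final=final_norm.passed,
        levene_stat=levene_stat,
        levene_p=levene_p,
        levene_degenerate=levene_degenerate,
        branch=branch,
    )
    return GroupComparisonResult(
        biomarker=biomarker,
        statistic_kind=kind,
        statistic=float(stat),
        df1=d1,
        df2=d2,
        n_total=int(n_tot),
        p=float(p),
        effect_size_kind=es_kind,
        effect_size=float(es),
        effect_size_approx=approx,
        posthoc=pairs,
        trail=trail,
    )
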