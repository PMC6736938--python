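"""Statistical evaluation layer.

Covers the analyses used to evaluate the eye-tracking score against
clinical reference data: Spearman rank correlation (exact permutation p
for small samples), Kruskal–Wallis with the Steel–Dwass all-pairs
follow-up, one-way ANOVA with Tukey–Kramer pairwise comparisons,
Pearson chi-square independence tests, and ROC/AUC with a stratified
bootstrap confidence interval.  Scalar primitives (tie-corrected H,
chi-square, F, the studentized-range distribution) come from scipy;
the Steel–Dwass procedure, exact/permutation p-values, effect sizes
and the direction-aware AUC are implemented here.

Effect sizes: Kruskal–Wallis reports epsilon-squared
(H / (n - 1), the rank analogue of eta-squared); contingency tables
report Cramer's V; ANOVA reports eta-squared = SS_between / SS_total.

ROC direction: a *lower* score marks the impaired (positive) class for
both the eye-tracking score and the MMSE, so
AUC = P(score_impaired < score_healthy) + 1/2 P(tie),
the normalized Mann–Whitney U.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .gaze_model import Cohort, Group
from .scoring import mmse_category

__all__ = [
    "TestResult",
    "CorrelationResult",
    "AnovaResult",
    "ROCResult",
    "spearman",
    "kruskal_wallis",
    "steel_dwass",
    "anova_tukey",
    "chi_square_independence",
    "roc_auc",
    "cohort_report",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p: float
    method: str
    effect_size: float | None = None
    effect_size_label: str | None = None
    pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p must be in [0,1], got {self.p}")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValidationError(f"|rho| must be <= 1, got {self.rho}")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p must be in [0,1], got {self.p}")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    eta_squared: float
    p: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_squared <= 1.0):
            raise ValidationError(f"eta_squared must be in [0,1], got {self.eta_squared}")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    direction: str = "lower_score_impaired"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValidationError(
                f"CI must satisfy 0 <= ci_low <= auc <= ci_high <= 1, got "
                f"({self.ci_low}, {self.auc}, {self.ci_high})"
            )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    p is two-sided: exact by full permutation enumeration for
    n <= ``exact_max_n``, otherwise the t-approximation on n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"spearman needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman undefined for a constant vector")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        sy = ry - ry.mean()
        sx = rx - rx.mean()
        denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
        obs = abs(float(sx @ sy))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(float(sx @ sy[list(perm)]))
            if stat >= obs - 1e-12 * denom:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=min(p, 1.0), n=n)


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H from first principles."""
    all_v = np.concatenate(groups)
    n = all_v.size
    ranks = sps.rankdata(all_v)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(all_v, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups,
    p_method: str = "asymptotic",
    n_perm: int = 10000,
    seed: int | None = 0,
) -> TestResult:
    """Kruskal–Wallis rank test across k groups.

    ``p_method``: "asymptotic" (chi-square on k-1 df), "permutation"
    (Monte Carlo label shuffles), or "exact" (full enumeration of group
    assignments; small samples only).  Effect size is epsilon-squared
    = H / (n - 1).  All observations identical is degenerate: H = 0,
    p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("kruskal_wallis needs >= 2 nonempty groups")
    k = len(groups)
    n = sum(g.size for g in groups)
    all_v = np.concatenate(groups)
    if np.ptp(all_v) == 0:
        return TestResult(
            statistic=0.0, df=k - 1, p=1.0, method="kruskal-wallis",
            effect_size=0.0, effect_size_label="epsilon_squared",
        )
    h = _kw_h(groups)
    sizes = [g.size for g in groups]
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(h, k - 1))
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        vals = all_v.copy()
        for _ in range(n_perm):
            rng.shuffle(vals)
            perm_groups = np.split(vals, np.cumsum(sizes)[:-1])
            if _kw_h(list(perm_groups)) >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    elif p_method == "exact":
        count = 0
        total = 0
        for assign in _group_assignments(n, sizes):
            perm_groups = [all_v[list(ix)] for ix in assign]
            if _kw_h(perm_groups) >= h - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        raise ValidationError(f"unknown p_method: {p_method!r}")
    return TestResult(
        statistic=h, df=k - 1, p=min(p, 1.0), method=f"kruskal-wallis ({p_method})",
        effect_size=h / (n - 1), effect_size_label="epsilon_squared",
    )


def _group_assignments(n: int, sizes: list[int]):
    """All ways to partition indices 0..n-1 into ordered groups of the
    given sizes (exhaustive; use for small n only)."""

    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        m = sizes_left[0]
        if len(sizes_left) == 1:
            yield [remaining]
            return
        for combo in itertools.combinations(remaining, m):
            cs = set(combo)
            rest = tuple(i for i in remaining if i not in cs)
            for tail in rec(rest, sizes_left[1:]):
                yield [combo] + tail

    yield from rec(tuple(range(n)), sizes)


# ---------------------------------------------------------------------------
# Steel–Dwass
# ---------------------------------------------------------------------------


def steel_dwass(groups, labels: list[str] | None = None) -> list[TestResult]:
    """Steel–Dwass all-pairs nonparametric multiple comparison.

    For each pair of groups, the Wilcoxon rank-sum statistic is computed
    on that pair alone, standardized with the tie-corrected variance,
    and sqrt(2)|t| is referred to the studentized-range distribution
    with k groups and infinite df (asymptotic reference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValidationError("steel_dwass needs >= 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("steel_dwass needs every group size >= 2")
    labels = labels if labels is not None else [f"g{i}" for i in range(k)]
    out: list[TestResult] = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = groups[i], groups[j]
        m, nn = a.size, b.size
        pooled = np.concatenate([a, b])
        big_n = m + nn
        ranks = sps.rankdata(pooled)
        w = float(ranks[:m].sum())
        e = m * (big_n + 1) / 2.0
        v = m * nn / (big_n * (big_n - 1)) * (
            float((ranks**2).sum()) - big_n * (big_n + 1) ** 2 / 4.0
        )
        if v <= 0:
            t = 0.0
            p = 1.0
        else:
            t = (w - e) / math.sqrt(v)
            p = float(sps.studentized_range.sf(math.sqrt(2.0) * abs(t), k, np.inf))
        out.append(
            TestResult(
                statistic=t, df=(m, nn), p=min(max(p, 0.0), 1.0),
                method="steel-dwass", pair=(labels[i], labels[j]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey–Kramer
# ---------------------------------------------------------------------------


def anova_tukey(groups, labels: list[str] | None = None) -> AnovaResult:
    """One-way ANOVA with eta-squared and Tukey–Kramer pairwise p's.

    The Tukey–Kramer form handles unequal group sizes; pairwise
    p-values come from the studentized-range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("anova_tukey needs >= 2 groups with n >= 2 each")
    labels = labels if labels is not None else [f"g{i}" for i in range(len(groups))]
    n = sum(g.size for g in groups)
    k = len(groups)
    if all(np.ptp(g) == 0 for g in groups):
        raise ValidationError("zero within-group variance everywhere: F undefined")
    grand = float(np.concatenate(groups).mean())
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((np.concatenate(groups) - grand) ** 2).sum())
    f_stat, p = sps.f_oneway(*groups)
    pairwise: list[tuple[str, str, float]] = []
    if k >= 2:
        res = sps.tukey_hsd(*groups)
        for i, j in itertools.combinations(range(k), 2):
            pairwise.append((labels[i], labels[j], float(res.pvalue[i, j])))
    return AnovaResult(
        F=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        eta_squared=ss_between / ss_total if ss_total > 0 else 0.0,
        p=float(p),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Chi-square independence
# ---------------------------------------------------------------------------


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction (the comparison of interest has df > 1).
    Effect size is Cramer's V.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("table must be at least 2x2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValidationError("table must hold nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    n = float(table.sum())
    r, c = table.shape
    v = math.sqrt(chi2 / (n * (min(r, c) - 1))) if chi2 > 0 else 0.0
    return TestResult(
        statistic=float(chi2), df=int(df), p=float(p),
        method="chi-square independence",
        effect_size=v, effect_size_label="cramers_v",
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _auc_lower_impaired(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos < neg) + 1/2 P(pos == neg), via midranks."""
    scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(scores)
    n_pos, n_neg = pos.size, neg.size
    # U counting (neg > pos) pairs with half credit for ties
    u_neg = float(ranks[n_pos:].sum()) - n_neg * (n_neg + 1) / 2.0
    return u_neg / (n_pos * n_neg)


def roc_auc(
    scores,
    labels,
    direction: str = "lower_score_impaired",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """AUC of ``scores`` for separating impaired (``labels`` truthy)
    from healthy, with a stratified percentile-bootstrap 95% CI.

    Under the default direction a lower score marks impairment, so the
    AUC is the probability that a random impaired subject scores below
    a random healthy one, ties half-credited (the normalized
    Mann–Whitney U).  Bootstrap resamples the two classes separately;
    the percentile interval is widened, if needed, to contain the point
    estimate so the CI ordering invariant always holds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    if direction not in ("lower_score_impaired", "higher_score_impaired"):
        raise ValidationError(f"unknown direction: {direction!r}")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    if direction == "higher_score_impaired":
        pos, neg = -pos, -neg
    auc = _auc_lower_impaired(pos, neg)
    if n_boot >= 1:
        rng = np.random.default_rng(seed)
        bp = pos[rng.integers(0, pos.size, size=(n_boot, pos.size))]
        bn = neg[rng.integers(0, neg.size, size=(n_boot, neg.size))]
        # vectorized pairwise comparison per bootstrap replicate
        diff = bn[:, None, :] - bp[:, :, None]
        boot = (np.mean(diff > 0, axis=(1, 2)) + 0.5 * np.mean(diff == 0, axis=(1, 2)))
        lo, hi = np.percentile(boot, [2.5, 97.5])
        lo = min(float(lo), auc)
        hi = max(float(hi), auc)
    else:
        lo = hi = auc
    return ROCResult(
        auc=auc, ci_low=lo, ci_high=hi,
        n_pos=int(pos.size), n_neg=int(neg.size), direction=direction,
    )


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

_CLINICAL_COLS = ("mmse", "adas_cog", "fab")


def _corr_dict(r: CorrelationResult) -> dict:
    return {"rho": r.rho, "p": r.p, "n": r.n}


def _roc_dict(r: ROCResult) -> dict:
    return {
        "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "n_pos": r.n_pos, "n_neg": r.n_neg,
    }


def cohort_report(cohort: Cohort, n_boot: int = 2000, seed: int = 0) -> dict:
    """Run the full evaluation suite on a scored cohort.

    Produces (a) Spearman correlations of the eye-tracking score with
    each available clinical score, (b) group comparisons of the score
    by clinical group and by MMSE category (ANOVA + Tukey–Kramer),
    (c) ROC/AUC of the score and of the MMSE for MCI-vs-HC and
    (MCI+dementia)-vs-HC, and (d) Table-1-style demographics (group
    sizes, clinical scores by group via Kruskal–Wallis + Steel–Dwass,
    and an MMSE-category-by-group chi-square).  Analyses whose inputs
    are missing are skipped with a logged reason.
    """
    df = cohort.to_frame()
    if df["et_score"].notna().sum() == 0:
        raise ValidationError("cohort_report requires et_score on at least one subject")
    report: dict = {"n": len(cohort), "skipped": []}
    report["group_sizes"] = {
        g.value: int((df["group"] == g.value).sum()) for g in Group
    }

    # (a) correlations
    report["correlations"] = {}
    for col in _CLINICAL_COLS:
        ok = df["et_score"].notna() & df[col].notna()
        if ok.sum() < 3:
            report["skipped"].append(
                f"spearman et_score~{col}: only {int(ok.sum())} complete pairs"
            )
            continue
        try:
            r = spearman(df.loc[ok, "et_score"], df.loc[ok, col])
        except ValidationError as exc:
            report["skipped"].append(f"spearman et_score~{col}: {exc}")
            continue
        report["correlations"][col] = _corr_dict(r)

    # (b) group comparisons of et_score
    report["group_comparison"] = {}
    scored = df[df["et_score"].notna()]
    by_group = [
        scored.loc[scored["group"] == g.value, "et_score"].to_numpy() for g in Group
    ]
    names = [g.value for g in Group]
    if all(len(g) >= 2 for g in by_group):
        a = anova_tukey(by_group, labels=names)
        report["group_comparison"]["by_clinical_group"] = {
            "F": a.F, "df": [a.df_between, a.df_within],
            "eta_squared": a.eta_squared, "p": a.p,
            "pairwise": [list(t) for t in a.pairwise],
        }
    else:
        report["skipped"].append("ANOVA by clinical group: a group has n < 2")
    with_mmse = scored[scored["mmse"].notna()]
    if len(with_mmse):
        cats = with_mmse["mmse"].map(lambda v: mmse_category(int(v)).value)
        cat_names = ["LOW", "MIDDLE", "HIGH"]
        by_cat = [
            with_mmse.loc[cats == c, "et_score"].to_numpy() for c in cat_names
        ]
        present = [(c, g) for c, g in zip(cat_names, by_cat) if len(g) >= 2]
        if len(present) >= 2:
            a = anova_tukey([g for _, g in present], labels=[c for c, _ in present])
            report["group_comparison"]["by_mmse_category"] = {
                "F": a.F, "df": [a.df_between, a.df_within],
                "eta_squared": a.eta_squared, "p": a.p,
                "pairwise": [list(t) for t in a.pairwise],
                "category_n": {c: int(len(g)) for c, g in zip(cat_names, by_cat)},
            }
        else:
            report["skipped"].append("ANOVA by MMSE category: < 2 categories with n >= 2")
    else:
        report["skipped"].append("ANOVA by MMSE category: no MMSE scores")

    # (c) ROC
    report["roc"] = {}
    rng = np.random.default_rng(seed)

    def _roc_block(sub: list[str], name: str, col: str) -> None:
        dd = scored if col == "et_score" else df[df[col].notna()]
        dd = dd[dd["group"].isin(sub)]
        y = (dd["group"] != Group.HC.value).to_numpy()
        if y.sum() == 0 or (~y).sum() == 0:
            report["skipped"].append(f"roc {col} {name}: a class is empty")
            return
        r = roc_auc(
            dd[col].to_numpy(), y, n_boot=n_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        report["roc"].setdefault(col, {})[name] = _roc_dict(r)

    for col in ("et_score", "mmse"):
        if df[col].notna().sum() == 0:
            report["skipped"].append(f"roc {col}: no values")
            continue
        _roc_block([Group.HC.value, Group.MCI.value], "mci_vs_hc", col)
        _roc_block(
            [Group.HC.value, Group.MCI.value, Group.DEMENTIA.value],
            "impaired_vs_hc", col,
        )

    # (d) demographics
    demo: dict = {}
    for col in _CLINICAL_COLS + ("cdr", "et_score", "recording_efficiency"):
        avail = df[df[col].notna()]
        by_g = [avail.loc[avail["group"] == g.value, col].to_numpy() for g in Group]
        entry: dict = {
            "available": {g.value: int(len(v)) for g, v in zip(Group, by_g)},
            "mean_sd": {
                g.value: [float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else None]
                for g, v in zip(Group, by_g) if len(v)
            },
        }
        if all(len(v) >= 2 for v in by_g):
            kw = kruskal_wallis(by_g)
            entry["kruskal_wallis"] = {
                "H": kw.statistic, "df": kw.df, "p": kw.p,
                "epsilon_squared": kw.effect_size,
            }
            entry["steel_dwass"] = [
                {"pair": list(t.pair), "t": t.statistic, "p": t.p}
                for t in steel_dwass(by_g, labels=names)
            ]
        else:
            report["skipped"].append(f"demographics {col}: a group has n < 2")
        demo[col] = entry
    with_mmse = df[df["mmse"].notna()]
    if len(with_mmse):
        cats = with_mmse["mmse"].map(lambda v: mmse_category(int(v)).value)
        tab = np.array(
            [
                [int(((with_mmse["group"] == g.value) & (cats == c)).sum()) for g in Group]
                for c in ["LOW", "MIDDLE", "HIGH"]
            ]
        )
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            cs = chi_square_independence(tab)
            demo["mmse_category_by_group_chi2"] = {
                "chi2": cs.statistic, "df": cs.df, "p": cs.p,
                "cramers_v": cs.effect_size,
            }
        else:
            report["skipped"].append("chi-square: MMSE-category table degenerate")
    report["demographics"] = demo
    return report
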