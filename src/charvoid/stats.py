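"""Group-comparison statistics for per-seed category counts.

The workflow mirrors the classic SPSS-style analysis of grouped
measurements: a one-way ANOVA across seed groups, a variance-homogeneity
gate (Levene's test, mean-centered) that selects the post-hoc family —
Fisher's LSD when variances look equal, Dunnett's T3 when they do not —
and a plain two-tailed t-test for two-group contrasts.

Fisher's LSD uses pairwise t statistics built on the pooled
within-group mean square (the ANOVA error term) with its N − k degrees
of freedom.  Dunnett's T3 uses the Welch statistic per pair with
Welch–Satterthwaite degrees of freedom and adjusts family-wise via the
studentized maximum modulus (SMM) distribution, evaluated here by
seeded Monte Carlo (default 100 000 draws) rather than from printed
quantile tables, which keeps it exact at arbitrary fractional df.

All tests report effect sizes (mean differences with standard errors
and confidence intervals) alongside p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GroupData",
    "GroupComparison",
    "oneway_anova",
    "variance_gate",
    "fisher_lsd",
    "dunnett_t3",
    "t_test_two_tailed",
    "compare_groups",
]

DEFAULT_ALPHA = 0.05
SMM_MC_DRAWS = 100_000
SMM_MC_SEED = 20170227  # fixed: T3 adjusted p-values are reproducible


@dataclass(frozen=True)
class GroupData:
    """One labelled group of per-seed values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        if self.values.size < 2:
            raise ValidationError(
                f"group {self.label!r} needs >= 2 values for variance-based tests"
            )


@dataclass
class PairwiseResult:
    """One pairwise contrast."""

    group_a: str
    group_b: str
    mean_diff: float
    se: float
    df: float
    statistic: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class GroupComparison:
    """Full comparison report for one measurement across groups."""

    f_statistic: float
    df: tuple[int, int]
    p_anova: float
    homogeneity_p: float
    posthoc_method: str  # "LSD" or "DunnettT3"
    pairwise: list[PairwiseResult]
    pairwise_lsd: list[PairwiseResult] = field(default_factory=list)
    pairwise_t3: list[PairwiseResult] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def pairwise_p(self, a: str, b: str) -> float:
        for r in self.pairwise:
            if {r.group_a, r.group_b} == {a, b}:
                return r.p
        raise KeyError(f"no contrast {a} vs {b}")

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df": list(self.df),
            "p_anova": self.p_anova,
            "homogeneity_p": self.homogeneity_p,
            "posthoc_method": self.posthoc_method,
            "alpha": self.alpha,
            "pairwise": [
                {
                    "a": r.group_a,
                    "b": r.group_b,
                    "mean_diff": r.mean_diff,
                    "se": r.se,
                    "df": r.df,
                    "statistic": r.statistic,
                    "p": r.p,
                    "ci": [r.ci_low, r.ci_high],
                }
                for r in self.pairwise
            ],
        }


def _check_groups(groups: list[GroupData]) -> None:
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    pooled = np.concatenate([g.values for g in groups])
    centered = np.concatenate([g.values - g.values.mean() for g in groups])
    if np.allclose(centered, 0.0):
        raise DegenerateDataError(
            "zero within-group variance; ANOVA-family tests are undefined"
        )
    if not np.all(np.isfinite(pooled)):
        raise ValidationError("group values must be finite")


def oneway_anova(groups: list[GroupData]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, (df_between, df_within), p)`` where F is the ratio of
    between- to within-group mean squares and p comes from the F
    distribution.
    """
    _check_groups(groups)
    k = len(groups)
    n_total = sum(g.values.size for g in groups)
    grand = np.concatenate([g.values for g in groups]).mean()
    ss_between = sum(g.values.size * (g.values.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), (df_b, df_w), p


def variance_gate(groups: list[GroupData], alpha: float = DEFAULT_ALPHA) -> str:
    """Select the post-hoc family by Levene's test (mean-centered).

    p >= alpha: variances look homogeneous → ``"LSD"``; otherwise
    ``"DunnettT3"``.
    """
    _check_groups(groups)
    _, p = sps.levene(*[g.values for g in groups], center="mean")
    return "LSD" if p >= alpha else "DunnettT3"


def _pair_iter(groups: list[GroupData]):
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            yield groups[i], groups[j]


def fisher_lsd(
    groups: list[GroupData], alpha: float = DEFAULT_ALPHA
) -> list[PairwiseResult]:
    """Fisher's least-significant-difference pairwise comparisons.

    Each pair is tested with a t statistic whose standard error uses
    the pooled within-group mean square (MSW) on N − k df, i.e. the
    ANOVA error term; no multiplicity adjustment (the classical LSD).
    """
    _check_groups(groups)
    k = len(groups)
    n_total = sum(g.values.size for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    df_w = n_total - k
    msw = ss_within / df_w
    out = []
    for ga, gb in _pair_iter(groups):
        na, nb = ga.values.size, gb.values.size
        diff = float(ga.values.mean() - gb.values.mean())
        se = float(np.sqrt(msw * (1.0 / na + 1.0 / nb)))
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_w))
        tcrit = float(sps.t.ppf(1 - alpha / 2, df_w))
        out.append(
            PairwiseResult(ga.label, gb.label, diff, se, float(df_w), t, p,
                           diff - tcrit * se, diff + tcrit * se)
        )
    return out


def _smm_sf(
    q: float, n_comparisons: int, df: float, draws: int, rng: np.random.Generator
) -> float:
    """P(SMM(m, df) >= q) by Monte Carlo.

    SMM(m, ν) is the maximum of m independent |N(0,1)| variates divided
    by a shared sqrt(χ²_ν / ν).
    """
    z = np.abs(rng.standard_normal((draws, n_comparisons))).max(axis=1)
    s = np.sqrt(rng.chisquare(df, size=draws) / df)
    return float(np.mean(z / s >= q))


def dunnett_t3(
    groups: list[GroupData],
    alpha: float = DEFAULT_ALPHA,
    mc_draws: int = SMM_MC_DRAWS,
    mc_seed: int = SMM_MC_SEED,
) -> list[PairwiseResult]:
    """Dunnett's T3 pairwise comparisons for unequal variances.

    Per pair: Welch statistic with Welch–Satterthwaite df; the adjusted
    p-value is the tail probability of the studentized maximum modulus
    over all m = k(k−1)/2 comparisons at that pair's df, evaluated by
    seeded Monte Carlo.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValidationError(f"group {g.label!r} has fewer than 2 values")
    _check_groups(groups)
    m = len(groups) * (len(groups) - 1) // 2
    rng = np.random.default_rng(mc_seed)
    out = []
    for ga, gb in _pair_iter(groups):
        na, nb = ga.values.size, gb.values.size
        va, vb = ga.values.var(ddof=1), gb.values.var(ddof=1)
        diff = float(ga.values.mean() - gb.values.mean())
        se2 = va / na + vb / nb
        if se2 == 0.0:
            raise DegenerateDataError(
                f"pair {ga.label}/{gb.label} has zero variance in both groups"
            )
        se = float(np.sqrt(se2))
        t = diff / se
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = _smm_sf(abs(t), m, df, mc_draws, rng)
        # CI half-width from the MC SMM alpha-quantile at this df
        z = np.abs(rng.standard_normal((mc_draws, m))).max(axis=1)
        s = np.sqrt(rng.chisquare(df, size=mc_draws) / df)
        qcrit = float(np.quantile(z / s, 1 - alpha))
        out.append(
            PairwiseResult(ga.label, gb.label, diff, se, float(df), t, p,
                           diff - qcrit * se, diff + qcrit * se)
        )
    return out


def t_test_two_tailed(
    a, b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Student (pooled) by default, Welch
    via ``equal_var=False``.  Returns ``(t, p)``."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            raise DegenerateDataError(
                "both samples constant with equal means; t undefined"
            )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    groups: list[GroupData],
    alpha: float = DEFAULT_ALPHA,
    mc_draws: int = SMM_MC_DRAWS,
) -> GroupComparison:
    """Run the full ANOVA → gate → post-hoc workflow.

    Both post-hoc families are always computed and attached so either
    can be inspected; ``posthoc_method``/``pairwise`` reflect the one
    the Levene gate selected.
    """
    f, df, p = oneway_anova(groups)
    _, lev_p = sps.levene(*[g.values for g in groups], center="mean")
    method = "LSD" if lev_p >= alpha else "DunnettT3"
    lsd = fisher_lsd(groups, alpha)
    t3 = dunnett_t3(groups, alpha, mc_draws=mc_draws)
    return GroupComparison(
        f_statistic=f,
        df=df,
        p_anova=p,
        homogeneity_p=float(lev_p),
        posthoc_method=method,
        pairwise=lsd if method == "LSD" else t3,
        pairwise_lsd=lsd,
        pairwise_t3=t3,
        alpha=alpha,
    )


def groups_from_tidy(
    df: pd.DataFrame, category: str, value_col: str = "value"
) -> list[GroupData]:
    """Build :class:`GroupData` from a tidy frame.

    Expects columns ``group``, ``category`` and *value_col*; rows are
    filtered to *category* and grouped by ``group`` (label-sorted for
    a stable ordering).
    """
    sub = df[df["category"] == category]
    if sub.empty:
        raise ValidationError(f"no rows for category {category!r}")
    return [
        GroupData(label=str(g), values=v[value_col].to_numpy())
        for g, v in sub.groupby("group", sort=True)
    ]
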